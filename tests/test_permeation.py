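"""Event detection, conductance arithmetic and replicate statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from porepi.permeation import (GateDefinition, compare_models,
                               conductance_pS, count_permeation_events,
                               detect_permeation_events, estimate_conductance,
                               replicate_conductance, unwrap_axial)
from porepi.synthetic_data import PoreSystemSpec, Trajectory, simulate_pore

GATE = GateDefinition(-10.0, 10.0)
L = 80.0


def brute_force_event_count(z, gate, period, substep=0.5):
    """Independent oracle: refine the path so no substep can skip a region,
    then book-keep below/inside/above occupancy at every substep."""
    zz = [z[0]]
    for a, b in zip(z[:-1], z[1:]):
        n = max(1, int(abs(b - a) / substep) + 1)
        zz.extend(a + (b - a) * (i + 1) / n for i in range(n))
    net = 0
    last_outside = None  # id of last outside interval occupied
    for p in zz:
        k = math.floor((p - gate.z_low) / period)
        inside = p <= gate.z_high + k * period
        if inside:
            continue
        outside_id = k + 1
        if last_outside is not None and outside_id != last_outside:
            net += outside_id - last_outside
        last_outside = outside_id
    return net


def _traj_from_z(z_per_ion, box_z=L, dt=1.0):
    z = np.asarray(z_per_ion, dtype=float)  # (n_frames, n_ions)
    n_frames, n_ions = z.shape
    coords = np.zeros((n_frames, n_ions, 3))
    coords[:, :, 2] = z
    return Trajectory(times=np.arange(n_frames) * dt,
                      box=np.array([30.0, 30.0, box_z]),
                      ids=np.arange(n_ions),
                      species=np.array(["ion"] * n_ions), coords=coords)


class TestUnwrap:
    def test_minimum_image_across_boundary(self):
        traj = _traj_from_z(np.array([[39.0], [-39.0]]))
        _, z = unwrap_axial(traj)
        np.testing.assert_allclose(z[:, 0], [39.0, 41.0])

    def test_continuous_input_unchanged(self):
        series = np.linspace(-30, 30, 40)[:, None]
        traj = _traj_from_z(series)
        _, z = unwrap_axial(traj)
        np.testing.assert_allclose(z, series)

    def test_wrapped_random_walks_recover_true_path(self, rng):
        # oracle = the never-wrapped cumulative walk itself
        for _ in range(50):
            true = np.cumsum(rng.normal(0, 3.0, size=300))
            wrapped = true - L * np.round(true / L)
            traj = _traj_from_z(wrapped[:, None])
            _, z = unwrap_axial(traj)
            np.testing.assert_allclose(z[:, 0] - z[0, 0], true - true[0],
                                       atol=1e-9)

    def test_ambiguous_jump_warns_with_ion_and_frame(self):
        traj = _traj_from_z(np.array([[0.0], [39.0]]))
        with pytest.warns(RuntimeWarning, match="ion 0.*frames 0"):
            unwrap_axial(traj)


class TestDetector:
    def test_single_monotone_traversal_is_one_event(self):
        z = np.linspace(-30, 30, 61)
        ev = detect_permeation_events(z, np.arange(61), GATE, period=L)
        assert len(ev) == 1 and ev[0].direction == 1
        assert ev[0].completion_time == np.argmax(z > 10.0)

    def test_downward_traversal_is_minus_one(self):
        z = np.linspace(30, -30, 61)
        ev = detect_permeation_events(z, np.arange(61), GATE, period=L)
        assert [e.direction for e in ev] == [-1]

    def test_oscillation_below_gate_counts_nothing(self):
        t = np.arange(200)
        z = -20 + 5 * np.sin(t / 7)
        assert detect_permeation_events(z, t, GATE, period=L) == []

    def test_recrossings_inside_slab_do_not_double_count(self):
        z = np.array([-15, -5, 5, -5, 5, -5, 8, 15.0])
        ev = detect_permeation_events(z, np.arange(z.size), GATE, period=L)
        assert [e.direction for e in ev] == [1]

    def test_empty_series_empty_list(self):
        assert detect_permeation_events([], [], GATE, period=L) == []

    def test_matches_brute_force_oracle_on_biased_walks(self, rng):
        for i in range(100):
            drift = rng.uniform(-0.5, 0.5)
            true = np.cumsum(rng.normal(drift, 4.0, size=400))
            ev = detect_permeation_events(true, np.arange(true.size), GATE,
                                          period=L)
            net = sum(e.direction for e in ev)
            assert net == brute_force_event_count(true, GATE, L), f"walk {i}"

    def test_wrapped_and_unwrapped_inputs_agree(self, rng):
        for _ in range(30):
            true = np.cumsum(rng.normal(0.3, 4.0, size=400))
            traj = _traj_from_z((true - L * np.round(true / L))[:, None])
            _, z = unwrap_axial(traj)
            ev_wrapped = detect_permeation_events(z[:, 0], traj.times, GATE, L)
            ev_true = detect_permeation_events(true, traj.times, GATE, L)
            assert (sum(e.direction for e in ev_wrapped)
                    == sum(e.direction for e in ev_true))


class TestConductance:
    def test_worked_example_five_events(self):
        est = estimate_conductance(5, duration_ps=1e5, voltage=0.5)
        assert est.conductance == pytest.approx(16.02176634, abs=1e-8)

    def test_zero_events_zero_conductance(self):
        assert estimate_conductance(0, 1e5, 0.5).conductance == 0.0

    def test_fractional_event_check_at_effective_voltage(self):
        # 6.125 events/100 ns pairs with 17.5 pS at an effective |V| near
        # 0.56 V rather than the nominal 0.5 V
        est = estimate_conductance(6.125, 1e5, 0.56)
        assert est.conductance == pytest.approx(17.52, abs=0.01)
        nominal = estimate_conductance(6.125, 1e5, 0.5)
        assert nominal.conductance == pytest.approx(19.63, abs=0.01)

    def test_zero_voltage_is_an_error(self):
        with pytest.raises(ValueError, match="zero voltage"):
            conductance_pS(5, 1e5, 0.0)

    @given(n=st.integers(1, 1000), t=st.floats(1.0, 1e6),
           v=st.floats(0.05, 2.0), q=st.floats(0.5, 3.0))
    def test_linearity(self, n, t, v, q):
        g = conductance_pS(n, t, v, q)
        assert conductance_pS(2 * n, 2 * t, v, q) == pytest.approx(g)
        assert conductance_pS(2 * n, t, v, q) == pytest.approx(2 * g)

    def test_field_sign_does_not_change_magnitude(self):
        spec = PoreSystemSpec(voltage=-0.5, n_ions=10, n_waters=0,
                              n_steps=20_000, frame_stride=20, seed=21)
        g = {}
        for v in (-0.5, 0.5):
            nets = []
            for r in range(3):
                traj = simulate_pore(spec.replace(voltage=v, seed=50 + r))
                ev = count_permeation_events(traj)
                nets.append(sum(e.direction for e in ev))
            g[v] = nets
        assert sum(g[-0.5]) > 0 and sum(g[0.5]) < 0
        assert abs(sum(g[-0.5]) + sum(g[0.5])) < 0.35 * abs(sum(g[-0.5]))


class TestReplicates:
    def test_zero_variance_counts(self):
        est = replicate_conductance([2] * 6, 1e5, 0.5)
        assert est.mean_g == pytest.approx(6.41, abs=0.005)
        assert est.sem_g == 0.0

    def test_two_replicates_mean_is_midpoint(self):
        est = replicate_conductance([1, 5], 1e5, 0.5)
        g1 = conductance_pS(1, 1e5, 0.5)
        g5 = conductance_pS(5, 1e5, 0.5)
        assert est.mean_g == pytest.approx((g1 + g5) / 2)

    def test_poisson_counts_match_hand_arithmetic(self, rng):
        counts = rng.poisson(3, size=6).tolist()
        est = replicate_conductance(counts, 1e5, 0.5)
        per = [c * 1.602176634e-19 * 1e24 / (1e5 * 0.5) for c in counts]
        mean = sum(per) / 6
        sd = math.sqrt(sum((x - mean) ** 2 for x in per) / 5)
        assert est.mean_g == pytest.approx(mean)
        assert est.sem_g == pytest.approx(sd / math.sqrt(6))

    def test_single_replicate_sem_undefined(self):
        with pytest.raises(ValueError, match="2 replicates"):
            replicate_conductance([3], 1e5, 0.5)


class TestWelch:
    def test_identical_samples_p_one(self):
        assert compare_models([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])[1] == 1.0

    def test_separated_samples_p_tiny(self):
        a = [0.0, 1e-6, -1e-6]
        b = [10.0, 10.0 + 1e-6, 10.0 - 1e-6]
        _, p = compare_models(a, b)
        assert p < 1e-3

    def test_symmetric_under_swap(self, rng):
        a, b = rng.normal(5, 1, 6), rng.normal(6, 2, 6)
        _, pab = compare_models(a, b)
        _, pba = compare_models(b, a)
        assert pab == pytest.approx(pba)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_models([1.0], [1.0, 2.0])
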