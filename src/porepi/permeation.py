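"""Ion-permeation event detection and single-channel conductance.

A permeation event is one complete traversal of the gate slab: an ion that
enters the slab from below ``z_low`` and leaves above ``z_high`` counts +1
(toward +z, the extracellular side), the mirror image counts −1.
Conductance follows from counting: g = |N_net| q e / (T |V|), reported in
pS, with replicate mean ± SEM and a Welch t-test for model comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._units import ELEMENTARY_CHARGE_C
from .synthetic_data import Trajectory, _minimum_image

__all__ = [
    "GateDefinition",
    "PermeationEvent",
    "ConductanceEstimate",
    "unwrap_axial",
    "detect_permeation_events",
    "count_permeation_events",
    "estimate_conductance",
    "replicate_conductance",
    "compare_models",
    "conductance_pS",
]


@dataclass(frozen=True)
class GateDefinition:
    """Axial slab used for event counting (pore axis = z, extracellular = +z)."""

    z_low: float
    z_high: float
    axis: str = "z"

    def __post_init__(self):
        if not self.z_low < self.z_high:
            raise ValueError("gate requires z_low < z_high")


@dataclass(frozen=True)
class PermeationEvent:
    ion_id: int
    completion_time: float  # ps
    direction: int          # +1 toward +z, -1 toward -z
    replicate_id: int = 0


@dataclass
class ConductanceEstimate:
    """Event-counting conductance with optional replicate statistics."""

    n_events_net: float
    duration: float          # ps
    voltage: float           # V
    charge_per_ion: float    # e
    conductance: float       # pS
    per_replicate: list = field(default_factory=list)  # pS
    mean_g: float | None = None
    sem_g: float | None = None


def conductance_pS(n_net, duration_ps, voltage, charge=1.0) -> float:
    """g = |N| q e / (T |V|) in pS (e = 1.602176634e-19 C)."""
    if duration_ps <= 0:
        raise ValueError("duration must be > 0")
    if voltage == 0:
        raise ValueError(
            "conductance is undefined from drift counting at zero voltage"
        )
    # N e[C] / (T[ps]*1e-12 s) / |V| -> siemens; *1e12 -> pS
    return abs(n_net) * charge * ELEMENTARY_CHARGE_C * 1e24 / (
        duration_ps * abs(voltage)
    )


def unwrap_axial(traj: Trajectory, species: str = "ion"):
    """Continuous (unwrapped) z(t) per ion.

    Returns (ids, z) with z of shape (n_frames, n_ions).  Uses the minimum
    image of each frame-to-frame displacement; an apparent displacement
    close to Lz/2 is ambiguous and triggers a warning naming ion and frame.
    Already-continuous input (no wrapping) is returned unchanged.
    """
    cols = traj.select(species)
    z = traj.coords[:, cols, 2]
    lz = float(traj.box[2])
    dz = np.diff(z, axis=0)
    wrapped = _minimum_image(dz, lz)
    sus = np.abs(wrapped) > 0.45 * lz
    if np.any(sus):
        fi, ii = np.argwhere(sus)[0]
        warnings.warn(
            f"ion {traj.ids[cols[ii]]}: displacement between frames {fi} and "
            f"{fi + 1} is {abs(wrapped[fi, ii]):.1f} Å (close to Lz/2 = "
            f"{lz / 2:.1f} Å); unwrapping may be ambiguous",
            RuntimeWarning,
        )
    out = np.concatenate([z[:1], z[:1] + np.cumsum(wrapped, axis=0)], axis=0)
    return traj.ids[cols], out


def detect_permeation_events(z_series, times, gate: GateDefinition,
                             period: float, ion_id: int = 0,
                             replicate_id: int = 0):
    """Permeation events of one ion from its continuous z(t).

    The line is partitioned by the periodic images of the gate slab into
    "inside" intervals [z_low + kL, z_high + kL] and "outside" intervals
    between them.  A +1 event completes when the ion reaches the outside
    interval above the slab having last occupied the one below (mirror for
    −1); re-crossings within the slab never double-count, and a wrap of the
    periodic coordinate that bypasses the slab does not count.
    """
    z = np.asarray(z_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if z.size == 0:
        return []
    if gate.z_high - gate.z_low >= period:
        raise ValueError("gate slab must be narrower than the periodic box")

    def outside_index(zi):
        """Index of the outside interval containing zi, or None if inside a
        gate image.  Outside interval k spans (z_high + (k-1)L, z_low + kL)."""
        k = math.floor((zi - gate.z_low) / period)
        if zi <= gate.z_high + k * period:  # inside image k
            return None
        return k + 1

    events = []
    o_prev = None
    for i in range(z.size):
        o = outside_index(z[i])
        if o is None:
            continue
        if o_prev is not None and o != o_prev:
            step = 1 if o > o_prev else -1
            for _ in range(abs(o - o_prev)):
                events.append(PermeationEvent(ion_id=ion_id,
                                              completion_time=float(t[i]),
                                              direction=step,
                                              replicate_id=replicate_id))
        o_prev = o
    return events


def count_permeation_events(traj: Trajectory, gate: GateDefinition | None = None,
                            replicate_id: int | None = None):
    """All permeation events of a trajectory's ions (unwrap + detect)."""
    if gate is None:
        gr = traj.metadata.get("gate_region")
        if gr is None:
            raise ValueError("no gate given and trajectory metadata has none")
        gate = GateDefinition(*gr)
    if replicate_id is None:
        replicate_id = int(traj.metadata.get("replicate_id", 0))
    ids, z = unwrap_axial(traj)
    events = []
    for j, ion in enumerate(ids):
        events.extend(
            detect_permeation_events(z[:, j], traj.times, gate,
                                     period=float(traj.box[2]),
                                     ion_id=int(ion), replicate_id=replicate_id)
        )
    return events


def _net_count(events) -> int:
    return sum(e.direction for e in events)


def estimate_conductance(events_or_count, duration_ps: float, voltage: float,
                         charge: float = 1.0) -> ConductanceEstimate:
    """Conductance from a signed net event count (or an event list).

    N_net counts traversals in the field direction minus those against it;
    g = |N_net| q e / (T |V|) in pS.
    """
    if isinstance(events_or_count, (int, float, np.integer, np.floating)):
        n_net = float(events_or_count)
    else:
        n_net = float(_net_count(events_or_count))
    g = conductance_pS(n_net, duration_ps, voltage, charge)
    return ConductanceEstimate(
        n_events_net=n_net, duration=duration_ps, voltage=voltage,
        charge_per_ion=charge, conductance=g,
    )


def replicate_conductance(per_replicate_counts, duration_ps: float,
                          voltage: float, charge: float = 1.0) -> ConductanceEstimate:
    """Replicate-resolved conductance: per-replicate g, mean and SEM.

    SEM is the sample standard deviation (n−1 denominator) over replicates
    divided by sqrt(n); requires at least two replicates.
    """
    counts = list(per_replicate_counts)
    if len(counts) < 2:
        raise ValueError("SEM undefined with fewer than 2 replicates")
    per_g = [conductance_pS(c, duration_ps, voltage, charge) for c in counts]
    mean_g = float(np.mean(per_g))
    sem_g = float(np.std(per_g, ddof=1) / math.sqrt(len(per_g)))
    return ConductanceEstimate(
        n_events_net=float(sum(counts)), duration=duration_ps, voltage=voltage,
        charge_per_ion=charge,
        conductance=conductance_pS(abs(sum(counts)), duration_ps * len(counts),
                                   voltage, charge),
        per_replicate=per_g, mean_g=mean_g, sem_g=sem_g,
    )


def compare_models(g_samples_a, g_samples_b):
    """Two-sided Welch t-test between two conductance samples.

    Returns (statistic, p_value).  Two zero-variance samples with equal
    means are identical by construction and return p = 1.
    """
    a = np.asarray(g_samples_a, dtype=float)
    b = np.asarray(g_samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(p):
        p = 1.0
    return float(t), float(p)
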