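"""Ideal helix building, α/π assignment, register shifts, pore facing."""

import math

import numpy as np
import pytest

import porepi.helix_geometry as hg
from porepi.synthetic_data import HelixSpec, build_ideal_helix


def labels_string(ss):
    code = {"pi": "P", "alpha": "A", "coil": "c"}
    return "".join(code[ss.labels[n]] for n in sorted(ss.labels))


def place_on_pore_wall(backbone, distance=10.0, inward_residue=1):
    """Rotate about the helix (z) axis so the chosen residue's Cβ points at
    the pore axis, then shift the helix distance Å along +x."""
    r = backbone.residues[inward_residue - 1]
    cb = hg.reconstruct_cbeta(r.atoms["N"], r.atoms["CA"], r.atoms["C"])
    v = cb - r.atoms["CA"]
    th = math.pi - math.atan2(v[1], v[0])
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return backbone.transformed(rotation=R,
                                translation=np.array([distance, 0.0, 0.0]))


class TestBuilderGeometry:
    def test_alpha_rise_per_residue(self):
        bb = build_ideal_helix(HelixSpec("A" * 30, "A" * 30))
        rise = np.mean(np.diff(bb.coords("CA")[:, 2]))
        assert rise == pytest.approx(1.5, abs=0.08)

    def test_pi_rise_per_residue(self):
        bb = build_ideal_helix(HelixSpec("A" * 30, "P" * 30))
        rise = np.mean(np.diff(bb.coords("CA")[:, 2]))
        assert rise == pytest.approx(1.15, abs=0.08)

    def test_residues_per_turn(self):
        for ss, target, tol in (("A", 3.6, 0.15), ("P", 4.4, 0.35)):
            bb = build_ideal_helix(HelixSpec("A" * 30, ss * 30))
            ca = bb.coords("CA")
            ang = np.unwrap(np.arctan2(ca[:, 1], ca[:, 0]))
            twist = abs(np.degrees(np.mean(np.diff(ang))))
            assert 360.0 / twist == pytest.approx(target, abs=tol)

    def test_numbering_and_subunit_follow_spec(self):
        bb = build_ideal_helix(HelixSpec("AILV" * 5, "A" * 20,
                                         first_residue_number=405,
                                         subunit_label="DI"))
        assert bb.numbers()[0] == 405 and bb.numbers()[-1] == 424
        assert bb.residues[0].subunit_label == "DI"


class TestAssignmentRoundTrip:
    @pytest.mark.parametrize("ss_string", [
        "A" * 30,
        "A" * 9 + "P" * 6 + "A" * 15,   # the canonical interior stretch
        "A" * 4 + "P" * 5 + "A" * 21,
        "A" * 14 + "P" * 7 + "A" * 9,
        "P" * 6 + "A" * 24,
        "AAPPPPPAAAAAAAAPPPPPAAAAAAAAAA",
    ])
    def test_interior_round_trip_exact(self, ss_string):
        bb = build_ideal_helix(HelixSpec("A" * 30, ss_string))
        assert labels_string(hg.assign_secondary_structure(bb)) == ss_string

    def test_pi_interval_matches_design(self):
        ss_string = "A" * 9 + "P" * 6 + "A" * 15
        bb = build_ideal_helix(HelixSpec("A" * 30, ss_string))
        ss = hg.assign_secondary_structure(bb)
        assert ss.pi_intervals == [(10, 15)]

    def test_terminal_residues_extend_interior_label(self):
        bb = build_ideal_helix(HelixSpec("A" * 30, "A" * 30))
        ss = hg.assign_secondary_structure(bb)
        assert all(v == "alpha" for v in ss.labels.values())

    def test_too_short_chain_rejected(self):
        bb = build_ideal_helix(HelixSpec("A" * 8, "A" * 8))
        bb.residues = bb.residues[:5]
        with pytest.raises(ValueError, match="at least 6"):
            hg.assign_secondary_structure(bb)

    def test_missing_atom_names_residue(self):
        bb = build_ideal_helix(HelixSpec("A" * 8, "A" * 8))
        del bb.residues[3].atoms["O"]
        with pytest.raises(ValueError, match="DI:4.*O"):
            hg.BackboneModel(bb.residues)


class TestPiStretchLocation:
    def _assignment(self, start, end, first=1755, n=30):
        labels = {first + i: "alpha" for i in range(n)}
        for num in range(start, end + 1):
            labels[num] = "pi"
        return hg.SSAssignment(labels=labels, subunit_label="DIV")

    def test_interval_and_anchor(self):
        ss = self._assignment(1762, 1766)
        (hit,) = hg.locate_pi_stretch(ss)
        assert hit == {"start": 1762, "end": 1766, "anchor": 1762}

    def test_one_turn_downward_shift_is_plus_five(self):
        # the DIV-S6 comparison: bulge at F1762 versus at N1767
        a = self._assignment(1762, 1766)
        b = self._assignment(1767, 1771)
        assert hg.pi_stretch_shift(a, b) == 5

    def test_identical_assignments_shift_zero(self):
        a = self._assignment(1762, 1766)
        assert hg.pi_stretch_shift(a, a) == 0

    def test_no_pi_interval_empty(self):
        ss = self._assignment(1762, 1766)
        all_alpha = hg.SSAssignment(
            labels={k: "alpha" for k in ss.labels}, subunit_label="DIV")
        assert hg.locate_pi_stretch(all_alpha) == []
        assert hg.pi_stretch_shift(ss, all_alpha) is None


class TestPoreFacing:
    def test_matches_brute_force_angle_scan(self):
        bb = place_on_pore_wall(build_ideal_helix(HelixSpec("A" * 18, "A" * 18)))
        facing = hg.predict_pore_facing(bb)
        got = sorted(facing.facing.get("DI", set()))
        oracle = []
        for r in bb.residues:
            cb = hg.reconstruct_cbeta(r.atoms["N"], r.atoms["CA"], r.atoms["C"])
            ca = r.atoms["CA"]
            inward = np.array([-ca[0], -ca[1], 0.0])
            u = (cb - ca) / np.linalg.norm(cb - ca)
            w = inward / np.linalg.norm(inward)
            ang = math.degrees(math.acos(np.clip(np.dot(u, w), -1, 1)))
            if ang <= 60.0:
                oracle.append(r.number)
        assert got == oracle
        assert got[0] == 1  # phased so residue 1 faces the pore
        gaps = np.diff(got)
        assert set(gaps) <= {3, 4}  # i, i+3/i+4 helical lattice

    def test_half_turn_rotation_gives_disjoint_set(self):
        bb = build_ideal_helix(HelixSpec("A" * 18, "A" * 18))
        Rpi = np.diag([-1.0, -1.0, 1.0])  # 180 deg about the helix axis
        a = place_on_pore_wall(bb)
        b = place_on_pore_wall(bb.transformed(rotation=Rpi), inward_residue=1)
        sa = hg.predict_pore_facing(a).facing.get("DI", set())
        # placing without re-phasing: rotate the placed helix itself
        b = a.transformed(rotation=Rpi)
        b = b.transformed(translation=np.array([20.0, 0.0, 0.0]))
        sb = hg.predict_pore_facing(b).facing.get("DI", set())
        assert sa and sb and not (sa & sb)

    def test_glycine_uses_ideal_cbeta_placeholder(self):
        bb = place_on_pore_wall(build_ideal_helix(HelixSpec("G" * 18, "A" * 18)))
        facing = hg.predict_pore_facing(bb)
        assert facing.facing.get("DI")  # no crash, non-empty set

    def test_degenerate_axis_rejected(self):
        bb = build_ideal_helix(HelixSpec("A" * 10, "A" * 10))
        with pytest.raises(ValueError, match="degenerate"):
            hg.predict_pore_facing(bb, axis_dir=(0.0, 0.0, 0.0))


class TestRegisterShift:
    @pytest.mark.parametrize("alpha_facing,bulge,pi_facing", [
        ({409, 413}, 405, {410, 414}),      # DI:  I409/V413 -> L410/A414
        ({937, 941}, 930, {938, 942}),      # DII: F937/I941 -> I938/I942
        ({1766, 1770}, 1760, {1767, 1771}),  # DIV: V1766/I1770 -> N1767/A1771
    ])
    def test_s6_register_shift_worked_examples(self, alpha_facing, bulge,
                                               pi_facing):
        assert hg.register_shift_map(alpha_facing, bulge) == pi_facing

    def test_residues_before_bulge_unchanged(self):
        assert hg.register_shift_map({100, 200}, 150) == {100, 201}

    def test_inverse_shift_restores_alpha_set(self):
        shifted = hg.register_shift_map({409, 413}, 405)
        assert hg.register_shift_map(shifted, 405, shift=-1) == {409, 413}

    def test_works_on_pore_facing_set(self):
        pfs = hg.PoreFacingSet({"DIV": {1766, 1770}})
        out = hg.register_shift_map(pfs, 1760)
        assert out.facing == {"DIV": {1767, 1771}}


class TestPdbRoundTrip:
    def test_write_read_reassign(self, tmp_path):
        ss_string = "A" * 9 + "P" * 6 + "A" * 15
        bb = build_ideal_helix(HelixSpec("A" * 30, ss_string,
                                         first_residue_number=401,
                                         subunit_label="D"))
        p = tmp_path / "helix.pdb"
        hg.write_pdb_backbone(bb, p)
        back = hg.read_pdb_backbone(p, chain="D")
        assert back.numbers() == bb.numbers()
        assert labels_string(hg.assign_secondary_structure(back)) == ss_string
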