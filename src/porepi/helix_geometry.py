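"""α/π secondary-structure geometry for pore-lining helices.

A π-helix hydrogen-bonds its carbonyl O(i) to the amide N(i+5) (~4.4
residues/turn, ~1.15 Å rise/residue) where an α-helix bonds O(i)···N(i+4)
(~3.6 residues/turn, ~1.5 Å rise).  The one-residue "bulge" of a π stretch
rotates every downstream side chain's register, which is how a π insertion
in an S6 helix swaps the pore-facing residue set.  This module builds ideal
mixed α/π backbones, assigns labels from a geometric H-bond criterion,
locates π stretches and their register shifts, and predicts pore-facing
residues from reconstructed Cβ directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Residue",
    "BackboneModel",
    "SSAssignment",
    "PoreFacingSet",
    "build_helix_backbone",
    "assign_secondary_structure",
    "locate_pi_stretch",
    "pi_stretch_shift",
    "predict_pore_facing",
    "register_shift_map",
    "reconstruct_cbeta",
    "read_pdb_backbone",
    "write_pdb_backbone",
]

# Ideal backbone covalent geometry (bond lengths Å, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_OMEGA = 180.0

# Backbone dihedrals tuned numerically so the ideal-geometry chains hit the
# canonical helical parameters: α → 1.50 Å rise, ~3.7 res/turn; π → 1.15 Å
# rise, ~4.1 res/turn (with i→i+4 resp. i→i+5 carbonyl-amide H-bonds).
_ALPHA_PHI, _ALPHA_PSI = -62.0, -45.0
_PI_PHI, _PI_PSI = -56.5, -66.0

# Geometric H-bond criterion: O(i)···N(i+k) distance and C=O···N angle
HBOND_MAX_DIST = 3.5   # Å
HBOND_MIN_ANGLE = 120.0  # deg


@dataclass
class Residue:
    number: int
    amino_acid: str
    subunit_label: str
    atoms: dict  # name -> np.ndarray(3), requires N, CA, C, O


@dataclass
class BackboneModel:
    """Ordered backbone residues of one (or more) helices."""

    residues: list
    source: str = "ideal"  # "ideal" | "PDB"

    def __post_init__(self):
        by_subunit: dict[str, int] = {}
        for r in self.residues:
            for name in ("N", "CA", "C", "O"):
                if name not in r.atoms:
                    raise ValueError(
                        f"residue {r.subunit_label}:{r.number} is missing "
                        f"backbone atom {name}"
                    )
            prev = by_subunit.get(r.subunit_label)
            if prev is not None and r.number <= prev:
                raise ValueError(
                    f"residue numbering not strictly increasing in "
                    f"{r.subunit_label} at {r.number}"
                )
            by_subunit[r.subunit_label] = r.number

    def __len__(self):
        return len(self.residues)

    def coords(self, atom: str) -> np.ndarray:
        return np.array([r.atoms[atom] for r in self.residues])

    def numbers(self) -> list:
        return [r.number for r in self.residues]

    def helix_axis(self):
        """(origin, unit direction) from the principal axis of the Cα trace,
        oriented from the first toward the last residue."""
        ca = self.coords("CA")
        center = ca.mean(axis=0)
        _, _, vt = np.linalg.svd(ca - center)
        axis = vt[0]
        if np.dot(axis, ca[-1] - ca[0]) < 0:
            axis = -axis
        return center, axis

    def transformed(self, rotation=None, translation=None) -> "BackboneModel":
        R = np.eye(3) if rotation is None else np.asarray(rotation)
        t = np.zeros(3) if translation is None else np.asarray(translation)
        res = [
            Residue(r.number, r.amino_acid, r.subunit_label,
                    {k: R @ v + t for k, v in r.atoms.items()})
            for r in self.residues
        ]
        return BackboneModel(res, source=self.source)


@dataclass
class SSAssignment:
    """Per-residue secondary-structure labels with π intervals."""

    labels: dict            # residue number -> "alpha" | "pi" | "coil"
    subunit_label: str = "DI"
    pi_intervals: list = field(default_factory=list)  # [(start, end), ...]

    def __post_init__(self):
        if not self.pi_intervals:
            self.pi_intervals = _runs(self.labels, "pi")


def _runs(labels: dict, target: str):
    nums = sorted(labels)
    runs, start, prev = [], None, None
    for n in nums:
        if labels[n] == target and (prev is None or n != prev + 1 or start is None):
            if start is not None:
                runs.append((start, prev))
            start = n
        elif labels[n] != target and start is not None:
            runs.append((start, prev))
            start = None
        prev = n
    if start is not None:
        runs.append((start, prev))
    return runs


@dataclass
class PoreFacingSet:
    """Residue numbers facing the pore axis, per subunit."""

    facing: dict  # subunit label -> set of residue numbers


# ---------------------------------------------------------------------------
# vector helpers

def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate (zero-length) vector")
    return v / n


def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension placement: position D with |CD| = bond, angle
    B-C-D = angle and dihedral A-B-C-D = torsion."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return math.degrees(math.atan2(y, x))


def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u, v = _unit(a - b), _unit(c - b)
    return math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))


# ---------------------------------------------------------------------------
# builder

def build_helix_backbone(spec) -> BackboneModel:
    """Build an ideal mixed α/π backbone from a HelixSpec.

    The N/Cα/C trace follows ideal covalent geometry with per-residue
    (φ, ψ) chosen by the design string; each carbonyl O is then pointed at
    its intended acceptor N(i+4) (α) or N(i+5) (π), which makes the
    geometric assignment a round trip on interior residues.  The result is
    centered on the origin and aligned with +z.
    """
    n_res = len(spec.sequence)
    # The O(i)→N(i+k) span of a donor is shaped by the dihedrals of the
    # residues between donor and acceptor, so π backbone geometry must
    # extend a few residues past the designed stretch for the acceptor to
    # sit in H-bond range; the designed string still decides each O target.
    ext = 3
    use_pi = [
        "P" in spec.ss_string[max(0, j - ext): j + 1] for j in range(n_res)
    ]
    phi = [(_PI_PHI if p else _ALPHA_PHI) for p in use_pi]
    psi = [(_PI_PSI if p else _ALPHA_PSI) for p in use_pi]

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N,
                            psi[i - 1]))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA,
                             _OMEGA))
        C.append(place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i]))

    O: list = [None] * n_res
    last_real = None
    for i in range(n_res):
        k = 4 if spec.ss_string[i] == "A" else 5
        if i + k < n_res:
            O[i] = C[i] + _B_C_O * _unit(N[i + k] - C[i])
            last_real = i
    for i in range(n_res):
        if O[i] is not None:
            continue
        if last_real is not None:
            # terminal carbonyl: reuse the local-frame orientation of the
            # last carbonyl with a real acceptor, so a terminal O keeps the
            # designed helical direction instead of faking another pattern
            j = last_real
            coeffs = _residue_frame(N[j], CA[j], C[j]).T @ (O[j] - C[j])
            O[i] = C[i] + _residue_frame(N[i], CA[i], C[i]) @ coeffs
        else:
            ref = N[i + 1] if i + 1 < n_res else N[i]
            direction = _unit(np.cross(np.cross(CA[i] - C[i], ref - C[i]),
                                       CA[i] - C[i]))
            O[i] = C[i] - _B_C_O * direction

    residues = [
        Residue(spec.first_residue_number + i, spec.sequence[i],
                spec.subunit_label,
                {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]})
        for i in range(n_res)
    ]
    model = BackboneModel(residues, source="ideal")
    origin, axis = model.helix_axis()
    R = _rotation_onto(axis, np.array([0.0, 0.0, 1.0]))
    return model.transformed(rotation=R, translation=-R @ origin)


def _residue_frame(n, ca, c):
    """Orthonormal local frame (columns) anchored on a residue's backbone."""
    e1 = _unit(c - ca)
    v = n - ca
    e2 = _unit(v - np.dot(v, e1) * e1)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _rotation_onto(u, v):
    """Rotation matrix taking unit vector u onto unit vector v."""
    u, v = _unit(np.asarray(u, float)), _unit(np.asarray(v, float))
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis for the half-turn
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        k = _unit(np.cross(u, p))
    else:
        k = _unit(np.cross(u, v))
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    s = math.sqrt(max(0.0, 1 - c * c))
    return np.eye(3) + s * K + (1 - c) * (K @ K)


# ---------------------------------------------------------------------------
# assignment

def _hbond(backbone, i, j) -> bool:
    """Geometric backbone H-bond test: O(i)···N(j) distance + C=O···N angle."""
    ri, rj = backbone.residues[i], backbone.residues[j]
    o, c, n = ri.atoms["O"], ri.atoms["C"], rj.atoms["N"]
    if np.linalg.norm(n - o) > HBOND_MAX_DIST:
        return False
    return _angle(c, o, n) >= HBOND_MIN_ANGLE


def assign_secondary_structure(backbone: BackboneModel) -> SSAssignment:
    """Label residues α, π or coil from the backbone geometry.

    Residue i is π if O(i)···N(i+5) forms an H-bond (distance ≤ 3.5 Å,
    C=O···N angle ≥ 120°), else α if O(i)···N(i+4) does; π takes precedence.
    Trailing residues whose acceptor would fall past the chain inherit the
    label of the adjacent interior residue.
    """
    n = len(backbone)
    if n < 6:
        raise ValueError("need at least 6 residues to assign helical H-bonds")
    labels = {}
    nums = backbone.numbers()
    last_interior = None
    for i in range(n):
        if i + 5 < n and _hbond(backbone, i, i + 5):
            lab = "pi"
        elif i + 4 < n and _hbond(backbone, i, i + 4):
            lab = "alpha"
        elif i + 5 >= n:
            # terminal: the (remaining) acceptor falls past the chain, so
            # the pattern cannot be decided; extend the interior label
            lab = None
        else:
            lab = "coil"
        labels[nums[i]] = lab
        if lab not in (None, "coil"):
            last_interior = lab
    for i in range(n):
        if labels[nums[i]] is None:
            labels[nums[i]] = last_interior or "coil"
    sub = backbone.residues[0].subunit_label
    return SSAssignment(labels=labels, subunit_label=sub)


def locate_pi_stretch(ss: SSAssignment, subunit: str | None = None):
    """π intervals with their anchor (first bulged) residue.

    Returns a list of dicts: {"start", "end", "anchor"}; the anchor is the
    residue at which the bulge begins (interval start).
    """
    if subunit is not None and subunit != ss.subunit_label:
        return []
    return [{"start": a, "end": b, "anchor": a} for a, b in ss.pi_intervals]


def pi_stretch_shift(ss_a: SSAssignment, ss_b: SSAssignment):
    """Residue shift between the first π stretches of two assignments.

    A result of +5 means the second π stretch starts five residues (one
    α-helical turn) downstream of the first — the pattern seen when the same
    helix is resolved with its π bulge one turn lower.  Returns None if
    either assignment lacks a π stretch.
    """
    a, b = locate_pi_stretch(ss_a), locate_pi_stretch(ss_b)
    if not a or not b:
        return None
    return b[0]["anchor"] - a[0]["anchor"]


# ---------------------------------------------------------------------------
# pore facing

# Cβ reconstruction: ideal tetrahedral geometry off the N/CA/C frame.
_B_CA_CB = 1.53
_A_C_CA_CB = 110.6
_T_N_C_CA_CB = 122.6  # L-amino-acid branch


def reconstruct_cbeta(n, ca, c):
    """Ideal Cβ position from backbone N, Cα, C (works for Gly too)."""
    return place_atom(n, c, ca, _B_CA_CB, _A_C_CA_CB, _T_N_C_CA_CB)


def predict_pore_facing(backbone: BackboneModel, axis_point=(0.0, 0.0, 0.0),
                        axis_dir=(0.0, 0.0, 1.0),
                        max_angle_deg: float = 60.0) -> PoreFacingSet:
    """Residues whose Cα→Cβ direction points toward the pore axis.

    A residue faces the pore if the angle between its (reconstructed)
    Cα→Cβ vector and the inward radial direction at its Cα is at most
    ``max_angle_deg``.  Glycines use the same ideal Cβ placeholder.
    """
    axis_point = np.asarray(axis_point, float)
    axis_dir = np.asarray(axis_dir, float)
    if np.linalg.norm(axis_dir) < 1e-9:
        raise ValueError("degenerate pore axis direction")
    axis_dir = _unit(axis_dir)
    facing: dict[str, set] = {}
    for r in backbone.residues:
        ca = r.atoms["CA"]
        cb = r.atoms.get("CB")
        if cb is None:
            cb = reconstruct_cbeta(r.atoms["N"], ca, r.atoms["C"])
        rel = axis_point - ca
        inward = rel - np.dot(rel, axis_dir) * axis_dir
        if np.linalg.norm(inward) < 1e-9:
            continue  # residue sits on the axis; direction undefined
        ang = _angle(cb, ca, ca + inward)
        if ang <= max_angle_deg:
            facing.setdefault(r.subunit_label, set()).add(r.number)
    return PoreFacingSet(facing=facing)


def register_shift_map(facing, bulge_start: int, shift: int = 1):
    """Map an α-helix pore-facing set to its π-helix counterpart.

    Inserting a π bulge at ``bulge_start`` rotates every downstream residue
    by one position: residues numbered below the bulge keep their facing;
    residues at or past it advance by ``shift`` (+1 for α→π; −1 inverts).
    This reproduces the S6 swaps I409/V413→L410/A414 (DI), F937/I941→
    I938/I942 (DII) and V1766/I1770→N1767/A1771 (DIV) — the last rotating
    the conserved Asn toward the pore.
    """
    def shift_set(s):
        return {r if r < bulge_start else r + shift for r in s}

    if isinstance(facing, PoreFacingSet):
        return PoreFacingSet({k: shift_set(v) for k, v in facing.facing.items()})
    return shift_set(set(facing))


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)

def read_pdb_backbone(path, chain: str | None = None,
                      subunit_label: str | None = None) -> BackboneModel:
    """Read backbone (N, CA, C, O) residues from a PDB file (first model)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]
    residues = []
    for res_id in np.unique(atoms.res_id):
        sel = atoms[atoms.res_id == res_id]
        rec = {}
        for name in ("N", "CA", "C", "O", "CB"):
            hit = sel[sel.atom_name == name]
            if len(hit):
                rec[name] = np.asarray(hit.coord[0], dtype=float)
        if all(k in rec for k in ("N", "CA", "C", "O")):
            residues.append(Residue(int(res_id), str(sel.res_name[0]),
                                    subunit_label or (chain or "A"), rec))
    if not residues:
        raise ValueError(f"{path}: no complete backbone residues found")
    return BackboneModel(residues, source="PDB")


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_pdb_backbone(backbone: BackboneModel, path) -> None:
    """Write the backbone as a standard PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = sum(len([k for k in r.atoms if k in ("N", "CA", "C", "O", "CB")])
                  for r in backbone.residues)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for r in backbone.residues:
        res3 = _AA3.get(r.amino_acid.upper(), r.amino_acid.upper()[:3] or "UNK")
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in r.atoms:
                continue
            arr.coord[i] = r.atoms[name]
            arr.chain_id[i] = (r.subunit_label or "A")[:1]
            arr.res_id[i] = r.number
            arr.res_name[i] = res3
            arr.atom_name[i] = name
            arr.element[i] = name[0]
            i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
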