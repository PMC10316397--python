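"""Desk-scale stand-ins for channel MD systems.

The generator produces Brownian-dynamics trajectories of cations in a
cylindrical pore: ions drift-diffuse along the pore axis (z) under a
configurable potential of mean force plus a uniform field equivalent to a
transmembrane voltage, while water particles are resampled each frame from
the occupancy implied by a tunable dewetting gate.  Ideal α/π helix
backbones for the secondary-structure analyses are built in
:mod:`porepi.helix_geometry` and re-exported here as :func:`build_ideal_helix`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from ._units import EV_TO_KCAL_PER_MOL, thermal_energy

__all__ = [
    "GaussianTerm",
    "PoreSystemSpec",
    "Trajectory",
    "HelixSpec",
    "simulate_pore",
    "build_ideal_helix",
    "pmf_energy",
    "pmf_force",
]

_PMF_GRID_SIZE = 4096


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian component of the axial PMF.

    height : kcal/mol (positive = barrier, negative = well)
    center : Å
    width  : Å (Gaussian sigma)
    """

    height: float
    center: float
    width: float

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError(f"PMF Gaussian width must be > 0, got {self.width}")


@dataclass(frozen=True)
class PoreSystemSpec:
    """Full parameterization of one synthetic pore system.

    Units: Å, ps, kcal/mol, K, elementary charges, volts.  ``voltage`` is the
    potential difference across the box height Lz (extracellular side = +z);
    ``dewetting_factor`` interpolates the gate water occupancy between
    bulk-like (0) and fully dewetted (1).
    """

    box_lengths: tuple[float, float, float] = (30.0, 30.0, 80.0)
    pore_radius: float = 5.0
    gate_region: tuple[float, float] = (-10.0, 10.0)
    pmf_terms: tuple[GaussianTerm, ...] = ()
    voltage: float = 0.0
    n_ions: int = 10
    ion_charge: float = 1.0
    diffusion_coeff: float = 0.02
    temperature: float = 300.0
    n_waters: int = 200
    dewetting_factor: float = 0.0
    dt: float = 1.0
    n_steps: int = 100_000
    frame_stride: int = 100
    seed: int = 0

    def __post_init__(self):
        lx, ly, lz = self.box_lengths
        if min(lx, ly, lz) <= 0:
            raise ValueError("box_lengths must be positive")
        z_low, z_high = self.gate_region
        if not z_low < z_high:
            raise ValueError("gate_region must satisfy z_low < z_high")
        if z_low < -lz / 2 or z_high > lz / 2:
            raise ValueError("gate_region must lie inside the box")
        if not self.pore_radius > 0:
            raise ValueError("pore_radius must be > 0")
        if not self.diffusion_coeff > 0:
            raise ValueError("diffusion_coeff must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not 0.0 <= self.dewetting_factor <= 1.0:
            raise ValueError("dewetting_factor must be in [0, 1]")
        if self.n_steps < 1 or self.frame_stride < 1:
            raise ValueError("n_steps and frame_stride must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        object.__setattr__(
            self, "pmf_terms",
            tuple(t if isinstance(t, GaussianTerm) else GaussianTerm(*t)
                  for t in self.pmf_terms),
        )

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def Lz(self) -> float:
        return self.box_lengths[2]

    def replace(self, **kwargs) -> "PoreSystemSpec":
        d = asdict(self)
        d["pmf_terms"] = tuple((t.height, t.center, t.width) for t in self.pmf_terms)
        d.update(kwargs)
        d["box_lengths"] = tuple(d["box_lengths"])
        d["gate_region"] = tuple(d["gate_region"])
        return PoreSystemSpec(**d)

    def fingerprint(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class Trajectory:
    """Frames of labeled particles in a periodic box.

    coords has shape (n_frames, n_particles, 3); particle identity and
    species are constant across frames.  Coordinates are wrapped: z lies in
    [-Lz/2, Lz/2).
    """

    times: np.ndarray          # (n_frames,) ps
    box: np.ndarray            # (3,) Å
    ids: np.ndarray            # (n_particles,) int
    species: np.ndarray        # (n_particles,) str in {ion, water, backbone}
    coords: np.ndarray         # (n_frames, n_particles, 3) Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.ids = np.asarray(self.ids)
        self.species = np.asarray(self.species)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if len(self.ids) != self.coords.shape[1] or len(self.species) != self.coords.shape[1]:
            raise ValueError("ids/species and coords disagree on particle count")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def select(self, species: str) -> np.ndarray:
        """Column indices of the given species."""
        return np.flatnonzero(self.species == species)

    def z(self, species: str | None = None) -> np.ndarray:
        """Axial coordinates, shape (n_frames, n_selected)."""
        if species is None:
            return self.coords[:, :, 2]
        return self.coords[:, self.select(species), 2]


@dataclass(frozen=True)
class HelixSpec:
    """An S6-like helix: sequence plus per-residue α/π design string.

    ss_string uses 'A' for α and 'P' for π; subunit_label follows the
    channel's DI–DIV convention.
    """

    sequence: str
    ss_string: str
    first_residue_number: int = 1
    subunit_label: str = "DI"

    def __post_init__(self):
        if len(self.sequence) != len(self.ss_string):
            raise ValueError("sequence and ss_string must have equal length")
        if set(self.ss_string) - {"A", "P"}:
            raise ValueError("ss_string may only contain 'A' (alpha) and 'P' (pi)")


# ---------------------------------------------------------------------------
# PMF evaluation

def _minimum_image(dz, period):
    return dz - period * np.round(dz / period)


def pmf_energy(z, terms: Sequence[GaussianTerm], period: float):
    """U(z) in kcal/mol, summing each Gaussian over its ±1 periodic images."""
    z = np.asarray(z, dtype=float)
    u = np.zeros_like(z)
    for t in terms:
        for k in (-1.0, 0.0, 1.0):
            d = z - (t.center + k * period)
            u += t.height * np.exp(-0.5 * (d / t.width) ** 2)
    return u


def pmf_force(z, terms: Sequence[GaussianTerm], period: float):
    """F(z) = -dU/dz in kcal/mol/Å."""
    z = np.asarray(z, dtype=float)
    f = np.zeros_like(z)
    for t in terms:
        for k in (-1.0, 0.0, 1.0):
            d = z - (t.center + k * period)
            f += t.height * d / t.width**2 * np.exp(-0.5 * (d / t.width) ** 2)
    return f


def _pmf_force_table(spec: PoreSystemSpec):
    """Tabulated total axial force (PMF + voltage) on the ion, plus grid step."""
    lz = spec.Lz
    grid = -lz / 2 + lz * np.arange(_PMF_GRID_SIZE) / _PMF_GRID_SIZE
    dz_grid = lz / _PMF_GRID_SIZE
    for t in spec.pmf_terms:
        if t.width < 2 * dz_grid:
            raise ValueError(
                f"PMF width {t.width} Å too small versus force-grid spacing "
                f"{dz_grid:.4f} Å; force would be under-resolved"
            )
    f = pmf_force(grid, spec.pmf_terms, lz)
    # constant-field force on a cation: F = -q dphi/dz, phi(z) = V*z/Lz
    f_volt = -spec.ion_charge * spec.voltage * EV_TO_KCAL_PER_MOL / lz
    f = f + f_volt
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite PMF force on the integration grid")
    mobility = spec.diffusion_coeff / spec.kT
    max_drift = float(np.max(np.abs(f))) * mobility * spec.dt
    if max_drift > lz / 10:
        raise ValueError(
            f"dt too large: max drift step {max_drift:.2f} Å exceeds Lz/10 = "
            f"{lz / 10:.2f} Å; reduce dt or smooth the PMF"
        )
    return f, dz_grid


def _sample_disk(rng, n, radius):
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    return r * np.cos(phi), r * np.sin(phi)


def _sample_water_frame(rng, spec: PoreSystemSpec):
    """One frame of water positions from the dewetting-gate occupancy."""
    z_low, z_high = spec.gate_region
    lz = spec.Lz
    gate_len = z_high - z_low
    out_len = lz - gate_len
    w_gate = (1.0 - spec.dewetting_factor) * gate_len
    p_gate = w_gate / (w_gate + out_len) if (w_gate + out_len) > 0 else 0.0
    in_gate = rng.uniform(size=spec.n_waters) < p_gate
    z = np.empty(spec.n_waters)
    n_gate = int(in_gate.sum())
    z[in_gate] = rng.uniform(z_low, z_high, size=n_gate)
    # outside region is contiguous modulo the period: [z_high, z_low + Lz)
    z_out = rng.uniform(z_high, z_low + lz, size=spec.n_waters - n_gate)
    z[~in_gate] = _minimum_image(z_out, lz)
    x, y = _sample_disk(rng, spec.n_waters, spec.pore_radius)
    return np.column_stack([x, y, z])


def simulate_pore(spec: PoreSystemSpec, replicate_id: int = 0) -> Trajectory:
    """Run overdamped Langevin dynamics of the ions and resample waters.

    Ions obey dz = (D/kT) F(z) dt + sqrt(2 D dt) η with F the tabulated PMF
    force plus the constant-field voltage term; x, y diffuse freely but steps
    leaving the pore cylinder are resampled (rejection), and z is periodic
    over Lz.  Waters are redrawn independently each stored frame from the
    gate-occupancy distribution.  Deterministic for a given (seed,
    replicate_id) pair.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, replicate_id]))
    lz = spec.Lz
    f_table, _ = _pmf_force_table(spec)
    mobility_dt = spec.diffusion_coeff / spec.kT * spec.dt
    noise_scale = np.sqrt(2.0 * spec.diffusion_coeff * spec.dt)
    n_ions = spec.n_ions
    r2_max = spec.pore_radius**2

    z = rng.uniform(-lz / 2, lz / 2, size=n_ions)
    x, y = _sample_disk(rng, n_ions, spec.pore_radius)

    frame_steps = list(range(0, spec.n_steps + 1, spec.frame_stride))
    n_frames = len(frame_steps)
    n_particles = n_ions + spec.n_waters
    coords = np.empty((n_frames, n_particles, 3))
    times = np.array([s * spec.dt for s in frame_steps], dtype=float)

    def store(frame_idx):
        coords[frame_idx, :n_ions, 0] = x
        coords[frame_idx, :n_ions, 1] = y
        coords[frame_idx, :n_ions, 2] = z
        if spec.n_waters:
            coords[frame_idx, n_ions:, :] = _sample_water_frame(rng, spec)

    store(0)
    next_frame = 1
    # pre-generated noise blocks keep the step loop cheap
    zeta = rng.standard_normal((spec.n_steps, n_ions))
    xi = rng.standard_normal((spec.n_steps, n_ions, 2))
    scale_idx = _PMF_GRID_SIZE / lz
    for step in range(spec.n_steps):
        idx = ((z + lz / 2) * scale_idx).astype(np.intp) % _PMF_GRID_SIZE
        z = z + mobility_dt * f_table[idx] + noise_scale * zeta[step]
        z = _minimum_image(z, lz)
        # radial rejection: redraw offending xy steps, keep old position if
        # a few retries fail (preserves axial statistics either way)
        dx = noise_scale * xi[step, :, 0]
        dy = noise_scale * xi[step, :, 1]
        xn, yn = x + dx, y + dy
        bad = xn * xn + yn * yn > r2_max
        tries = 0
        while np.any(bad) and tries < 8:
            nb = int(bad.sum())
            xn[bad] = x[bad] + noise_scale * rng.standard_normal(nb)
            yn[bad] = y[bad] + noise_scale * rng.standard_normal(nb)
            bad = xn * xn + yn * yn > r2_max
            tries += 1
        xn[bad] = x[bad]
        yn[bad] = y[bad]
        x, y = xn, yn
        if next_frame < n_frames and step + 1 == frame_steps[next_frame]:
            store(next_frame)
            next_frame += 1

    ids = np.arange(n_particles)
    species = np.array(["ion"] * n_ions + ["water"] * spec.n_waters)
    meta = {
        "replicate_id": replicate_id,
        "seed": spec.seed,
        "spec_fingerprint": spec.fingerprint(),
        "temperature": spec.temperature,
        "kT": spec.kT,
        "voltage": spec.voltage,
        "ion_charge": spec.ion_charge,
        "gate_region": list(spec.gate_region),
        "pore_radius": spec.pore_radius,
        "dewetting_factor": spec.dewetting_factor,
        "diffusion_coeff": spec.diffusion_coeff,
    }
    return Trajectory(times=times, box=np.array(spec.box_lengths), ids=ids,
                      species=species, coords=coords, metadata=meta)


def build_ideal_helix(spec: HelixSpec):
    """Build an ideal backbone (N, Cα, C, O per residue) for the helix spec.

    α residues are placed with ~3.6 residues/turn and ~1.5 Å rise; π
    residues with ~4.4 residues/turn and ~1.15 Å rise.  Carbonyl oxygens
    point at the i+4 (α) or i+5 (π) amide nitrogen so that the geometric
    H-bond criterion in :mod:`porepi.helix_geometry` recovers the designed
    labels on interior residues.  Returns a
    :class:`porepi.helix_geometry.BackboneModel` aligned to the z axis.
    """
    from .helix_geometry import build_helix_backbone

    return build_helix_backbone(spec)
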