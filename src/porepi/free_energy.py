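"""Well-tempered metadynamics on the axial ion coordinate.

A single tagged ion diffuses in the pore while Gaussian hills are deposited
along its z coordinate every ``deposition_stride`` steps, with heights
tempered by exp(−V_bias/((γ−1) kT)).  The converged free energy follows the
standard well-tempered estimator F(z) = −γ/(γ−1) · V_bias(z) (min-shifted);
an unbiased Boltzmann-inversion estimate F = −kT ln ρ(z) serves as an
independent cross-check.  Voltage is always zeroed for free-energy runs:
permeation free energy is an equilibrium quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import (PoreSystemSpec, Trajectory, _minimum_image,
                             _pmf_force_table)

__all__ = [
    "MetaDParams",
    "Hill",
    "FreeEnergyProfile",
    "run_wt_metadynamics",
    "reconstruct_free_energy",
    "boltzmann_invert",
    "barrier_height",
    "profile_rmsd",
    "write_hills",
    "read_hills",
]

_BIAS_GRID_SIZE = 2048


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered metadynamics parameters.

    initial_hill_height : w₀, kcal/mol
    hill_width          : σ, Å
    deposition_stride   : steps between hills
    bias_factor         : γ > 1 (γ→∞ recovers standard metadynamics)
    kT                  : kcal/mol (0.596 at 300 K)
    """

    initial_hill_height: float = 0.3
    hill_width: float = 1.0
    deposition_stride: int = 500
    bias_factor: float = 10.0
    kT: float = 0.596

    def __post_init__(self):
        if self.initial_hill_height <= 0:
            raise ValueError("initial hill height must be > 0")
        if self.hill_width <= 0:
            raise ValueError("hill width must be > 0")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.deposition_stride < 1:
            raise ValueError("deposition stride must be >= 1")


@dataclass(frozen=True)
class Hill:
    center: float       # Å
    height: float       # kcal/mol, after tempering
    width: float        # Å
    deposit_step: int


@dataclass
class FreeEnergyProfile:
    """F(z) on a grid, min-shifted so min F = 0; NaN marks unsampled bins."""

    z: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.F = np.asarray(self.F, float)
        if self.z.shape != self.F.shape:
            raise ValueError("z and F must have equal shape")
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - np.min(self.F[finite])


def run_wt_metadynamics(spec: PoreSystemSpec, params: MetaDParams,
                        replicate_id: int = 0):
    """Run biased Langevin dynamics of one CV ion; returns (Trajectory, hills).

    The spec must carry exactly one ion (the collective-variable carrier);
    waters are not propagated.  Any voltage in the spec is zeroed.  The bias
    potential and force are accumulated on a grid; hills use minimum-image
    periodic Gaussians.
    """
    if spec.n_ions != 1:
        raise ValueError("metadynamics runs use a single tagged ion (n_ions=1)")
    spec = spec.replace(voltage=0.0, n_waters=0)
    lz = spec.Lz
    f_pmf, _ = _pmf_force_table(spec)
    ngrid = _BIAS_GRID_SIZE
    grid = -lz / 2 + lz * np.arange(ngrid) / ngrid
    v_bias = np.zeros(ngrid)
    f_bias = np.zeros(ngrid)
    # resample the PMF force on the bias grid for a single lookup table
    pmf_on_grid = f_pmf[((grid + lz / 2) / lz * len(f_pmf)).astype(int) % len(f_pmf)]

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, replicate_id, 7]))
    mobility_dt = spec.diffusion_coeff / spec.kT * spec.dt
    noise = math.sqrt(2.0 * spec.diffusion_coeff * spec.dt)
    gamma = params.bias_factor
    w0 = params.initial_hill_height
    sig = params.hill_width
    denom = (gamma - 1.0) * params.kT

    z = float(rng.uniform(-lz / 2, lz / 2))
    zeta = rng.standard_normal(spec.n_steps)
    scale_idx = ngrid / lz
    half = lz / 2

    frame_steps = set(range(0, spec.n_steps + 1, spec.frame_stride))
    times, zs = [0.0], [z]
    hills: list[Hill] = []
    stride = params.deposition_stride
    for step in range(spec.n_steps):
        i = int((z + half) * scale_idx) % ngrid
        z += mobility_dt * (pmf_on_grid[i] + f_bias[i]) + noise * zeta[step]
        z -= lz * round(z / lz)
        if (step + 1) % stride == 0:
            i = int((z + half) * scale_idx) % ngrid
            v_here = v_bias[i]
            if not math.isfinite(v_here):
                raise FloatingPointError("non-finite bias potential")
            w = w0 * math.exp(-v_here / denom)
            d = _minimum_image(grid - z, lz)
            g = np.exp(-0.5 * (d / sig) ** 2)
            v_bias += w * g
            f_bias += w * d / sig**2 * g
            hills.append(Hill(center=z, height=w, width=sig,
                              deposit_step=step + 1))
        if (step + 1) in frame_steps:
            times.append((step + 1) * spec.dt)
            zs.append(z)

    coords = np.zeros((len(times), 1, 3))
    coords[:, 0, 2] = zs
    traj = Trajectory(
        times=np.array(times), box=np.array(spec.box_lengths),
        ids=np.array([0]), species=np.array(["ion"]), coords=coords,
        metadata={
            "replicate_id": replicate_id, "seed": spec.seed,
            "spec_fingerprint": spec.fingerprint(), "kT": spec.kT,
            "temperature": spec.temperature, "voltage": 0.0,
            "biased": True, "bias_factor": gamma,
        },
    )
    return traj, hills


def reconstruct_free_energy(hills, z_grid, bias_factor: float, period: float,
                            time_average: float = 0.0) -> FreeEnergyProfile:
    """F(z) = −γ/(γ−1) · V_bias(z) from the deposited hills (min-shifted).

    ``time_average`` > 0 averages the instantaneous estimate over the last
    fraction of deposition times instead of using only the final bias — a
    standard variance reduction that damps the hill-deposition ripple.
    Equivalent to down-weighting hill j by the fraction of averaged times
    it has been present for.
    """
    if not hills:
        raise ValueError("empty hill list: nothing to reconstruct")
    if not 0.0 <= time_average < 1.0:
        raise ValueError("time_average must be in [0, 1)")
    z_grid = np.asarray(z_grid, float)
    v = np.zeros_like(z_grid)
    m = len(hills)
    m0 = int(m * (1.0 - time_average))
    for j, h in enumerate(hills):
        w = 1.0 if j < m0 or m == m0 else (m - j) / (m - m0)
        d = _minimum_image(z_grid - h.center, period)
        v += w * h.height * np.exp(-0.5 * (d / h.width) ** 2)
    F = -bias_factor / (bias_factor - 1.0) * v
    return FreeEnergyProfile(z=z_grid, F=F)


def boltzmann_invert(traj: Trajectory, z_grid, kT: float | None = None) -> FreeEnergyProfile:
    """Histogram-based F(z) = −kT ln ρ(z) from an unbiased trajectory.

    Requires a voltage-free, bias-free trajectory; empty bins come back as
    NaN.  Warns when fewer than 10⁴ samples are available (noisy estimate).
    """
    if traj.metadata.get("biased"):
        raise ValueError("Boltzmann inversion requires an unbiased trajectory")
    if traj.metadata.get("voltage", 0.0) != 0.0:
        raise ValueError("Boltzmann inversion requires a voltage-free trajectory")
    if kT is None:
        kT = traj.metadata.get("kT")
        if kT is None:
            raise ValueError("kT not given and absent from trajectory metadata")
    z_grid = np.asarray(z_grid, float)
    dz = z_grid[1] - z_grid[0]
    edges = np.concatenate([z_grid - dz / 2, [z_grid[-1] + dz / 2]])
    samples = traj.z("ion").ravel()
    if samples.size < 10_000:
        warnings.warn(
            f"only {samples.size} samples for Boltzmann inversion; the "
            "free-energy oracle will be noisy", RuntimeWarning,
        )
    counts, _ = np.histogram(samples, bins=edges)
    with np.errstate(divide="ignore"):
        F = -kT * np.log(counts.astype(float))
    F[counts == 0] = np.nan
    return FreeEnergyProfile(z=z_grid, F=F)


def barrier_height(profile: FreeEnergyProfile, gate_region, reference_region) -> float:
    """ΔF‡ = max F over the gate region − min F over the reference region.

    Invariant under additive shifts of F; clipped at zero from below.
    """
    z = profile.z
    g = (z >= gate_region[0]) & (z <= gate_region[1])
    r = (z >= reference_region[0]) & (z <= reference_region[1])
    if not g.any() or not r.any():
        raise ValueError("gate or reference region contains no grid points")
    gv, rv = profile.F[g], profile.F[r]
    if np.all(np.isnan(gv)) or np.all(np.isnan(rv)):
        raise ValueError("gate or reference region has no sampled bins")
    return max(0.0, float(np.nanmax(gv) - np.nanmin(rv)))


def profile_rmsd(a: FreeEnergyProfile, b: FreeEnergyProfile,
                 z_range=None) -> float:
    """RMSD between two profiles on their shared grid, after removing the
    arbitrary additive offset (mean-aligned over the compared bins)."""
    if a.z.shape != b.z.shape or not np.allclose(a.z, b.z):
        raise ValueError("profiles must share a grid")
    sel = np.isfinite(a.F) & np.isfinite(b.F)
    if z_range is not None:
        sel &= (a.z >= z_range[0]) & (a.z <= z_range[1])
    if not sel.any():
        raise ValueError("no overlapping sampled bins to compare")
    d = a.F[sel] - b.F[sel]
    d = d - d.mean()
    return float(np.sqrt(np.mean(d**2)))


def write_hills(hills, path) -> None:
    """4-column TSV (step, center, height, width), PLUMED-style layout."""
    with open(path, "w") as fh:
        fh.write("#step\tcenter\theight\twidth\n")
        for h in hills:
            fh.write(f"{h.deposit_step}\t{h.center:.6f}\t{h.height:.6f}\t"
                     f"{h.width:.6f}\n")


def read_hills(path):
    hills = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            s, c, h, w = line.split()
            hills.append(Hill(center=float(c), height=float(h), width=float(w),
                              deposit_step=int(s)))
    return hills
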