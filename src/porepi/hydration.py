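"""Axial water-density profiles and gate-hydration classification.

Hydrophobic gating shows up as a drop of the time-averaged water density
around the activation gate to well below the bulk value; a fully dewetted
gate reads zero.  Densities are sampled in a cylinder around the pore (z)
axis and normalized by a bulk reference slab.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import Trajectory
from .permeation import GateDefinition

__all__ = [
    "DensityProfile",
    "HydrationCall",
    "water_density_profile",
    "bulk_density",
    "classify_gate_hydration",
    "DEHYDRATED_THRESHOLD",
    "PARTIAL_THRESHOLD",
]

# normalized-density cutoffs for the qualitative hydration call
DEHYDRATED_THRESHOLD = 0.05
PARTIAL_THRESHOLD = 0.5


@dataclass
class DensityProfile:
    """Time-averaged axial water density ρ(z) in a cylinder."""

    bin_edges: np.ndarray      # (n_bins+1,) Å
    density: np.ndarray        # (n_bins,) waters/Å³
    bulk_density: float        # waters/Å³
    cylinder_radius: float     # Å
    n_frames_averaged: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.density = np.asarray(self.density, float)
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("density length must be len(bin_edges) - 1")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def normalized(self) -> np.ndarray:
        if self.bulk_density <= 0:
            raise ValueError("bulk density must be positive to normalize")
        return self.density / self.bulk_density


@dataclass(frozen=True)
class HydrationCall:
    min_normalized_density: float
    hydration_class: str  # hydrated | partially_dehydrated | dehydrated


def _cylinder_mask(traj: Trajectory, cols, radius: float):
    xy = traj.coords[:, cols, :2]
    return (xy[..., 0] ** 2 + xy[..., 1] ** 2) <= radius**2


def water_density_profile(traj: Trajectory, cylinder_radius: float = 5.0,
                          bin_width: float = 1.0,
                          z_range: tuple[float, float] | None = None,
                          bulk_slab: tuple[float, float] | None = None) -> DensityProfile:
    """Time-averaged water density per axial bin inside the pore cylinder.

    Per-bin density is the mean in-cylinder water count divided by the bin
    volume π r² Δz, averaged over all frames.  ``bulk_slab`` (default: the
    outer quarter of the box on each side) sets the normalization density.
    """
    if cylinder_radius <= 0 or bin_width <= 0:
        raise ValueError("cylinder_radius and bin_width must be > 0")
    if traj.n_frames == 0:
        raise ValueError("trajectory has zero frames")
    lz = float(traj.box[2])
    if z_range is None:
        z_range = (-lz / 2, lz / 2)
    z_lo, z_hi = z_range
    n_bins = max(1, int(round((z_hi - z_lo) / bin_width)))
    edges = np.linspace(z_lo, z_hi, n_bins + 1)

    cols = traj.select("water")
    if cols.size == 0:
        raise ValueError("trajectory contains no water particles")
    z = traj.coords[:, cols, 2]
    mask = _cylinder_mask(traj, cols, cylinder_radius)
    counts, _ = np.histogram(z[mask], bins=edges)
    bin_volume = np.pi * cylinder_radius**2 * (edges[1] - edges[0])
    density = counts / (traj.n_frames * bin_volume)

    if bulk_slab is None:
        half = lz / 2
        rho_bulk = 0.5 * (
            bulk_density(traj, (-half, -half / 2), cylinder_radius)
            + bulk_density(traj, (half / 2, half), cylinder_radius)
        )
    else:
        rho_bulk = bulk_density(traj, bulk_slab, cylinder_radius)
    return DensityProfile(bin_edges=edges, density=density,
                          bulk_density=rho_bulk,
                          cylinder_radius=cylinder_radius,
                          n_frames_averaged=traj.n_frames)


def bulk_density(traj: Trajectory, reference_slab: tuple[float, float],
                 cylinder_radius: float = 5.0) -> float:
    """Mean in-cylinder water density (waters/Å³) within a reference slab.

    The slab should sit away from the gate so it reflects bulk-like
    occupancy.
    """
    z_lo, z_hi = reference_slab
    if not z_lo < z_hi:
        raise ValueError("reference slab requires z_low < z_high")
    cols = traj.select("water")
    if cols.size == 0:
        raise ValueError("trajectory contains no water particles")
    z = traj.coords[:, cols, 2]
    mask = _cylinder_mask(traj, cols, cylinder_radius)
    in_slab = mask & (z >= z_lo) & (z < z_hi)
    volume = np.pi * cylinder_radius**2 * (z_hi - z_lo)
    if volume <= 0:
        raise ValueError("empty reference slab")
    return float(in_slab.sum() / (traj.n_frames * volume))


def classify_gate_hydration(profile: DensityProfile,
                            gate: GateDefinition) -> HydrationCall:
    """Classify gate hydration from the minimum normalized density.

    dehydrated if min < 0.05 of bulk, partially_dehydrated if < 0.5,
    hydrated otherwise.
    """
    mid = profile.z_mid
    sel = (mid >= gate.z_low) & (mid <= gate.z_high)
    if not np.any(sel):
        raise ValueError("gate region contains no profile bins")
    m = float(np.min(profile.normalized[sel]))
    if m < DEHYDRATED_THRESHOLD:
        cls = "dehydrated"
    elif m < PARTIAL_THRESHOLD:
        cls = "partially_dehydrated"
    else:
        cls = "hydrated"
    return HydrationCall(min_normalized_density=m, hydration_class=cls)
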