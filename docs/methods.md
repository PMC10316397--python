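# Methods

This note documents the models, parameters and numerical choices behind
`porepi`, and what the synthetic stand-in does and does not establish.

## Units and constants

Å, ps, kcal/mol, Kelvin, elementary charges, volts. kB = 0.0019872041
kcal/mol/K (kB·300 K = 0.596 kcal/mol); e = 1.602176634×10⁻¹⁹ C; 1 eV =
23.060548 kcal/mol. A voltage V across the box height Lz acts on a charge
q as a uniform axial force q·V·(23.060548)/Lz kcal/mol/Å; with the
extracellular side at +z and V = −0.5 V, cations are pushed toward +z.

## The Brownian pore generator

Ions evolve by overdamped (Euler–Maruyama) Langevin dynamics in z:

    Δz = (D/kT)·F(z)·Δt + √(2DΔt)·η,   F = −dU_pmf/dz + q·e·V/Lz

with U_pmf a sum of Gaussian components evaluated with ±1 periodic images
and tabulated on a 4096-point grid (widths below twice the grid spacing
are rejected; a drift step exceeding Lz/10 is rejected as a too-large Δt).
x, y diffuse freely with steps leaving the pore cylinder resampled
(rejection with a keep-old-position fallback after 8 retries), which
preserves the axial statistics exactly. z is periodic over Lz.

Waters are *resampled* each stored frame, not propagated: the analyses
need occupancy statistics only. Each frame draws `n_waters` positions from
the piecewise-uniform axial density with weight (1 − dewetting_factor)
inside the gate slab and 1 elsewhere, uniform over the pore cross-section.
Water count per frame is therefore exactly `n_waters`, and gate occupancy
is exactly monotone in the dewetting factor in expectation.

Defaults follow MD-toy conventions: Lz = 80 Å, pore radius 5 Å, gate
(−10, +10) Å, D = 0.02 Å²/ps, dt = 1 ps, 10⁵ steps per replicate stored
every 100 steps, six replicates, T = 300 K. All randomness flows from one
integer seed (plus a replicate id) through `numpy`'s `SeedSequence`;
identical spec + seed is bitwise reproducible, and the seed and a spec
fingerprint are embedded in the trajectory metadata and output files.

The generator has no protein degrees of freedom at all: helices enter only
through the separate ideal-backbone builder, and the coupling between π
content, hydration and barrier is imposed by the scenario table (below),
not emergent. This is deliberate — the package tests the *analysis
chain* and the *decision logic*, not channel physics.

## Permeation counting and conductance

An event is a complete traversal of the gate slab. On the unwrapped axial
coordinate the line decomposes into gate images [z_low + kLz, z_high + kLz]
and the outside intervals between them; moving from outside interval k to
k±1 records one ±1 event. This counts a traversal exactly once, ignores
re-crossings inside the slab, is insensitive to frame stride (a jump
across several intervals records each crossing), and never mistakes a
periodic wrap for a permeation. Conductance uses the net signed count:
g[pS] = |N_net|·q·e/(T·|V|); replicate statistics use the sample SD with
n−1 and SEM = SD/√n; model comparisons use the two-sided Welch t-test
(p = 1 for two identical zero-variance samples).

Completed-traversal counting truncates the partial traversal at each end
of a finite trajectory, a bias of order 0.2 events per ion independent of
duration; tests that compare against the analytic drift count therefore
use conditions where replicate scatter dominates this truncation.

The printed experimental anchor 17.5 pS ↔ 6.125 events/100 ns is
internally consistent at an effective |V| ≈ 0.56 V, not the nominal 0.5 V
(N = g·|V|·T/e gives 5.47 at 0.5 V). The package computes both
conversions; all conductance estimation defaults to the literal voltage
of the run.

## Hydration profiles

Water density is sampled in a cylinder (default radius 5 Å) around the
pore axis in 1 Å axial bins: density = mean in-cylinder count / (πr²Δz),
normalized by a bulk slab far from the gate (default: the outer quarter of
the box on each side). The density integrates back to the mean in-cylinder
count to ~1e-6 relative (mass consistency). The gate call takes the
minimum normalized density over gate bins: dehydrated < 0.05, partially
dehydrated < 0.5, hydrated otherwise. The cutoffs and the cylindrical
sampling volume are package choices — the source analyses report
qualitative hydration only.

## Well-tempered metadynamics and its oracle

One tagged ion carries the collective variable (its absolute z, pore
centered at 0). Every `deposition_stride` steps a Gaussian hill is added
at the current CV with height w₀·exp(−V_bias/((γ−1)kT)); bias potential
and force live on a 2048-point periodic grid and hills use minimum-image
distances. Defaults: w₀ = 0.3 kcal/mol, σ = 1.0 Å, stride = 500 steps,
γ = 10, kT = 0.596 kcal/mol. Voltage is always zeroed in free-energy runs
(permeation free energy is an equilibrium quantity). The profile is
F(z) = −γ/(γ−1)·V_bias(z), min-shifted; `reconstruct_free_energy` can
average the estimate over the last fraction of deposition times
(`time_average`), the usual variance reduction against hill ripple.
Barriers are max F over the gate region minus min F over a reference
region (shift-invariant, clipped at 0).

The independent cross-check is Boltzmann inversion, F = −kT·ln ρ(z), of an
unbiased voltage-free run. For a ~4 kcal/mol (≈6.7 kT at 300 K) barrier an
unbiased desk-scale run cannot cross often enough to histogram the barrier
top, so the oracle run uses an elevated temperature (900 K) and a faster
test-particle diffusivity: with non-interacting ions the equilibrium
density at any temperature inverts to the same input PMF, while barrier
visits become ~e⁴ more frequent. At 10⁶+ steps the two estimators agree to
≲0.25 kcal/mol RMSD on the central 80% of the grid (profiles are
mean-aligned over the compared bins before the RMSD, free energies being
defined up to an additive constant).

## Ideal α/π backbones and assignment

Backbones are built by natural-extension (NeRF) placement with ideal bond
lengths/angles and per-residue (φ, ψ) = (−62.0°, −45.0°) for α and
(−56.5°, −66.0°) for π — tuned numerically so the chains measure 1.50 and
1.15 Å rise/residue and ~3.7 and ~4.1 residues/turn. (Rise was prioritized
where ideal covalent geometry cannot hit the textbook ~4.4 residues/turn
simultaneously; measured π-helices average ~4.1.) Because the O(i)→N(i+k)
span is shaped by the dihedrals of residues i…i+4, π backbone geometry
extends three residues past a designed stretch; each carbonyl O is then
pointed at its designed acceptor N(i+4) (α) or N(i+5) (π). Terminal
carbonyls whose acceptor falls past the chain reuse the local-frame
orientation of the last real carbonyl so they do not fake the other
pattern.

Assignment is geometric, not DSSP-electrostatic: residue i is π if
O(i)···N(i+5) ≤ 3.5 Å with C=O···N angle ≥ 120°, else α by the same test
at i+4; π takes precedence (π detection is the point); unmatched interior
residues are coil; terminal residues whose π acceptor falls past the chain
extend the adjacent interior label. Builder → assigner is an exact round
trip for any design whose π stretches end at least five residues before
the C-terminus; stretches running into the terminus are unrecoverable in
principle (their encoding H-bonds do not exist) and inherit the interior
label — a known limitation.

Pore-facing residues: Cβ is reconstructed from N/Cα/C by ideal tetrahedral
geometry (so side-chain-free PDB files and Gly work); a residue faces the
pore if its Cα→Cβ direction is within 60° of the inward radial direction.
The register-shift map sends facing residue r to r+1 for r at or past the
bulge start (r−1 inverts it), reproducing the three S6 swaps
I409/V413→L410/A414, F937/I941→I938/I942 and V1766/I1770→N1767/A1771 —
the last rotating the conserved Asn toward the pore.

## Conductance classes and the scenario table

Model names follow `<k>pi[_d<i>…]`. With DIII-S6 π (as in every resolved
conformation), the class is a pure function of DI/DIV: both π → fully
conductive, one → subconductance, neither → nonconducting; DII toggling
never changes it. DIII-α compositions raise "outside modeled space" rather
than extrapolate. Functional labels (O / S2 candidacy) are advisory
strings. The expected-conductance ranking orders by class then π count and
reports equal keys as ties.

The pipeline maps each model to a single-Gaussian gate barrier (σ =
2.5 Å): measured values 4.8 (2pi_d1_d3), 4.1 (2pi_d3_d4), 5.0
(3pi_d1_d2_d3), 3.4 (3pi_d1_d3_d4), 2.9 (4pi); 4.6 for 3pi_d2_d3_d4 is
interpolated between its neighbours and flagged as such in config and
report. The two dehydrated models carry a stand-in barrier of 8.5 kcal/mol
chosen from the toy's Kramers-type rate estimate — rate ∝
(D/(Lz·σ))·exp(−ΔF‡/kT), each extra kcal/mol suppressing events ~5.4× —
so that expected events stay below 0.1 per replicate. Dewetting factors
follow the class: 1.0 (nonconducting), 0.3 (subconductance; gate hydrated
but below bulk), 0.0 (fully conductive).

Scenario runs use a toy diffusivity of 0.75 Å²/ps with dt = 0.5 ps,
10 ions, 2×10⁴ steps × 6 replicates — roughly 40× faster-diffusing ions
than the generator default, so that desk-scale runs accumulate countable
events across the whole barrier range. Absolute toy conductances are
therefore ~2 orders of magnitude above single-channel values; only
orderings, ratios and classes are meaningful, and those reproduce the
expected pattern (Spearman −1.0 between configured barrier and mean
conductance across the hydrated models). Per-scenario replicate seeds
derive from a CRC of the scenario name plus a base seed; reports embed a
config fingerprint.

## Problem sizes and tolerances

Tests run in about a minute on one CPU: drift recovery uses 6 replicates
× 10⁵ steps (3-SEM criterion); the barrier–conductance anticorrelation
uses barriers {1, 3, 5} kcal/mol × 6 replicates × 4×10⁴ steps (strict
ordering, margins of several SEM); metadynamics recovery uses one 10⁶-step
run (±0.5 kcal/mol and ≤0.5 kcal/mol RMSD against the oracle); the Welch
calibration uses 2000 null pairs at n = 6 (type-I error within 5% ± 1.5%).
Equilibrium correctness is a one-sample KS test against exp(−U/kT) with
seed-robust tolerance 0.025 on correlated samples.

## What passing does and does not show

The generator emulates drift-diffusion transport, field-driven counting
statistics, dewetting-controlled occupancy and equilibrium sampling of a
1-D PMF — enough to validate every estimator in the package against
closed forms and independent oracles. It does not emulate ion–ion or
ion–water coupling, selectivity-filter chemistry, protein flexibility
(Cα-restrained or otherwise), or the actual free-energy consequences of a
π insertion; the barrier and dewetting values per model are inputs taken
from the table above, so pipeline-level agreement with the expected class
partition demonstrates internal consistency of the analysis chain, not an
independent prediction about Nav channels.
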