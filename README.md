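# porepi

Toy Brownian-dynamics pore models linking the α/π secondary structure of
Nav-channel S6 helices to pore hydration, ion-permeation free energy and
single-channel conductance class.

## The scientific problem

Eukaryotic voltage-gated sodium (Nav) channels are pseudo-tetramers whose
four pore-lining S6 helices (subunits DI–DIV) have been resolved both fully
α-helical and with short π-helix stretches below the selectivity filter. A
π-helix is an i→i+5 hydrogen-bonded segment (~4.4 residues/turn, ~1.15 Å
rise/residue) carrying a one-residue bulge relative to the i→i+4 α-helix;
inserting one rotates the register of every downstream side chain, which
swaps the residues lining the activation gate. Because gate-lining
hydrophobicity controls pore wetting — and a dewetted gate blocks
conduction — the α/π composition of the four S6 helices is a candidate
switch between fully conductive, subconductance and nonconducting pore
states.

`porepi` packages that reasoning as a tested pipeline at desk scale. In
place of all-atom MD it uses a Brownian-dynamics stand-in: cations
drift-diffusing along a cylindrical pore axis under a configurable
potential of mean force (PMF) plus a constant field equivalent to a
transmembrane voltage, with water occupancy set by a tunable dewetting
gate. On top of the generator sit the same analyses one would run on MD:

- **permeation** — double-gate detection of complete ion traversals;
  conductance from counting, `g = |N_net|·q·e / (T·|V|)` in pS, with
  replicate SEM and Welch t-tests between models;
- **hydration** — time-averaged axial water-density profiles normalized by
  bulk, and a hydrated / partially dehydrated / dehydrated gate call;
- **free_energy** — well-tempered metadynamics on the ion's axial
  coordinate (tempered hill heights `w = w₀·exp(−V/((γ−1)kT))`, estimator
  `F(z) = −γ/(γ−1)·V_bias(z)`), cross-checked by Boltzmann inversion
  `F(z) = −kT·ln ρ(z)` of unbiased runs;
- **helix_geometry** — ideal mixed α/π backbone construction, geometric
  H-bond assignment of α/π/coil labels, π-stretch localization and the
  one-residue register-shift map for pore-facing residues;
- **state_model** — the conductance-class decision logic over model names
  like `2pi_d1_d3` (π in DI-S6 and DIII-S6): with DIII-S6 π-helical, π in
  both DI and DIV ⇒ fully conductive, in exactly one ⇒ subconductance, in
  neither ⇒ nonconducting; DII-S6 never changes the class;
- **pipeline** — the eight-model synthetic reproduction, mapping each
  composition to a PMF barrier and dewetting factor and emitting a
  comparison report.

## Worked example

```python
import numpy as np
from porepi import PoreSystemSpec, simulate_pore
from porepi.permeation import count_permeation_events, replicate_conductance
from porepi import state_model as sm

spec = PoreSystemSpec(pmf_terms=((2.9, 0.0, 2.5),),  # 2.9 kcal/mol gate barrier
                      voltage=-0.5, n_ions=10, n_waters=0,
                      diffusion_coeff=0.75, dt=0.5,
                      n_steps=20_000, frame_stride=20, seed=2023)
counts = []
for r in range(6):
    traj = simulate_pore(spec.replace(seed=2023 + r))
    counts.append(sum(e.direction for e in count_permeation_events(traj)))
est = replicate_conductance(counts, duration_ps=10_000, voltage=-0.5)
print(counts, round(est.mean_g, 1), round(est.sem_g, 1))
cls = sm.classify(sm.parse_model_name("4pi"))
print(cls.conductance_class, "|", cls.functional_label)
```

prints

```
[76, 81, 79, 88, 88, 73] 2590.2 80.8
fully_conductive | O (first open) candidate
```

i.e. 73–88 complete traversals toward +z per 10 ns replicate, a toy-scale
conductance of 2590 ± 81 pS (mean ± SEM over six replicates — the toy ion
diffuses ~40× faster than a real ion in a channel, so absolute values are
not comparable to experiment; orderings and classes are the object of
study), and the class assignment for the all-π composition. A
five-events-in-100 ns count at −500 mV, the paper-scale arithmetic, gives
`estimate_conductance(5, 1e5, 0.5).conductance == 16.02` pS.

A command-line interface mirrors the library:
`porepi classify 2pi_d1_d3 4pi`, `porepi permeation --traj t.extxyz`,
`porepi hydration --traj t.extxyz --gate -10:10`,
`porepi helix --pdb helix.pdb`, `porepi run --out results/`.

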