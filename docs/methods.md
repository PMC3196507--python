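# Methods

## Model

`cadsort` simulates differential-adhesion cell sorting in two dimensions
with the Glazier-Graner-Hogeweg (GGH, Cellular Potts) model.  Biological
cells are domains of lattice pixels sharing a cell index; index 0 is the
cell-culture medium.  The configuration evolves by pixel-copy attempts: a
random lattice site takes the index of a random site in its copy
neighborhood with probability 1 if the effective-energy change ΔH ≤ 0 and
exp(−ΔH/T) otherwise, where the motility T plays the role of a temperature
set by membrane fluctuations.  One Monte Carlo step (MCS) is W·H attempts on
a W×H lattice.  The effective energy is

    H = Σ_links J(σ_i, σ_j) + Σ_cells λ (V_σ − V_t)²

with the adhesion sum over unordered site pairs up to fourth-nearest
neighbors (20 sites; Euclidean shells 1, √2, 2, √5) belonging to different
cells, counted once per pair, and an elastic volume constraint.  Cell-medium
links carry a constant contact energy J_cm; there is no surface-area
constraint term.  Boundary conditions are fixed: the outer two-pixel rim of
the lattice never changes, and lattices are sized with a ≥10-pixel medium
margin so aggregates never reach it.  Cell connectivity is *not* enforced
during dynamics; fragmentation at high motility is possible and reported by
the metrics rather than prevented.

## Binding models

Each cell i carries a cadherin expression number N_i.  Because all cells
share the same target volume and membrane area, surface densities are
proportional to expression numbers and all geometric factors (areas, the
fluctuation amplitude normal to the membrane) are folded into a single
effective equilibrium constant k_eff.  The bound-pair density B between
cells expressing N_1 and N_2 is

* CDM (cis-dimer model):  B = k_eff (N_1 N_2)²  — cis-dimers on each
  membrane bind into trans-tetramers;
* THBM (trans-homophilic-bond model):  B = k_eff N_1 N_2 — individual
  trans bonds;
* SM (saturation model):  B = k_eff min(N_1, N_2) — binding saturates at
  the lower-expressing cell.

The contact energy density is J(N_1, N_2) = J_0 + ΔG·B with ΔG < 0 the
per-bond free energy and J_0 the non-cadherin baseline.  The interfacial
tension γ(N_1, N_2) = J(N_1,N_2) − [J(N_1,N_1) + J(N_2,N_2)]/2 has closed
forms (−ΔG·k_eff/2)·(N_1−N_2)², (−ΔG·k_eff/2)·(N_1²−N_2²)² and
(−ΔG·k_eff/2)·|N_1−N_2| for THBM, CDM and SM; it is nonnegative, vanishes
only for identical cells, and is independent of J_0.

For two cell types the complete-sorting (wetting) condition requires the
heterotypic tension to be positive and the higher-expressing (more
cohesive) type to have the larger cell-medium tension; with a
level-independent J_cm the engulfment margin reduces to
|ΔG|·(B(lo,hi) − B(lo,lo)), strictly positive for CDM and THBM and exactly
zero — neutral wetting — for SM.  All three models therefore predict that
low expressers envelop high expressers whenever levels differ.

When several binding models are compared, their k_eff are chosen so the
maximum homotypic adhesion magnitude |ΔG|·B(N_max, N_max) is identical
across models (`match_energy_ranges`), removing energy-scale differences
from the comparison.

## Parameters and calibration

The physical literature fixes the functional forms but not the lattice
energy scale, so the defaults were set by pilot runs against three
requirements: cells must neither pin to the lattice at the reference
motility nor dissociate (shed pixels or whole cells into the medium, or
fragment), and two-level aggregates must sort well inside the desk-scale
budget.  Two lattice pathologies bound the viable window.  A negative
cell-cell contact energy (J_0 < |ΔG|·B) rewards contact proliferation and
shreds cells into interpenetrating pixels, so J_0 sits above the maximum
cadherin contribution and every J(n₁, n₂) stays positive.  Conversely,
contact energies large compared to T make the marginal adhesion gain of
shedding a rim pixel to medium (roughly ten links' worth of J) overwhelm
the volume penalty, and low-expressing cells evaporate.  The mild-positive
regime between the two, with J/T ratios matching the classic GGH
cell-sorting parameter sets, is death-free and unfragmented at T ≤ 20 over
the desk-scale budgets.

| parameter | default | meaning |
|---|---|---|
| ΔG | −1 | per-bond free energy (sets the energy unit together with k_eff) |
| max adhesion | 16 | \|ΔG\|·B(23,23), matched across models; fixes k_eff per model |
| J_0 | 20 | non-cadherin contact energy (max adhesion + 4, so J(n,n) ≥ 4 > 0) |
| J_cm | 20 | cell-medium contact energy (cohesion without rim evaporation) |
| λ | 5 | volume elasticity (λ=2 lets the aggregate's surface tension squeeze cells ~10% under target) |
| T | 20 | default motility; the motility study brackets it with {5, 60} |
| V_t | 25 px | target volume (≈2 µm/pixel, metadata only) |
| neighbor order | 4 | adhesion and copy neighborhoods (20 sites) |

## Initial aggregates

A circular disk of area n_cells·V_t pixels is partitioned into cells by
k-means on the disk's pixel coordinates (nearest-centroid assignment gives
convex, connected cells of near-equal area), then relaxed for 50 MCS at the
configured motility with homogeneous adhesion before expression levels are
drawn.  Two details matter: the relaxation uses a homotypic contact energy
of 6 (interfaces must cost something or cells dissolve into each other) and
a stiff volume constraint λ=40 (with the run-time λ the rim compression
would push total cell area several percent below n_cells·V_t).  Because
order-4 copy vectors can deposit pixels detached from their cell, a final
pass reabsorbs all but each cell's largest 4-connected component, so every
cell in the initial state is connected.  Levels are assigned i.i.d. —
uniformly over a discrete list or uniformly over a continuous range — with
each allowed value equally probable.  The scheme catalog contains the
standard lists (2, 3, 5, 9 evenly spaced levels on [1, 23]; continuous
(1, 23); seven two-level range variants down to [19.62, 23]).

## Sorting metrics

* **HBL** — heterotypic boundary length: unit-distance lattice links whose
  sites belong to different cells with different levels (cell-medium links
  excluded), an integer contour length in pixels.  Boundary links are
  counted at order 1 even though the energy uses order ≤ 4: order-1 links
  make the HBL a true contour length (configurable for sensitivity checks).
* **WHBL** — each heterotypic link weighted by the interfacial tension of
  its level pair; equals γ·HBL when only two levels exist.  For continuous
  levels every contact is heterotypic and the HBL saturates, so the WHBL is
  the primary observable there.
* **Normalization** — (L(t) − L_ref)/(L(0) − L_ref), with L_ref either the
  empirical minimum over the run or the theoretical minimum of the ideal
  configuration (concentric rings ordered by level, each interface a circle
  of perimeter 2π√(A_k/π) over the cumulative inner area A_k, optionally
  tension-weighted).  Both references are computed and reported side by
  side; they answer different questions (progress toward the run's own
  asymptote vs. absolute completeness).
* **Relaxation time τ** — first time the smoothed normalized series
  (centered 5-sample moving average; raw series cross 1/e spuriously)
  settles below 1/e; "not reached" (∞) marks incomplete sorting.  Inside
  experiment summaries the crossing is refined by linear interpolation
  between the bracketing samples, which removes the recording-cadence
  quantization from replica statistics.  The sorting rate is 1/τ, with rate
  0 for runs that never relax.
* **Radial sorting index** — Spearman rank correlation between each cell's
  level and its centroid's distance to the aggregate centroid, negated:
  +1 = perfect inward ordering of high expressers.
* **Cluster analysis** — cells with equal levels sharing at least one
  order-1 link form homotypic clusters (connected components of the
  equal-level contact graph); their counts decay as coalescence proceeds
  and are fitted by a power law of MCS.  For continuous levels clustering
  is defined only after quantile binning.
* **Power-law fits** — ordinary least squares of log y on log x, reporting
  amplitude, exponent and the adjusted coefficient of determination.

## Experiment designs and problem sizes

Full-scale studies use 305-cell aggregates (≈200 µm across at 2 µm/pixel)
run for 10⁶ MCS with ten replicas (six for clustering); all designs accept
those sizes via keyword overrides.  The shipped defaults are desk-scale,
chosen so that the qualitative orderings — not absolute τ values — are
resolved in minutes on one CPU:

* level-count sweep: 150 cells, 15k MCS, 5 replicas (80-cell aggregates
  cannot separate the 2-level vs 3-level relaxation times above replica
  noise; the ordering is stable from ~10k MCS on);
* range, motility and model-comparison sweeps: 80 cells, 30k MCS,
  5 replicas;
* clustering: 500 cells, 10k MCS, 6 replicas, standing in for a ~5000-cell
  aggregate.

Replica i uses seed seed_base + i for the aggregate build and the
simulation stream, so paired conditions see identical initial geometries
and the whole pipeline is reproducible bit for bit from the manifest.
Error bars are standard errors over replicas.

## What the desk-scale defaults do and do not show

They reproduce the structural claims: engulfment direction (low expressers
outside), strictly increasing relaxation time with level count, relaxation
time falling with interfacial tension approximately as a power law (the
narrowest range [19.62, 23] is slowest by more than an order of
magnitude), matched binding models agreeing at two levels, the motility
optimum (pinned and incompletely sorted at T=5, sorted at T=20, fluid but
disordered at T=60 with some cells dissolving into the medium), and
per-level cluster counts decaying with negative power-law exponents.

Normalization choice matters for the motility comparison: the
empirical-minimum τ is completeness-blind (a pinned run relaxes quickly
toward its own shallow minimum), so the pinning effect τ(20) < τ(5) is
read from the theoretical-ring normalization, under which the T=5 runs
mostly never cross 1/e at all.  The level-count ordering, by contrast, is
measured on the empirical-minimum normalization, where it is sharp.

Known limitations: cluster censuses skip the t=0 partition (its convex
construction cells touch more same-level neighbors than relaxed round
cells, a transient outside the coalescence scaling regime); at T=60 a
quarter of the cells may dissolve — excessive motility violates the
fixed-cell-count assumption rather than merely roughening boundaries; and
the synthetic dynamics lack everything the model assumes away: no growth,
division or death, uniform constant cadherin distributions on membranes, a
single cadherin species, fixed motility per run.  Conclusions about real
tissues should lean on the orderings, not the absolute MCS counts.

## Numerical choices

Tension closed forms are exact algebra; tests compare them to the energy
composition at 10⁻¹² *relative to the composed homotypic terms*, since for
CDM those terms reach ~3·10⁵ on [1, 23] and float64 cancellation makes an
absolute 10⁻¹² unattainable.  The incremental ΔH of the compiled kernel is
the line-for-line mirror of the pure-Python `delta_H`, which in turn is
tested against full energy recomputation to 10⁻⁹; a scripted-attempt mode
replays identical attempt sequences through both paths and requires
byte-identical grids.  Random streams: the aggregate builder and level
draws use `numpy.random.default_rng(seed)`; each recording chunk of a run
draws an independent child seed from `SeedSequence(seed)`, so recording
cadence does not perturb trajectories.  Degenerate inputs fail loudly:
equal levels in the sorting condition, normalization with L(0) ≤ L_ref,
power-law fits with nonpositive data or fewer than three points, single
cells in the radial index.
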