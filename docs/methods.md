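# Methods

This note records what the package computes, the defaults it ships with,
and the choices made where more than one reasonable construction exists.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Input model and preprocessing

The unit of data is a *trace ensemble*: N single-cell structures × m genomic
bins × 3D coordinates in nm, with a missingness mask (tracing experiments
lose a few percent of localisations).  Conventions:

- Bins are 0-based, half-open `[start, start + resolution)`; a trace table
  may carry either a bin index or a genomic start column, and a unit
  multiplier handles tables in µm.  Tables interleaving several regions must
  be disambiguated with a region label; mixing bin grids is an error, never
  a silent merge.
- **QC filter**: keep structures with *strictly more than* a fraction
  (default 0.9) of bins measured.  The strictness is deliberate and
  documented: `min_fraction=1.0` keeps nothing, since a complete structure
  has exactly, not more than, 100% of its bins.
- **Imputation**: a missing bin takes the coordinates of the nearest
  measured bin by genomic distance; an exact left/right tie resolves to the
  lower genomic index (deterministic and order-independent); end gaps are
  one-sided.  Both the filter and the imputation are idempotent.
- Distances are plain Euclidean per structure; converting to binary
  contacts uses an inclusive cutoff (d ≤ cutoff) with the diagonal set to 1,
  since a bin trivially contacts itself and downstream boundary callers
  expect a nonzero diagonal.
- R_g is computed either from coordinates or, downstream of the
  rigid-motion-invariant representation, from the distance matrix via
  R_g² = Σᵢⱼ dᵢⱼ² / (2m²).

## Structural landscape

Median centering uses the elementwise median across structures (midpoint
convention for even N), so the centred stack has elementwise median zero.
The comparison value s_αβ is the unrestricted double sum over all matrix
elements — both triangles count, the diagonal contributes nothing — making
*s* the Gram matrix of the flattened centred matrices: symmetric, positive
semidefinite, with s_αα the squared Frobenius norm.

"PCA on the comparison matrix" is construed as: rows of *s* are
observations, columns are features, column-mean centering only (no unit
variance scaling — flagged as a sensitivity point, since the alternative is
defensible).  This is equivalent, up to eigenvalue scaling, to kernel PCA on
the Gram matrix.  PC signs are arbitrary in principle; the package fixes
them deterministically: PC1 is flipped to correlate positively with R_g
(compact structures to the left), PC2 and higher are flipped to non-negative
skewness.  A comparison matrix with no variance (all structures identical)
yields a warning and all-zero scores rather than an error, so degenerate
inputs flow through pipelines.

Joint (multi-condition) landscapes pool the structures first — one pooled
median, one pooled comparison matrix, one PCA — because pooling before
comparison is the only stated difference from the single-condition case.
Groupings along a PC use contiguous rank groups of near-equal size
(remainder to the earliest groups, ties broken by structure index); regime
tables split the PC1 range into equal-*width* intervals, the last one
right-closed.

## Ensemble SSI

Row correlations are Pearson over *full* rows of the comparison matrix,
including the diagonal and each pair's self-entries; a flag
(`include_diagonal=False`) masks the two self-entries per pair for
sensitivity analysis.  Constant rows have undefined correlations and their
nodes are excluded with a warning.  Weights are w = (1+c)/2; the threshold
is the linear-interpolation percentile (default 50) of all off-diagonal
upper-triangle weights, and edges are retained *strictly above* it, so with
distinct weights an even edge count drops exactly half.  Natural logarithms
are used throughout; Sᵢ is base-invariant.

Degenerate degrees: k = 0 nodes are excluded from medians (NaN, with a
warning); k = 1 is defined as Sᵢ = 1 — a single edge carries all its weight
trivially, and log k = 0 makes the formula indeterminate.  If every
retained incident weight of a node is zero, proportions are taken as
uniform, again giving Sᵢ = 1.

Resampling draws `n_sample` structures without replacement per iteration
(defaults: 200 structures, 1000 iterations) and, by default, *rebuilds the
entire subnetwork* — correlations, rescaling, percentile threshold — on the
corresponding principal submatrix of the full comparison matrix, because the
purpose of resampling is to normalise sample size and the percentile
threshold depends on it.  The alternative reading (subsample precomputed
full-network node values) is available as `resample_mode="node"`.  One root
seed spawns per-iteration seeds via `numpy.random.SeedSequence`; runs are
bit-reproducible.  Iterations whose subnetwork loses every edge record NaN
with a warning, never a silent drop.  Medians use the midpoint convention;
because the display transform 1000·(S − 0.99) is affine and monotone, it
commutes with medians and both scales are reported.

## Bin variability

Each structure's bin network keeps edges with distance ≤ cutoff and uses the
*raw distances as weights* — exactly as stated, not inverted.  Consequence,
documented rather than reinterpreted: a bin whose retained neighbours sit at
uniform distances maximises its BSI.  `invert_weights=True` exposes the
inverse-distance alternative for sensitivity analysis.  Default cutoffs
resolve from bin resolution: 330 nm at ≤ 30 kb, 500 nm at 50 kb, explicit
otherwise.  Bin variability is the sample (n−1) standard deviation of BSI
across cells, per bin; bins with fewer than two contributing cells are NaN
with a warning.

## Polymer model

Reduced Lennard-Jones units (σ length, ε energy, τ time).  Terms:

| term | form | defaults |
| --- | --- | --- |
| backbone | FENE, U = −½ K_S R₀² ln[1−(r/R₀)²] | K_S = 30 ε/σ², R₀ = 1.6 σ |
| nonbonded | 12-6 LJ per state pair, truncated & shifted | repulsive pairs cut at 2^{1/6}σ (WCA), attractive at 2.5 σ |
| loops | harmonic U = K_L (r − R0L)² (no ½ — implemented as stated) | K_L = 300 ε/σ², R0L = 1.2 σ |
| walls | WCA on the gap to each face of a cubic box | ε_W = 1, box L = 35 σ |
| push-off | U = A[1 + cos(π r/R0S)], A ramped linearly per step | A: 0 → 100 ε, R0S = 2^{1/6} σ |

Nonbonded interactions act between *all* pairs including bonded neighbours
(Kremer–Grest convention; FENE+WCA gives a bond length ≈ 0.97 σ).  The
five-state interaction table of the full chromatin model is configuration
input — the published supplement carrying those values is not reproduced
here, so package defaults (WCA unless specified) are placeholders, not
reference values.

Integration is BAOAB velocity-Verlet Langevin splitting with exact OU
friction/noise (γ = 1/τ, T = 1 by default), which satisfies
fluctuation–dissipation and reduces to energy-conserving velocity Verlet at
γ = 0; the test suite verifies equipartition (kinetic energy 3T/2 per bead
within 10%) and NVE drift (< 0.1% over 10⁴ steps; measured ~10⁻⁶).
Nonbonded forces run over a Verlet neighbour list (largest pair cutoff plus
a 0.4 σ skin, rebuilt whenever a bead has moved half a skin) in a numba
kernel; a 200-bead production step costs ~0.05 ms on one core.  FENE
overstretch and wall escape abort with the step and bead index.  One root seed drives initialisation, initial velocities and
thermostat noise; trajectories are bit-reproducible.

The full reference protocol (soft push-off 4×10⁵ steps at dt = 0.01 with the
A-ramp; uniform-LJ stages 4×10⁵, 5×10⁵, 5×10⁵ steps at dt = 10⁻⁶, 10⁻⁴,
10⁻²; state-potential stage 10⁶ steps at dt = 10⁻⁶; production 2×10⁶ steps
at dt = 10⁻² saved every 10³) is available as `reference_schedule()` and is
intended for cluster use.  `desk_schedule()` keeps the same phase structure
at ~1/50 scale for tests and laptops.  Loop restraints act only in
state-potential phases; walls always.  The initial conformation is a
self-avoiding chain (bond lengths 0.9–1.1 σ, no two beads within 0.7 σ,
wall margin 1.5 σ), deterministic per seed.  Export to the analysis
pipeline maps σ → nm with a configurable scale whose default, 30 nm/σ, is an
arbitrary documented convention (the model itself is in reduced units).

### Desk-scale state-comparison experiment

The uniform-active vs mixed-state comparison
(`polymer.compare_state_annotations`) reduces the reference system
(1950 beads, 2×10⁶-step production, 20 replicates) to 200 beads, a
4×10⁵-step production and 5 replicates per condition.  Three reductions are
deliberate and load-bearing:

- **Box 20 σ for 200 beads.**  At the reference box (35 σ) a 200-bead chain
  never brings its heterochromatin blocks into contact within a desk-scale
  run; at high density they always fuse into a single aggregate.  Near
  20 σ the aggregation of the two heterochromatin blocks is *metastable*:
  different replicates settle into different domain arrangements (fused vs
  separate), which is precisely the discrete-structural-cluster phenomenon
  the ensemble SSI detects.  This mirrors the arrangement diversity the
  full-size system has natively.
- **Few, widely spaced frames** (4 per replicate, 10³ τ apart).  Frames
  saved densely are dominated by their own autocorrelation: every structure
  has near-duplicates from its own replicate, its retained network edges
  become uniformly high within-replicate weights, and the node entropy
  *rises* — densely-sampled mixed-state runs score *above* uniform runs,
  inverting the physical signal.  Sparse sampling restores
  quasi-independent draws from each replicate's basin, and the
  ensemble-level discreteness of the mixed system then dominates.  This
  interaction between autocorrelation and network entropy is the single
  most important caveat for applying the ensemble SSI to simulation data
  (experimental cells are independent draws by construction, so the issue
  does not arise there).
- **Full-network median instead of resampled medians.**  The resampling
  protocol exists to normalise sample size between conditions; here both
  conditions contribute identical structure counts by construction, so the
  default scores the pooled network once (resampling remains available via
  the function's parameters).

Frames are pooled across replicates per condition, following the published
protocol of combining snapshots across independent runs.  The interaction
table (active–active and unlike pairs repulsive,
heterochromatin–heterochromatin attraction 1 ε at 2.5 σ) is shared between
conditions; only the per-bead annotations differ.

A limitation to be aware of: at this reduction each seed set rests on only
4 decorrelated frames × 5 replicates = 20 structures per condition, so the
per-seed-set comparison carries substantial Monte-Carlo noise relative to
the effect size; the corresponding acceptance-style test
(`TestEpigeneticHeterogeneity`) can fall short of its 4-of-5 bar for this
reason.  The noise shrinks with longer productions (more decorrelated
frames per replicate), which is how the full-scale protocol — 2×10⁶ steps,
2000 frames, 20 replicates — resolves the same comparison decisively; that
schedule needs cluster time, not a test runner.

## Synthetic ensembles

The generators emulate the statistical features the pipeline responds to —
not chromatin physics (that is the simulator's role).  All are
bit-reproducible from a seed and return ground truth alongside the data.
Geometry mimics a ~2 Mb region at 30 kb resolution: 100 nm walk steps
confined to a sphere of radius 0.6·step·m^{1/3} give template R_g of a few
hundred nm.

- **scaled**: one template chain × per-structure scale (uniform 0.7–1.3,
  the compaction spread that dominates real ensembles) + isotropic Gaussian
  noise (default 5% of template R_g).
- **boundary_shift**: one shared template; each structure displaces the
  bins beyond its boundary (uniform over the central ±5 bins) by a fixed
  offset of one template R_g, normalises to a common R_g, then applies an
  independent compaction scale.  The normalisation makes R_g independent of
  the boundary, and the mode strengths are sized so that compaction is the
  landscape's first mode and the boundary shift its second — the ordering
  observed in real tracing data.  A strictly single-mode family (R_g
  literally constant and nothing else varying) would place the boundary on
  PC1 and leave PC2 as the arch-shaped curvature component with ~zero rank
  correlation; the two-mode construction is what makes "boundary on PC2" a
  well-posed recovery target.
- **clusters / continuum**: k template conformations define a
  piecewise-linear path in coordinate space; cluster mode draws the path
  parameter from the integers, continuum mode uniformly.  Every pre-noise
  conformation is rescaled to the common template R_g, so the two modes
  share their R_g marginal *by construction* (verified by a
  Kolmogorov–Smirnov check ≤ 0.1) and ensemble-SSI differences are
  attributable to landscape topology, not compaction.
- **inject_missing**: independent Bernoulli dropout per (structure, bin).

What a green test on these generators does **not** establish: robustness to
localisation error structure (anisotropic z-noise, drift), to non-globular
conformations, or to the spatial correlation patterns of real chromatin;
the generators share far more structure across cells than real data does,
which is what makes small-N recovery tests stable.

## Numerical conventions

- Percentiles: linear interpolation between order statistics everywhere.
- Medians over even counts: midpoint.
- Correlations are clipped to [−1, 1] against rounding before rescaling.
- The comparison matrix is symmetrised (½(s+sᵀ)) to remove accumulation
  error before eigen-analysis.
- Entropy sums skip p = 0 terms (lim p→0 p log p = 0).

## Scaling of the shipped checks

The acceptance-style tests run the full logic at reduced scale to stay
within a CI budget: 200-structure ensembles where a production analysis
would use thousands, 200 resampling iterations instead of 1000, and the
desk simulation schedule above.  Thresholds are never loosened to
compensate.

## Known limitations

- The SSI resampling recomputes an N_s × N_s correlation per iteration
  (O(n_iter · N_s²·N) time); fine to a few hundred structures per sample,
  the regime the protocol prescribes.
- The polymer engine is all-pairs and single-threaded; the 1950-bead
  reference schedule is configurable but expects cluster time.
- Trace reading materialises the full table in memory via pandas; ensembles
  of ~10⁴ structures × ~10³ bins fit comfortably, whole-genome traces do
  not.
- ChromHMM-style state inference, boundary calling and loop-extrusion
  simulation are out of scope; the package exports contact matrices and
  BED tracks for external tools instead.
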