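# Methods

## Cell-file switching model

The simulator represents the root division zone as `n_files` (default 1000)
independent clonal files of `file_length` (default 30) cells. The state of a
cell is the unordered pair of its two *FLC* copies' chromatin states — the
number of active copies (0, 1 or 2). Per-copy switching is Markovian:
in each timestep an active copy silences with probability `p_off` and a
silenced copy reactivates with probability `p_on`. The per-cell transition
probabilities are the induced two-copy products (e.g. ON/OFF → OFF/OFF with
`p_off·(1−p_on)`), applied by comparing a single uniform draw against
cumulative intervals in a fixed order: double switch first, single switch
second, stay otherwise. Both probabilities are **per timestep** at the
configured `timestep` (default 1 h) and are deliberately *not* rescaled when
the timestep changes — rates quoted against one timestep are not portable to
another without re-fitting.

Each timestep executes division before switching. Remaining cell-cycle
times decrease by the timestep; cells at or below zero divide in place,
shifting all higher positions up by one (simultaneous divisions are
processed from the tip upward, with shifts accumulating); both daughters
inherit the mother's chromatin state and draw fresh position-dependent
cycle durations; cells whose position exceeds the file length are removed.
Every simulation starts from all-ON/ON files at day 0, with initial
remaining cycle times desynchronized as a uniform fraction of a freshly
drawn duration — a synchronized start would introduce artificial division
waves without affecting state fractions.

Because division is independent of chromatin state, the *marginal* state
distribution of any cell follows the 3-state Markov chain exactly; the
simulator's contribution beyond the chain is the clonal correlation
structure along files (runs of same-state cells). Both properties are
tested: censused fractions against matrix powers, and adjacent-cell state
agreement against position-shuffled data.

### Cell cycle durations

Durations are truncated normal with position-indexed means and SDs and a
hard floor of 13 h, the shortest epidermis/cortex cycle reported in the
root kinematics literature the model's defaults are drawn from. In the
absence of a published per-position table, the default applies a single
(mean 20 h, SD 4 h) pair to all positions; both tables are fully
configurable, and positions beyond the table clamp to the nearest entry.
Truncation uses exact inverse-CDF sampling of the lower-truncated normal
(identical in law to rejection resampling but loop-free); a `clip` option
replaces sub-floor draws by the floor instead, which inflates the mass at
exactly 13 h and is provided only for sensitivity comparisons.

### Emission model

Per-cell Venus intensity is `k·e^{X_ON} + e^{X_OFF}` for `k` active copies,
with `X_ON ~ N(μ_ON, σ_ON²)` and `X_OFF ~ N(μ_OFF, σ_OFF²)`. Note the ON/ON
case doubles a *single* signal draw, following the published emission
formula literally; an `iid_copies` option draws two independent signals for
sensitivity analysis and is off by default. The background term makes all
intensities strictly positive; measured (background-corrected) data can be
negative, which the fitting histograms accommodate by extending the lowest
bin to −∞.

### Census

Histograms and fractions exclude the bottom `exclude_bottom` (default 4)
cells of every file, because cells adjacent to the quiescent center are not
captured in the imaging the model is compared against.

### Implementation and performance

Files hold exactly `file_length` cells throughout (each division inserts one
daughter and evicts the top cell), so the population is a rectangular
`(n_files, file_length)` array and all steps are vectorized; the default
21-day run (1000 × 30 × 504 steps) takes a few seconds on one core. A single
numpy `Generator` seeded from the config drives the whole run, so results
are bit-reproducible per seed; per-file substreams are not used, so changing
`n_files` changes all trajectories. `advance_file` provides the equivalent
readable single-file step used by the unit tests.

## Parameter fitting

The observed data are per-cell intensity vectors at two or more timepoints
(days 7/15/21 in the study design). The objective is the summed
total-variation distance between model and data histograms over 40 shared
bins spanning the pooled 0.1–99.9 percentile range, the outermost bins
extended to ±∞. Total variation was chosen over a likelihood because it is
bounded, robust to tail noise, and zero exactly when the binned
distributions coincide.

The search is deterministic given its seed: every objective evaluation
simulates with the same seed (common random numbers), and the emission
mapping reuses one frozen set of standard normals, so the objective is a
fixed function of the parameters. The procedure is (1) a 9 × 5 log-spaced
grid over `(p_off, p_on)` with moment-initialized emission parameters,
(2) Nelder–Mead refinement of the four emission parameters at the grid
winner (cheap: cell states depend only on the switching rates, so cached
state censuses are reused and only the emission mapping is re-evaluated),
(3) Nelder–Mead refinement of `(log10 p_off, log10 p_on)` with the refined
emission fixed, clipped to bounds with a warning recorded in the trace, and
(4) a final emission refinement. Refining emission *before* the switching
stage matters: with a poorly initialized emission model the objective
surface develops a broad spurious plateau at high `p_off` where inflated
background variance absorbs the ON-cell signal. Searches simulate 300 files
and the winner is re-scored at 1000, trading search noise for speed.
Moment initialization splits the earliest timepoint at an ON threshold
(default intensity 1), estimating the background log-moments from the lower
group and the single-copy signal from the upper group after median-background
subtraction and halving.

Under the default synthetic conditions (`p_off` = 0.01/step,
`p_on` = 0.0005/step, 1000 files), five replicate fits recover `p_off`
within ±10% and the rate ordering in every replicate; the acceptance test
asserts the weaker ×1.5 / 4-of-5 level to leave room for Monte-Carlo
variation.

## smFISH quantification

Spot detection zeroes the top and bottom z-slices (cell-wall reflection
artifacts), applies a white tophat with a ball structuring element (default
radius 3 voxels), min–max normalizes the retained range and thresholds it,
then labels 26-connected components and reports one centroid per component.
Thresholds are per-dataset configuration, mirroring the per-replicate,
per-genotype tuning the experimental pipeline required; no auto-thresholding
is attempted, and a `background_caveat` flag can mark datasets (such as
low-expression wild type) whose counts are known to include false
positives. Coordinates are 0-based voxel indices in (z, y, x) order.

Cells come from a watershed seeded at manually annotated nucleus markers;
the relief is the inverted Gaussian-smoothed image (σ = 2 voxels), with a
gradient-magnitude alternative behind a flag. Spots are counted for the
region containing their rounded centroid; background spots are ignored and
occluded-marker regions are dropped (conservation of detected spots across
assigned/background/occluded is a tested invariant). A cell is ON when
strictly more than three mRNAs are counted.

## Nuclear Venus quantification

Segmented label volumes are accepted as input (the experimental masks were
manually curated; the watershed above can bootstrap labels for synthetic
work). Within each cell a discrete sphere — voxel centers within the radius,
isotropic in voxel units, default radius 15 — is placed at the cell's
brightest Venus voxel (raw by default, optional Gaussian pre-smoothing;
ties resolve to the lexicographically smallest (z, y, x), making output
deterministic). `mean_in_sphere` divides the summed intensity of the
sphere–cell intersection by the full sphere voxel count; `overlap_fraction`
is the in-cell fraction of sphere voxels (out-of-image voxels count against
it); `mean_outside_sphere` is the mean over the cell's remaining voxels
(cell-restricted; an image-restricted variant was considered and rejected as
it mixes neighboring cells' signal). The corrected intensity
`mean_in_sphere / overlap_fraction − mean_outside_sphere` may legitimately
be negative for background-only cells. Cells with overlap strictly below
0.55 are flagged excluded; a consequence of the definitions worth noting is
that the corrected intensity is exactly invariant to adding a constant to
the whole volume, at any overlap fraction. Cells smaller than two voxels
are emitted excluded with a warning.

## Downstream statistics

- Housekeeping normalization: target abundance divided by the geometric
  mean of *PP2A* and *UBC*.
- Outlier screening: iterated two-sided Grubbs test at α = 0.05 per round
  (critical value from the t quantile at `1 − α/(2n)`), stopping at the
  first non-significant round or below n = 3.
- Trends: ordinary least-squares slope per day with its two-sided t-test.
- Group comparisons: tie-corrected Kruskal–Wallis omnibus; pairwise
  two-sided Wilcoxon rank-sum tests (exact null for tie-free samples up to
  n = 20, tie/continuity-corrected normal approximation otherwise) with
  Bonferroni adjustment (×number of pairs, capped at 1); one-way ANOVA with
  Tukey HSD for the replicate-level qPCR comparisons.
- Half-lives: OLS of ln(level) against time, `t½ = ln 2 / |slope|`, with a
  sign-violation flag for non-decaying fits. The log-linear route was chosen
  over nonlinear least squares for determinism and because the assays report
  a single decay rate.
- Summaries: OFF fraction (counts ≤ 3), percentile exceedance (strictly
  above the linearly interpolated percentile — the convention is documented
  because no interpolation rule is standard), and the ON-tail histogram
  above intensity 1, normalized by the tail count so sub-cutoff mass is
  irrelevant.

qPCR trend regression uses replicate-level points by default (means are
also supported).

## Synthetic data

Generators are pure functions of spec + seed (bit-identical reruns) and
produce exactly the formats the analysis modules consume.

- `make_fish_stack`: nearest-seed cell regions around jittered nucleus
  seeds, Gaussian spots (σ = 1 voxel) at recorded sub-voxel positions that
  avoid the top/bottom z-slices, keep a minimum separation, and stay ≥ 3
  voxels inside their cell; nuclear blobs on a separate DAPI channel;
  optional additive Gaussian noise. Unresolvable spot-density requests are
  recorded as warnings in the truth metadata rather than silently violated.
- `make_venus_volume`: slab-shaped cells each holding one near-uniform
  nuclear ball (flat to within 1% but strictly peaked at the center so the
  arg-max is well defined); the truth table stores each cell's contrast.
- `make_cell_table`: simulator output in the deposited per-cell table shape
  (genotype, time_d, file_id, position, n_active_copies, intensity) with a
  JSON sidecar of generating parameters.
- `make_count_table`: per-genotype smFISH count tables. A cell is OFF with
  the genotype's stated no-appreciable-expression probability (72% for the
  intermediate allele, 1.5% for the null, drawn from a ≤3-count truncated
  Poisson background) and otherwise draws a negative-binomial count
  conditioned above the threshold (dispersion r = 2, a typical smFISH
  burstiness level; ON means 8 and 40, encoding the ~1:5 intermediate:null
  ratio). The measured OFF fraction therefore equals the stated condition
  in expectation by construction.
- `make_qpcr_decay` / `make_qpcr_timeseries` / `make_venus_trend_table`:
  exponential decays (half-lives 5 h mRNA, 1.5 h protein) with unit-mean
  multiplicative log-normal noise, and linear trends (−0.13 relative
  units/day for whole-seedling qPCR; −0.0077 intensity units/day per cell)
  at the study's replicate and cell counts.

What the generators do *not* emulate: PSF z-anisotropy, spectral
bleed-through, segmentation errors, uneven illumination, or cell-size and
burstiness effects beyond what the log-normal emission absorbs. Passing
round-trip tests therefore demonstrates correctness of the algorithms under
clean conditions, not robustness to real microscopy artifacts — thresholds
and radii still need per-dataset tuning on real data.

## Numerical choices and limitations

- Probabilities are validated to [0, 1]; transition rows sum to 1 to 1e−12
  by construction and are asserted at that tolerance.
- Emission σ = 0 is allowed (degenerate log-normals) for exact unit tests.
- The fitting objective's determinism relies on common random numbers;
  changing `n_files_search` changes the frozen normals and hence the exact
  optimum.
- The simulator does not model mRNA dynamics, spatial geometry beyond the
  1-D file, elongation-zone behavior, or cold-induced silencing; switching
  rates are constant in time, which is exactly the assumption the observed
  excess of long ON files at late timepoints strains.
- Acceptance-level checks run at 1000 files (the study scale); statistical
  tolerances are three Monte-Carlo standard errors estimated from per-file
  variation, which respects the clonal correlation within files.
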