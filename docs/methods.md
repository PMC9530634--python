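# Methods

`rsnet` reimplements, as a tested and reusable pipeline, the
resting-state functional-connectivity network analysis commonly applied to
two-group (control / experimental), two-session (baseline / follow-up)
intervention studies: correlation-network construction, proportional
sparsity thresholding, graph metrics with area-under-curve aggregation, and
a mixed-ANOVA / FDR / correlation-trend-GLM inference layer.  Because the
kind of fMRI dataset such studies analyze is not publicly distributable,
the pipeline ships with a first-class synthetic cohort generator whose
planted effects give every downstream stage a known ground truth.

## Network construction

Each subject-session is a T x N matrix of regional signals (N regions of
interest, T frames).  Functional connectivity is the N x N matrix of
pairwise Pearson correlations.  Networks are obtained by *proportional
thresholding*: the top k-percentile of the N(N-1)/2 unique off-diagonal
values become edges of a simple undirected graph, for
k in {0.05, 0.10, ..., 0.50}.  Conventions:

* **Signed ranking by default.** Whether proportional thresholds should rank
  signed or absolute correlations is a genuinely open choice in
  connectomics; the default ranks signed r (strong positive couplings are
  kept first, the common toolbox convention), with `absolute=True`
  available throughout.
* **Edge count** is round-half-up of k·N(N-1)/2; ties at the cutoff are
  broken by ascending (i, j) index.  The deterministic tie-break makes
  edge sets *nested* along the grid and runs byte-reproducible.
* No Fisher z-transform is applied before thresholding; rank-based
  selection is invariant to monotone transforms.
* The weighted (un-binarized) variant keeps the retained correlations as
  weights; retained negative values are set to zero and counted.

## Graph metrics

Local (per region): degree centrality; betweenness centrality (Brandes,
unnormalized, summed over unordered source-target pairs — group statistics
are invariant to the (N-1)(N-2)/2 normalizing constant at fixed N, and a
normalized option exists); nodal clustering coefficient 2t_i/(k_i(k_i-1));
nodal efficiency (mean inverse distance to all peers); local efficiency
(global efficiency of the neighbor-induced subgraph); nodal shortest path
(mean distance to reachable peers, NaN when isolated).

Global: network efficiency E = mean over ordered pairs of 1/d_ij with
1/inf = 0; average shortest path length L = mean d over *reachable* pairs,
with the number of excluded pairs reported (sparse proportional thresholds
routinely disconnect the graph, so the convention matters and is stated);
small-worldness sigma = (C/C_null)/(L/L_null) with C the mean nodal
clustering and null values averaged over n_nulls (default 100)
Maslov-Sneppen degree-preserving rewirings (mean-of-nulls rather than
null-by-null ratios).  The rewiring discards inadmissible swaps rather than
failing, so graphs with no admissible swap (e.g. complete graphs) return
unchanged and sigma = 1 exactly.

Weighted variants replace degree by strength, use edge lengths 1/w for
distances, and use the Onnela geometric-mean form of weighted clustering
(several definitions exist; this one is stated explicitly).

Per-metric values across the grid are aggregated by the trapezoidal area
under the metric-versus-k curve ("AUC"); a missing value at any grid point
makes the AUC missing, with the gap count reported.

Distances on binary graphs use a vectorized breadth-first frontier
expansion; weighted distances use Dijkstra via `scipy.sparse.csgraph`;
betweenness and weighted clustering build on `networkx`.  All metrics are
validated against brute-force Floyd-Warshall / path-counting oracles on
random graphs in the test suite.

## Inference layer

* **Demographics**: Welch (and pooled) two-sample t from summary
  statistics; Pearson chi-squared with optional Yates correction on the
  2x2 gender table.
* **Mixed-design (split-plot) 2x2 ANOVA**: between-subjects group,
  within-subjects time, computed in closed form from per-subject means and
  difference scores with the weighted (unbalanced-aware) decomposition.
  All three F tests share df = (1, n-2) for n completers.  For this design
  the interaction F equals the squared pooled t on difference scores; the
  suite asserts that identity to 1e-8 on every simulated dataset, and
  cross-checks against `pingouin.mixed_anova`.  Degenerate variance yields
  coded infinite statistics rather than exceptions so batch screens
  complete.
* **Local-metric screen**: for each region x metric x threshold (plus the
  AUC aggregate), the interaction F and p over completers; BH-FDR applied
  across regions within each metric x threshold family (the family is
  configurable — `joint` pools thresholds within a metric — because the
  grouping convention is a genuine design choice); a post-hoc paired t
  (follow-up minus baseline, experimental group) accompanies every row,
  with both one- and two-sided p-values since significance listings in this
  literature commonly print the one-sided value.
* **Correlation-trend GLM**: OLS on the full covariate x group x time
  factorial design (intercept, covariate, group, time, all two-way
  products, and covariate·group·time), with the three-way coefficient as
  the "change in correlation trend" statistic: the shift, specific to the
  experimental group at follow-up, in the slope between a social-anxiety
  score (LSAS / BFNE / SIAS) and the AUC-aggregated global metric.  The
  saturated factorial with 0/1 dummies makes that contrast a single
  coefficient.  `correlation_trend_glm` is direction-agnostic (it takes an
  outcome and a covariate); the global screen defaults to regressing the
  *score on the metric*, because that slope is the quantity the generator
  plants (scores are drawn conditionally on the realized metric) and the
  direction in which a change of correlation driven by symptom change is
  statistically identifiable — the reverse regression dilutes a slope
  change into the much larger unexplained metric variance.  The
  metric-on-score reading remains available via ``glm_outcome="metric"``.
* **Fisher z comparison** of the score-metric correlation at baseline
  versus follow-up within the experimental group, treating the two
  correlations as independent (the simplest reading of a post-hoc z-test;
  the overlap of subjects across sessions makes this slightly
  conservative in practice).

## Synthetic cohort generator

The generator defines the study conditions; it is the simplest structure
exhibiting every statistical feature the inference layer tests.

* **Design**: 28 control / 24 experimental subjects at baseline, with 8 / 3
  completely-at-random dropouts after baseline (20 / 21 completers, who
  alone enter the screens; non-completers keep a flagged baseline row).
  Ages are Normal(23.18, 2.04) / Normal(23.75, 2.64); gender is Bernoulli
  with the 10/28 and 10/24 female proportions of the emulated study.
* **Connectivity**: a block-modular population correlation matrix —
  default 30 regions in 5 modules, within-module r = 0.4, between-module
  r = 0.1, a desk-scale stand-in for modular resting-state organization.
  Positive definiteness is repaired by clipping eigenvalues at 1e-6,
  reconstructing, and rescaling to unit diagonal; the maximum absolute
  entry perturbation is recorded on the returned structure.
* **Planted edge effect**: +0.4 correlation on five cross-module edges
  from hub region 0, applied only in the (experimental, follow-up) cell —
  a localized group-by-time interaction that degree-centrality screens
  should recover.
* **Timeseries**: x_t = phi·x_{t-1} + eps_t with eps_t jointly normal with
  covariance equal to the target correlation matrix and phi = 0.3
  (BOLD-like smoothness at a ~2 s sampling interval); because the AR
  filter is shared across channels, the stationary lag-0 cross-correlation
  equals the target exactly.  T = 150 frames matches a 5-minute resting
  scan; 100 burn-in frames are discarded.
* **Scores**: each subject-session's LSAS is
  intercept(cell) + slope(cell)·z + Normal(0, 10), where z is the
  subject's *own realized* average-shortest-path-length AUC, standardized
  across the cohort.  Conditioning on the realized rather than population
  metric makes the planted slope change exactly the quantity the trend GLM
  estimates.  Cell intercepts reproduce the emulated study's observed scale
  means; the slope rises from 5 to 20 in the experimental follow-up cell
  (a standardized slope change of 1.5 residual SDs, sized so the design's
  ~41 completers detect it with roughly 85% power).  BFNE and SIAS carry
  cell-constant slopes (no planted trend), and RSES / HADS subscales are
  plain cell-mean normals.

What the generator does *not* emulate: hemodynamic-response convolution,
scanner noise and motion artifacts, physiological confounds, spatially
heterogeneous module sizes, heavy-tailed score distributions, or
informative dropout.  Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under a plausible generative model,
not that the original biological findings replicate.

## Problem sizes and numerical choices

The shipped configurations run at a desk-scale parcellation of 30 regions
(12 in the smoke configuration); the machinery is size-agnostic and the
atlas label is free text.  Calibration and recovery studies in the
acceptance suite use 500 replicates (type-I error within the 99% binomial
interval of alpha = 0.05; Kolmogorov-Smirnov uniformity of null p-values;
2-SE coverage of the planted trend coefficient >= 90%), and the planted-edge
enrichment check uses 20 replicates.  `scripts/acceptance.py` re-runs the
same studies at 300/200/20 replicates and writes the rates it measures.

Tolerances: oracle equivalence at 1e-8; the split-plot identity at 1e-8;
the mean-nodal-efficiency = global-efficiency identity at 1e-12.  Repairs,
exclusions and degeneracies (PD repair size, unreachable-pair counts,
zeroed negative weights, infinite statistics) are reported rather than
silent.  All randomness flows from a single master seed through named
`numpy` SeedSequence substreams, so cohorts, null models and whole runs are
independently byte-reproducible; two runs with the same configuration and
seed produce byte-identical outputs (verified file-by-file in the suite).

## Known limitations

* The split-plot main-effect F's use the weighted (sample-size) marginal
  decomposition; with unbalanced groups other weighting conventions give
  slightly different main effects (the interaction test, the quantity of
  scientific interest, is identical across conventions).
* Betweenness on weighted graphs resolves shortest-path ties as `networkx`
  does; at the default binary settings this is exact.
* The default Fisher z post-hoc ignores the session overlap of subjects
  (slightly conservative); `fisher_z_compare_dependent` implements the
  Pearson-Filon-style dependent-correlations test given the full 4x4
  correlation matrix of (score, metric) x (baseline, follow-up).
* `small_worldness` at 100 nulls dominates runtime at larger parcellations;
  reduce `n_nulls` or drop sigma from the metric set for quick passes.
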