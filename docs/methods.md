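# Methods

## Overview

`topofc` implements a graph-theoretical analysis of whole-brain functional
connectivity of the kind used to compare clinical groups (here modeled on a
type-2-diabetes vs. healthy-control design): per-subject ROI time series are
cleaned, correlated, thresholded into binary networks across a sparsity range,
summarized by small-world and efficiency metrics normalized against
degree-preserving null networks, aggregated into per-subject AUCs, and compared
between groups with covariate adjustment and Bonferroni correction. A synthetic
cohort generator provides ground-truth data so every stage is testable without
access to raw fMRI.

## Signal cleaning

Operating on already-extracted ROI signals (a deliberate approximation: the
voxel-level steps — slice timing, realignment, normalization, smoothing — are
out of scope), the chain is: drop the first 10 volumes (scanner equilibration;
185 → 175 at TR = 2 s), remove each region's linear trend, band-pass to
0.01–0.08 Hz, and regress out nuisance signals. The filter is a second-order
Butterworth applied forward-backward (`sosfiltfilt`): zero phase (phase
distortion would change Pearson correlations), monotone response, effective
order 4. Confound regression always includes an intercept; with no confounds it
reduces to mean-centering. The global mean signal is not regressed. The
head-motion rule excludes a subject when any |translation| > 1.5 mm or any
|rotation| > 1.5°, strictly greater, so values exactly at threshold are
retained; the 24-parameter motion expansion is [p, p², p(t−1), p(t−1)²].

## Networks

Edges are sample Pearson correlations between region pairs (116 regions in the
default whole-brain parcellation: 90 cerebral, 26 cerebellar/vermis). Matrices
are binarized at each sparsity value S in 0.05–0.50, step 0.01 (46 values),
keeping exactly `round(S·N(N−1)/2)` strongest edges (round-half-even), so all
subjects' networks have identical edge counts at each threshold. Ranking is by
signed r — strong negative correlations are never selected (the dominant
convention for binarized resting-state connectomes); |r| ranking is a switch.
Ties break lexicographically on node indices, making graphs deterministic, and
a single stable ranking makes the 46 graphs nested. The Fisher z matrix is
computed and stored for reporting; since atanh is monotone, binarizing on z or
r yields identical graphs, so metrics are computed on the binary graphs only.

## Metrics

On each binary graph: mean clustering coefficient Cp, characteristic path
length Lp, global efficiency E_glob, local efficiency E_loc, and per-node
degree, efficiency, and betweenness (Brandes, endpoints excluded, reported
unnormalized — group statistics are invariant to the normalization constant).
Graphs can fragment at low sparsity: Lp averages finite-distance pairs only,
with the number of unreachable pairs logged per subject and threshold (a
largest-component policy is available); efficiencies need no policy since
1/∞ = 0. All metrics are validated against brute-force enumeration (triangle
counting, Floyd–Warshall, exhaustive shortest-path enumeration) on all graphs
with ≤ 6 nodes and on random 12-node graphs.

## Null normalization

Cp and Lp are normalized by the means of 100 (default) random networks with
exactly the subject graph's degree sequence, generated by Maslov–Sneppen
double-edge swaps: γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩, σ = γ/λ. Each null
targets 10 successful swaps per edge (convergence of null means between 10 and
20 swaps/edge is a test), with proposals that would create self-loops or
multi-edges rejected and an attempt budget of 20× the target; saturated graphs
(no legal swap) are returned unchanged with a warning. Because a cohort
requires hundreds of thousands of rewire-and-measure cycles, the swap loop,
triangle counting and all-pairs BFS are fused in a numba kernel; a pure-NumPy
twin of the rewiring loop backs the public single-graph API and the two paths
are cross-checked statistically in the tests.

## AUC and group statistics

Each metric curve is integrated over the sparsity grid by the trapezoid rule
(exact for piecewise-linear curves; a left-endpoint rectangle rule is a switch
for toolbox-compatibility studies; a one-point grid yields 0 with a warning).
Group comparison of an AUC is the t-test on the group coefficient of the
least-squares model `AUC ~ 1 + group + sex + age + education + BMI` — the
covariate-adjusted analogue of a two-sample t-test. Unadjusted tests are
Welch's t (the variant that reproduces published cognitive-score p-values
recomputed from mean ± SEM summaries), Mann-Whitney U (exact for tie-free
n ≤ 8, tie-corrected normal approximation otherwise), and Pearson chi-square
without continuity correction for sex ratios. Bonferroni correction is applied
within each metric across the 116 regions (the family choice is switchable).
Partial correlation residualizes both variables on the covariates plus
intercept and tests r via t on n − k − 2 df; it is cross-checked against an
independent implementation in the tests.

## Synthetic cohorts

Each subject receives a latent Watts–Strogatz graph (ring lattice of degree
k = 8 over N = 116 nodes, each edge rewired with probability p = 0.15). The
latent graph maps to a correlation matrix C = corr[(I − cA)⁻¹] with the
coupling c at 0.6 of the spectral bound 1/λ_max — positive definite by
construction, with correlations decaying over graph distance. Series are
zero-mean Gaussian draws from C, band-limited to 0.01–0.08 Hz (the same
zero-phase filter applied to every column preserves the between-column
correlation structure while giving BOLD-like spectra), plus white observation
noise with SD 1.0 relative to the unit-variance signal. Only second-order
structure matters downstream, so no hemodynamic model is attempted; motion and
physiological artifacts are not simulated.

Defaults mirror the modeled study: 30 subjects per group, 185 volumes at
TR = 2 s (the pipeline drops 10), 116 regions. Covariates are drawn from the
same distributions in both groups (matched design) with means and SDs
resembling a middle-aged clinical cohort; one cognitive score is generated as
`intercept + slope·(latent nodal degree of a chosen region) + noise`, plus a
fixed patient-group decrement, so score–metric partial-correlation recovery is
testable end to end (the generating metric value is recorded in the manifest).

### The planted group effect

The patient group's latent graphs are drawn with rewiring probability
`p·(1 − effect_size)` (default effect_size 0.8): patients retain a larger
fraction of within-neighborhood lattice edges, i.e. are more regularly
clustered at an unchanged, homogeneous degree sequence — which propagates to
higher measured γ, σ and E_loc, the direction of the group difference the
pipeline is designed to detect.

This mechanism was chosen after simulation showed that the more obvious
alternative — adding triangle-closing edges to patients' graphs — *inverts*
the measured γ difference once the full estimation channel is taken into
account: any add-only perturbation concentrates correlation mass on some
nodes, the thresholded patient networks become hub-heavy, and degree-preserving
nulls of hub-heavy graphs have inflated clustering, so normalized clustering
drops even while raw clustering rises. The triangle-closing perturbation
remains available (`effect_kind="triangle_edges"`); it greedily closes the
open pair with the most common neighbors, which does guarantee a latent
clustering increase.

### Operating points

Two deliberate operating points are used:

- **Default (realistic SNR).** With 175 retained volumes band-limited to a
  0.07 Hz bandwidth, sample correlations have roughly 50 effective degrees of
  freedom; adding unit observation noise halves correlations again. At this
  SNR both groups clearly exhibit the small-world signature (group-mean γ ≈ 3
  at S = 0.05 falling to ≈ 1.15 at S = 0.5; σ > 1 throughout; λ ≤ ~1.17 at
  the lowest threshold, near 1 elsewhere), while the planted group difference
  is sub-threshold — realistic for subtle clinical effects. A relevant model
  property found while scanning this family: any configuration with
  γ(0.05) ≳ 2.5 pins λ(0.05) near 1.2, because clustered edges are redundant
  for shortest paths; observation noise relaxes this by restoring marginal
  long-range edges at low density.
- **Power study (strong signal, scaled down).** Detection-power and
  type-I-error properties are evaluated on smaller cohorts (40 regions,
  coupling at 0.9 of the spectral bound, no observation noise, full planted
  effect, 30 subjects per group, a 9-point grid over 0.10–0.50, 8 nulls per
  graph; the grid starts at 0.10 because at 40 nodes a sparsity of 0.05 means
  mean degree ≈ 2 and degree-preserving nulls of near-tree graphs can be
  triangle-free, leaving γ undefined). At this design the per-metric
  standardized group difference exceeds 1, giving high power at n = 30; with
  no planted effect the adjusted test rejects at the nominal rate (measured
  ~0.06 over 120 independent null tests at design time).

What passing these tests does and does not show: the generator validates the
pipeline's statistical machinery and its sensitivity to a known topological
difference, but real BOLD data differ in ways the generator does not emulate
(hemodynamics, motion, physiological noise, non-stationarity, spatially
heterogeneous connectivity), so passing does not certify effect sizes or
p-values on real cohorts.

## Problem sizes and ensemble choices

The acceptance script (`scripts/acceptance.py`) regenerates the default cohort
and runs the full 46-point grid with 30 null networks per graph (the package's
chosen ensemble size for this summary; with ~2,760 graphs per group the
group-mean γ and σ have null-sampling error far below their between-subject
spread, and the 30 vs. 100 difference is negligible against both). The
small-world signature test in the suite uses 16 nulls per graph for the same
reason. Reported σ and γ are the minimum over the two group means, so the
small-world claim holds for each group separately.

## Numerical choices and degenerate inputs

Round-half-even for edge budgets; deterministic lexicographic tie-breaks in
edge ranking; |r| clipped at 1 − 1e-7 before whole-matrix atanh; zero-variance
regions rejected by name; rank-deficient confound or covariate designs
rejected; graphs with < 2 edges cannot be rewired; triangle-free null
ensembles (possible on very small graphs) raise rather than return γ = 0/0;
one-point grids integrate to 0 with a warning. All stages are pure functions
of their inputs and an integer seed; per-subject and per-threshold seeds are
derived with `SeedSequence` and kept below 2³¹.

## Known limitations

ROI-level rather than voxel-level preprocessing; binary undirected graphs only
(no weighted variants, no dynamic FC); the latent-connectivity family is a
homogeneous small-world model without hubs, modules or hemispheric structure;
the atlas ships as a label table only (no spatial definitions); nodal group
tests default to AUCs (per-threshold nodal testing is a documented switch away
but not exposed as a first-class report).
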