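# topofc

Graph-topological analysis of whole-brain functional connectivity, for
resting-state fMRI group studies: from per-subject ROI time series to
sparsity-thresholded binary networks, small-world and efficiency metrics
normalized against degree-preserving null networks, AUC summaries across the
threshold range, and a covariate-adjusted statistical comparison of two
groups. It is aimed at researchers comparing the network organization of a
clinical group against matched controls (the design it models is a
type-2-diabetes vs. healthy-control whole-brain study over the 116-region
AAL parcellation, cerebellum included), and at methodologists who want a
fully synthetic, ground-truth-controlled testbed for this class of pipeline.

## The analysis

For each subject with ROI signals X ∈ ℝ^(T×N) (T time points, N = 116
regions, TR = 2 s):

1. **Cleaning** — drop the first 10 volumes, linear detrend, zero-phase
   Butterworth band-pass 0.01–0.08 Hz, least-squares confound regression
   (WM/CSF signals, 24 motion parameters when available; the global mean is
   not removed). Subjects exceeding 1.5 mm translation or 1.5° rotation on
   any axis are excluded.
2. **Networks** — Pearson correlation matrix R (Fisher z stored alongside),
   binarized at each sparsity S ∈ {0.05, 0.06, …, 0.50}: keep exactly
   round(S·N(N−1)/2) strongest edges, so every subject's network has the same
   edge count at each threshold.
3. **Metrics** — per threshold: clustering coefficient Cp, characteristic
   path length Lp, global and local efficiency E_glob, E_loc; nodal degree,
   nodal efficiency, betweenness. Cp and Lp are normalized by the means of
   N = 100 Maslov–Sneppen degree-preserving random networks:

       γ = Cp / ⟨Cp_rand⟩,   λ = Lp / ⟨Lp_rand⟩,   σ = γ / λ,

   with σ > 1 (γ > 1, λ ≈ 1) the small-world signature.
4. **AUC + statistics** — each metric curve is integrated over the sparsity
   range (trapezoid rule); group differences in AUC are tested via the group
   coefficient of `AUC ~ 1 + group + sex + age + education + BMI`, with
   Bonferroni correction (per metric across the 116 regions for nodal
   metrics), plus Welch t / Mann-Whitney / chi-square for demographics and
   partial correlations between scores and nodal metrics.

A synthetic-cohort generator (`topofc.synthetic`) draws per-subject latent
Watts–Strogatz networks, maps them to correlation matrices via
corr[(I − cA)⁻¹], simulates band-limited Gaussian BOLD-like series with
observation noise, and plants a group difference (patients more regularly
clustered) plus a cognitive score linked to a latent nodal metric — see
`docs/methods.md` for the model and its deliberate limitations.

## Worked example

Library level — small-worldness of a Watts–Strogatz graph (116 nodes, degree
8, 10% rewiring) against 100 degree-preserving nulls:

```python
from topofc import (BinaryGraph, NullEnsembleConfig,
                    make_small_world_graph, normalized_metrics)

adj = make_small_world_graph(116, 8, 0.1, seed=42)
g = BinaryGraph(adjacency=adj, sparsity=adj.sum() / (116 * 115))
nm = normalized_metrics(g, NullEnsembleConfig(n_nulls=100, seed=0))
print(f"gamma = {nm.gamma:.3f}")   # gamma = 8.636
print(f"lambda = {nm.lam:.3f}")    # lambda = 1.287
print(f"sigma = {nm.sigma:.3f}")   # sigma = 6.709
```

The lattice-like graph is ~8.6× more clustered than its degree-matched random
networks at only ~29% longer paths — strongly small-world (σ ≫ 1).

End to end — simulate a small strong-signal cohort (40 regions, 15 per group,
full planted effect) and compare the groups:

```bash
topofc simulate --out-dir cohort --n-per-group 15 --seed 7 --config gen.yaml
topofc run --cohort cohort --out-dir run --seed 7 --config run.yaml
topofc summarize run
```

with `gen.yaml` setting `n_regions: 40`, `coupling_fraction: 0.85`,
`noise_sd: 0.0`, `effect_size: 1.0` and `run.yaml` setting
`sparsity_step: 0.05`, `n_nulls: 8`. Output:

```
Global AUC group comparison (patient vs control):
  gamma    t=+2.810  p=0.0097 *
  lambda   t=+1.232  p=0.2297
  sigma    t=+2.225  p=0.0357
  e_loc    t=+1.362  p=0.1860
  e_glob   t=+0.861  p=0.3978
```

The planted clustering increase in the "patient" group is recovered: the
covariate-adjusted test on the γ AUC rejects (p = 0.0097, surviving
Bonferroni across the five global metrics, hence the `*`), σ rejects at the
nominal level, λ and E_glob do not differ — the expected pattern when the
groups differ in local clustering but not in integration. Nodal AUC tables
(3 metrics × regions, raw/adjusted/Bonferroni) and score–metric partial
correlations are written as CSVs in `run/`.

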