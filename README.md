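# cytoclust

SPADE-style cluster analysis for mass cytometry (CyTOF), built around the
question of which CD4⁺ T-cell subpopulations expand or contract across HIV
infection stages and track the viral reservoir. It is aimed at
computational immunologists who want a scripted, reproducible version of
the classic workflow: bead normalization → arcsinh transform → gating →
density-normalized clustering → five-tier phenotyping → differential
abundance and covariate correlation — plus a synthetic-study generator with
full ground truth, so every stage can be validated without any external
download.

## The analysis in brief

**Preprocessing.** Raw dual counts are drift-corrected per acquisition
window using spiked-in normalization beads (factor = global bead median /
window bead median, per channel, with bead-blind channels borrowing the
median factor), transformed with `asinh(x/5)`, and gated through the
hierarchy DNA singlets → non-bead → live → CD45⁺ → CD3⁺CD19⁻CD4⁺CD8⁻.
Thresholds are data-driven (two-component Gaussian-mixture midpoints) or
manual.

**Clustering.** Samples are equalized by uniform downsampling to the
smallest sample, pooled, and density-normalized: each event's local density
is the count of neighbors within an L1 radius r (r = 5 × median
nearest-neighbor distance); events are kept with probability
min(1, TD/density), where TD is the 40%-quantile of densities, which
preserves rare populations while thinning dense ones. Ward agglomeration
cuts the kept events into k clusters (350 by default), every gated event is
up-sampled onto the nearest cluster median (L1), clusters under 40 cells
are dropped, and a minimum spanning tree over cluster medians gives the
topology. Cluster coherence is checked per marker with Hartigan's dip test
of unimodality (p > 0.05) and the interquartile range (IQR < 2).

**Phenotyping.** Each marker's 5th–95th percentile range over all CD4
T cells is split into five equal tiers (negative/low/medium/high/very
high); a cluster's tier is the binned mean-over-samples of its per-sample
medians. CCR7 × CD45RA tiers name the subsets (T_N, T_CM, T_Eff/Mem);
CD32a tiers ≥ 4 select the CD32a⁺ clusters (myeloid-looking clusters are
excluded by rule); Kolmogorov–Smirnov distances (threshold 0.30) profile a
cluster against its parent population.

**Statistics.** Cluster abundances are percentages of a parent population
per sample. Differentially abundant clusters (DACs): unpaired Student
t-test with p < 0.05 and fold change ≥ 2. Correlated clusters (CCs):
Pearson correlation of abundance with total HIV DNA (log₁₀ copies/10⁶
PBMC; 0 for uninfected donors), |r| > 0.65 and p < 0.05, with p from
t = r√(n−2)/√(1−r²) on n−2 degrees of freedom.

The dip statistic is computed exactly: the minimum sup-distance between
the sample ECDF and any unimodal CDF, via convex-minorant/concave-majorant
bounds per candidate mode with a small linear program resolving the cases
where the two pieces couple through the mode. Its p-value is Monte-Carlo
calibrated against the uniform null.

## Worked example

```python
from cytoclust import (generate_study, tiny_design, transform_arcsinh,
                       auto_gating_config, gate_events, cluster_events,
                       filter_small_clusters, abundance_matrix,
                       identify_dacs, identify_ccs)

study = generate_study(tiny_design(seed=1))      # 3 conditions x 3 samples
trans = [transform_arcsinh(t) for t in study.tables]
cfg = auto_gating_config(trans, study.panel, seed=0)
gated = [gate_events(t, study.panel, cfg).final for t in trans]
model = filter_small_clusters(
    cluster_events(gated, study.panel, k_target=25, seed=0), min_cells=40)
abund = abundance_matrix(model, study.sheet)
for r in identify_dacs(abund, study.sheet, [("primary_HIV", "healthy")]):
    if r.significant:
        print(f"cluster {r.cluster}: {r.mean_a:.2f}% vs {r.mean_b:.2f}% "
              f"(FC {r.fold_change:.1f} {r.direction}, p = {r.p:.2g})")
for r in identify_ccs(abund, study.sheet.covariate()):
    if r.significant:
        print(f"cluster {r.cluster}: r = {r.r:.2f}, p = {r.p:.2g}")
```

prints

```
cluster 1: 1.50% vs 3.26% (FC 2.2 down, p = 0.027)
cluster 5: 7.95% vs 2.01% (FC 4.0 up, p = 0.0027)
cluster 5: r = 0.76, p = 0.018
```

Cluster 5 is the planted CD32a⁺CD57⁺ effector/memory population: it comes
out four-fold enriched in primary infection (the planted effect size) and
as the positive HIV-DNA correlate. The `examples/` scripts walk through
each capability the same way; `cytoclust simulate` / `preprocess` /
`cluster` / `phenotype` / `stats` / `run` expose the stages on the command
line.

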