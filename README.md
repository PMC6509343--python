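# sczsubtypes

Patient stratification from bulk expression arrays: a tested, reusable
implementation of a pipeline that discovers **two molecular subtypes of
schizophrenia** in dorsolateral prefrontal cortex (DLPFC) expression data
and validates them by perturbation stability.

## The problem

Case/control differential-expression studies of schizophrenia pool
patients who may be biologically heterogeneous.  If only a subset of
patients carries a transcriptomic signature, pooling dilutes it.  This
package implements the full analysis chain for detecting that situation:

1. **Preprocessing** — quantile normalization, log2 transform, and three
   sequential probe filters (NA/Inf values; Illumina detection p-values in
   nearly all subjects; common SNP in the probe sequence), plus a cohort
   filter (diagnosis of interest, age ≥ 25).
2. **Robust mixed-effects differential expression** — per probe,
   `y = β₀ + β_dx·diagnosis + β'·(age, sex, ethnicity, RIN) + u_batch + ε`
   with a random intercept per array batch, fitted by iteratively
   reweighted least squares with Huber-type weights on robustly scaled
   residuals (bounded influence against heavy-tailed outliers), Wald tests
   on β_dx, and Bonferroni / Benjamini–Hochberg adjustment.
3. **Subject network subtyping** — patients are clustered from the DE
   probes: covariate-adjusted expression → signed soft-thresholded
   correlation adjacency `a_ij = ((1+r_ij)/2)^β` → topological overlap
   measure `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)` →
   hierarchical clustering of `1 − TOM` cut at two clusters.  "Type 1" is
   the cluster closer to the control centroid; "type 2" the divergent one.
4. **Perturbation stability** — uniform noise on ±(level·σ) is added to
   the adjusted data and the clustering repeated (100 runs per level);
   any patient misclassified at least once is relabelled "intermediate".
5. **Threshold graphs** — the subject TOM similarity is swept through a
   grid of edge thresholds and the connected-component structure
   (counts, sizes, label composition, isolated nodes) is tabulated.
6. **Per-subtype re-analysis** — each subtype is scanned against controls
   separately, and a GABAergic interneuron marker report (GAD1, LHX6,
   NPY, TAC1, VIP, SST, PVALB) is extracted.

A bundled synthetic-cohort generator (`simulate_study`) produces
control + two-latent-subtype studies with known ground truth — planted DE
probe sets, covariate and batch effects, heavy-tailed outlier
contamination and undetected probes — so the whole chain is testable
without access to controlled human data.

## Worked example

Generate a synthetic cohort and run the whole pipeline from one YAML:

```yaml
# demo.yaml
out_dir: demo_out
seed: 11
simulate:
  n_controls: 60
  n_type1: 25
  n_type2: 25
  n_probes: 800
  n_de_type2: 120
  effect_mean: 1.2
stability:
  levels: [0.0, 0.05, 0.1, 0.25, 0.5]
  n_runs: 50
```

```text
$ sczsubtypes --verbose run --config demo.yaml
preprocess: 749/800 probes retained, 110 subjects
subtyping: {'type1': 25, 'type2': 25}
stability: [{'level': 0.0, 'type1': 25, 'type2': 25, 'intermediate': 0, ...}]
subtype DE significant: {'type1': 4, 'type2': 116}
pipeline complete: demo_out
```

What the numbers mean: of 800 simulated probes, 40 fail the detection
filter and 11 carry a SNP flag, leaving 749.  Clustering the 50 patients
on the pooled-scan DE probes splits them 25/25 — exactly the planted
subtypes — and the split is perfectly stable here (0 intermediates even
at perturbation level 0.5, because the planted separation is large).
The per-subtype rescan then shows the asymmetry the pipeline exists to
detect: 116 probes significant in "type 2" vs controls (the generator
planted 120) but only 4 in "type 1" (the generator planted 4).
`demo_out/` also contains the Table-1-style `stability_summary.tsv`, the
TOM matrix, per-threshold `graph_summary.tsv`:

```text
threshold  n_components  n_isolated  n_edges  largest_component
0.05       5             4           413      46
0.08       22            20          305      26
0.10       26            25          300      25
0.12       26            25          300      25
```

(one mixed component at low threshold; above ~0.08 the cohesive type-2
block separates while diffuse type-1 subjects become isolated nodes),
and `marker_report.tsv` with per-subtype marker rows.

The same stages are importable as a library (`simulate_study`,
`filter_probes`, `de_scan`, `covariate_adjust`, `subject_adjacency`,
`tom`, `cluster_subjects`, `run_stability`, `component_evolution`,
`subtype_de_scan`, `marker_report`) and as individual CLI subcommands
(`simulate | preprocess | de | subtype | stability | graph | report | run`).

## Layout

- `src/sczsubtypes/simulate.py` — synthetic cohort generator
- `src/sczsubtypes/preprocess.py` — normalization, probe/cohort filters
- `src/sczsubtypes/diffexpr.py` — robust mixed-effects DE scan
- `src/sczsubtypes/subtyping.py` — adjacency, TOM, clustering
- `src/sczsubtypes/stability.py` — perturbation stability and relabelling
- `src/sczsubtypes/tomgraph.py` — threshold-graph component evolution
- `src/sczsubtypes/subtype_de.py` — per-subtype scans, marker report
- `src/sczsubtypes/{io,config,pipeline,cli}.py` — TSV I/O, YAML config,
  end-to-end pipeline with run manifest, command-line interface
- `docs/methods.md` — model assumptions, parameter choices, limitations
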