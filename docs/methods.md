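# Methods

This note documents the statistical models, the numerical choices, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where the design was genuinely open.

## Preprocessing

**Quantile normalization.** Every column (subject) is mapped onto the
common reference distribution, the row-wise mean of the column-wise
sorted matrix.  Tied values within a column all receive the mean of the
reference values over their rank span, which makes the map deterministic
and idempotent.  Columns containing missing cells are mapped through
interpolated quantiles of the reference.  Quantile normalization is a
strong assumption — it forces identical marginal distributions across
subjects — but is the standard treatment for bead-array intensity data.

**Probe filters.** Three filters applied sequentially, so a probe removed
by an earlier stage is never counted by a later one and the ledger
reconciles exactly: (1) any NA/Inf value across subjects; (2) an
Illumina-style detection p-value below `detection_alpha` (default 0.05)
in fewer than `min_detected_subjects` subjects — given as a count or as
a fraction of the cohort (default 841/849 ≈ 0.9906, a near-complete
detection requirement that scales to other cohort sizes); (3) a common
SNP inside the probe sequence (supplied as an id set; SNPs under the
probe distort hybridization and mimic differential expression).
The cohort filter keeps the diagnoses of interest with known age ≥ 25
years, excluding children and young adults whose cortical transcriptome
is still maturing.  Probe filters run on the full subject set before the
cohort filter, matching the convention that detection denominators refer
to the complete array cohort.

## Robust mixed-effects differential expression

Per probe, log2 expression is modelled with fixed effects for diagnosis,
age, sex, ethnicity and RIN, and a random intercept per expression-array
batch.  Estimation alternates:

1. a Henderson mixed-model solve for (β, u) under current observation
   weights and variance components;
2. an EM-style update of the batch variance τ² and a robust update of
   the residual scale s (1.4826·MAD);
3. Huber-type weights `w_i = min(1, c·s/|r_i|)` on the conditional
   residuals.

Numerical choices:

- **Tuning constant** `c = 5.0` (in robust-scale units) by default.  This
  is deliberately conservative: uncontaminated Gaussian residuals
  essentially never exceed 5 MAD-scales, so on clean single-batch data
  every weight is 1 and the estimate coincides with ordinary least
  squares *exactly* — a useful oracle property — while gross outliers
  (the generator's ten-fold noise inflation lands at ~8–30 scales) are
  still strongly downweighted.  The classical 95%-efficiency constant
  1.345 is available via `ModelSpec(robust_tuning=1.345)` when smoother
  downweighting is preferred over the clean-limit equivalence.
- **Wald covariance** uses the M-estimation sandwich scale
  `s²·Σψ(u)²/(n−p) / (mean ψ′(u))²` on the Henderson fixed-effect block.
  On unweighted data this reduces to the OLS covariance `RSS/(n−p)·(X'X)⁻¹`.
  The naive alternative (weighted RSS) is anti-conservative under
  contamination (measured null rejection ~0.10 at α = 0.05 with 2%
  ten-fold outliers; ~0.05 with the correction).
- **Reference distribution**: normal.  Degrees-of-freedom corrections for
  robust mixed models are unsettled and with cohorts of hundreds the
  difference is negligible.
- **τ² floor**: the EM update is floored (stickily) at an intraclass
  correlation of 0.1%.  Near the τ² = 0 boundary EM decays only as
  1/iteration; below the floor the random intercept is statistically
  indistinguishable from none.  Batches with a single subject are pooled
  into a pseudo-batch before fitting (a one-subject batch cannot carry
  its own intercept); if fewer than two batch levels remain the random
  term is dropped.
- **Convergence**: relative coefficient change below `tol` (default 1e-8)
  within `max_iter` (default 100).  Non-convergence is flagged on the
  result, never raised; flagged fits observed in testing differ from
  400-iteration fits by ≤ 3e-4 in the diagnosis effect.

Multiple testing: Bonferroni `min(1, p·m)` with m = number of probes
actually fitted, and Benjamini–Hochberg step-up FDR (via statsmodels).

## Subject subtyping

Patients are clustered on the probes found differentially expressed in
the pooled case/control scan (Bonferroni < 0.05 by default; the probe
set is an explicit input so restricted or replication sets can be
passed).  Expression is first residualized per probe on age, sex,
ethnicity, RIN and batch (never diagnosis), by exact least squares.

Similarity between patients i and j is the signed soft-thresholded
correlation `a_ij = ((1+r_ij)/2)^β` (β = 6) of their adjusted profiles
across the DE probes, followed by the topological overlap measure.  TOM
augments the direct edge with shared-neighbour weight and is bounded in
[0, 1] with unit diagonal.

Two defaults here deserve justification, because the generic
weighted-network defaults (unsigned adjacency, average linkage) fail for
*sample* networks with this structure:

- **Signed, not unsigned.**  After covariate adjustment the cohort mean
  is removed, so signature-carrying patients sit at `+(1−f)·δ` and
  signature-free patients at `−f·δ` along the signature profile δ (f =
  carrier fraction of the adjustment cohort).  The two groups are
  therefore *anti-correlated* (r ≈ −0.3 under the generator defaults)
  while the signature-free patients correlate only weakly with each
  other (r ≈ +0.17).  Unsigned adjacency `|r|^β` ranks the anti-correlation
  above the within-group similarity and merges the groups; the signed
  transform keeps them apart.
- **Ward, not average linkage.**  The near-control group is internally
  diffuse (weak mutual similarity); average linkage chains its members
  one by one onto the cohesive signature block, so a two-cluster cut
  splits off stragglers instead of the groups.  Ward's
  variance-minimizing criterion recovers the planted partition exactly
  (adjusted Rand index 1.0 across generator seeds).  Both alternatives
  remain selectable in `SubtypingConfig`.

Cluster naming: with a control reference, clusters are ordered by mean
Euclidean distance of their members' adjusted profiles to the control
centroid — the closest is "type 1" (near-control transcriptome), the
farthest "type 2".  Without a reference the more cohesive (higher mean
within-cluster TOM) cluster is "type 1".  Dynamic tree cutting is out of
scope; the number of clusters is a fixed parameter (default 2).

## Perturbation stability

Each cell of the covariate-adjusted matrix receives independent noise
uniform on ±(level·σ), where σ is by default the probe's own standard
deviation (`sd_scope="per_probe"`, keeping the perturbation
scale-equivariant across probes; a global-σ option exists).  The
clustering is repeated `n_runs` times (default 100) per level; run
clusters are aligned to the base clustering by maximum-overlap matching
(for two clusters, the identity-or-swap Hungarian assignment), and any
patient whose aligned label differs from the base label in ≥ 1 run is
relabelled "intermediate".  Levels are analysed independently with
seeds derived from one master seed.  Failed runs (degenerate clustering)
are excluded from the denominator and counted.

A planted *boundary* patient for testing is constructed at the point of
the segment joining the two subtype centroids with zero net signature
loading (zero projection onto the centroid difference).  That point —
not the Euclidean midpoint — is equidistant from both clusters in the
correlation geometry the clustering actually uses, and flips under
level-0.5 perturbation while well-separated patients do not.

## Threshold graphs

For a threshold grid, an edge joins patients with TOM ≥ t (closed
comparison, so t = 0 is the complete graph; a strict flag exists).
Connected components are computed per threshold (networkx) and
tabulated against the subtype labels: component count, sizes, label
composition and isolated-node count.  Component counts are monotone
non-decreasing and edge counts non-increasing in t; both are enforced as
checked postconditions, and components are verified in the tests against
a matrix-power reachability oracle.

## Per-subtype re-analysis

Each subtype is scanned against the controls with the same robust
mixed-effects model; "intermediate" patients are excluded from both
groups by default (a flag merges them in for sensitivity analysis).
Significance counts use Bonferroni or FDR at a stated α, with the
Bonferroni denominator the full filtered probe set.  The marker report
extracts the fitted rows for a configurable GABAergic marker list
(GAD1, LHX6, NPY, TAC1, VIP, SST, PVALB) per subtype; markers without
probes in the tested set are reported as not detected.

## Synthetic-data generator

`simulate_study` emulates: a control group and two latent schizophrenia
subtypes, where type 1 shares the control transcriptome except at
`n_de_type1` probes (default 4, a subset of the type-2 set) and type 2
differs at `n_de_type2` probes (default 200 of 2,000); covariate
structure (age ~ U(25, 80); sex with a male excess among controls,
echoing medical-examiner cohorts; ethnicity ~ Bernoulli(0.5);
RIN ~ N(8, 0.5) truncated to [5, 10]); per-probe batch random intercepts
(round-robin batch assignment, so no batch is empty and diagnosis is
balanced across batches); Gaussian noise (SD 0.5 log2 units) with a 2%
fraction of cells at ten-fold SD (heavy-tailed contamination); and a 5%
fraction of probes rendered undetected (detection p ≥ 0.05 in ~80% of
subjects).  Planted effects have magnitude ~ N(1.0, 0.2) log2 units and
balanced random signs (`effect_down_fraction = 0.5`): real DE signatures
mix up- and down-regulation, and a signed profile is what makes
signature carriers mutually correlated after the per-subject centring
inherent in Pearson correlation — an all-positive constant effect
carries no correlation signal at all.  Covariate effects are applied to
internally standardized covariates, so `covariate_effect_scale` is in
log2 units per covariate SD uniformly.

Not emulated: bead-level or idat-format data, RNAseq counts,
probe-sequence biology (SNP flags are random), circadian or brain-region
confounds, diagnosis-covariate confounding (covariates are drawn
independently of the subtype except for the sex/diagnosis imbalance),
and gene–gene co-expression modules (probes are independent given the
subject terms).  Passing tests therefore demonstrate the pipeline's
internal correctness and its behaviour under the generative assumptions
above — not performance on real cortex data, where effect-size spectra,
correlation structure and confounding are harsher.

## Default problem sizes

The bundled examples and the acceptance script use cohorts of 100
controls + 40 + 40 patients with 2,000 probes (calibration, recovery)
and 40 + 20 + 20 with 600 probes (stability), with 100 perturbation runs
per level — sizes at which every documented behaviour (calibration in
[0.03, 0.07], exact subtype recovery, ≥ 95% planted-probe recall,
boundary-subject relabelling) is reproducible in about a minute on one
CPU.  All counts, rates and scales are configuration fields; nothing in
the code depends on these particular sizes.

## Known limitations

- The robust mixed model is a pragmatic composite (Huber IRLS around a
  Henderson solve with an EM variance step), not a formally derived
  robust-REML estimator; its contract is behavioural — bounded
  influence, OLS equivalence in the clean single-batch limit — and is
  enforced by tests rather than theory.
- Wald inference ignores uncertainty in τ² and in the robust scale;
  fine at n in the hundreds, questionable for small cohorts.
- Probe→gene mapping is many-to-one via the annotation table; gene-level
  significance counts are distinct-gene counts over significant probes,
  with no probe aggregation model.
- The two-cluster cut is fixed, not selected by any gap statistic: the
  pipeline tests a two-subtype hypothesis, it does not discover the
  number of subtypes.
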