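# Methods

This note records the models, conventions, and parameter choices behind
`metimm`, and what the synthetic-data tests do and do not establish about
real cohorts.

## Consensus co-expression module discovery

Candidate metabolic genes (glycolysis and cholesterol-biosynthesis panels)
are clustered by resampled consensus hierarchical clustering:

* distance: `d(i, j) = 1 − ρ_s(i, j)`, Spearman rank correlation of the two
  genes across samples (average ranks at ties; a constant gene is an error,
  not a silent drop);
* linkage: Ward.D2, i.e. the Lance–Williams Ward update applied to the
  supplied (non-Euclidean) correlation distances, via
  `scipy.cluster.hierarchy.linkage(method="ward")` on the precomputed
  condensed matrix — the same behaviour as R's `hclust(..., "ward.D2")` on a
  precomputed distance;
* resampling: `reps = 100` repetitions, each drawing `⌈p_item·G⌉` genes
  (`p_item = 0.8`) and `⌈p_feature·n⌉` samples (`p_feature = 1`) without
  replacement from one seeded stream, cut at `k = 5`;
* consensus(i, j) = co-cluster count / co-sample count; pairs never
  co-sampled get 0 with a warning; the final partition cuts a Ward.D2 tree
  on 1 − consensus at k.  Only Ward.D2 is implemented for both the per-rep
  and the final cut.

Genes are canonicalized to sorted order before the subsample stream is
drawn, so results are invariant to input gene order, and the per-rep
subsample stream is exposed (`subsample_stream`) so the resampling
accounting can be tallied independently.

**Module selection.** From the k = 5 solution, each cluster of size ≥ 5 is
scored by the mean pairwise Spearman correlation of its members.
`select_coexpressed` returns the single best cluster (ties to the smaller
label).  The pipeline needs one module per pathway, so it additionally tags
each retained cluster by the majority pathway origin of its members
(glycolysis vs cholesterol candidate panel) and keeps the best-scoring
cluster per tag.  This selection rule is this package's own convention for
operationalizing "co-expressed": nothing canonical dictates how two modules
should be extracted from a five-cluster solution.

## Metabolic subtyping

Genes are z-scored across the cohort (mean 0, SD 1 per gene; constant genes
dropped with a warning) so that 0 anchors to cohort-average expression;
median centering and no centering are available alternatives.  Each
sample's glycolytic and cholesterol scores are the medians of its centered
module-gene values (even counts average the two central values).  The
quadrant rule then assigns quiescent (gly ≤ 0 and chol ≤ 0), glycolytic
(gly > 0 and gly > chol), or cholesterol (chol > 0 and chol > gly).  An
exact positive tie (gly = chol > 0) is genuinely outside the rule; it is
reported as `unclassified` with a warning rather than silently broken — a
measure-zero event for continuous scores.

## Signature scoring

**ssGSEA.** Per sample, genes are ranked by expression (average ranks at
ties).  Walking genes from highest to lowest expression, the enrichment
score is the summed difference between the in-set cumulative weight
(weights = rank statistic^α normalized to total 1 over set members) and the
out-of-set cumulative fraction.  α = 0.25; with normalization on (default),
all scores in a call are divided by one global (max − min) raw-score range.
Raw scores depend on a sample only through its within-sample ranks, so any
strictly monotone transform of one sample's profile leaves them unchanged.

**T-cell-inflamed (GEP) score.** Σ_g w_g · z_g(sample) over the 18-gene
panel with per-gene weights, where z is cohort z-scored expression.  The
weighted-sum-of-z form is the panel's usual convention; a zero-variance
signature gene is an error.

**ESTIMATE-style purity.** Stromal and immune scores are unnormalized
ssGSEA scores of the respective signatures; the combined score is their
sum, and purity = cos(0.6049872018 + 0.0001467884 · combined score), the
published calibration.  Purity outside [0, 1] (possible because the cosine
formula was calibrated on other platforms) is flagged, never clipped.

**ORA.** Hypergeometric upper tail P(X ≥ k) for the overlap of a query set
with each term, terms first intersected with the universe and filtered to
sizes in [5, 5000].  Significance is raw p ≤ 0.05 with BH q reported
alongside.

## Immune phenotype and strata

The GEP top-50% split assigns the ⌈n/2⌉ highest-scoring samples to
immuno-hot (ties break by sample-id lexicographic order, making the split
deterministic), computed **within EGFR-WT samples only** — the arithmetic
of an 881-sample WT cohort splitting 441/440 pins both the ⌈n/2⌉ convention
and the within-WT scope.  Strata: EGFR-mutant trumps phenotype; WT samples
split into WT-hot / WT-cold.

## Survival statistics

Kaplan–Meier product-limit curves (censoring shrinks the risk set without a
step) and the multi-group log-rank test are implemented directly: at each
distinct event time, observed events per group are compared with their
hypergeometric expectation; the statistic inverts the covariance of the
first G − 1 groups' O − E sums; df = G − 1.  Tied event times use the
standard hypergeometric-variance form; no tie-correction variants.  All
tests are two-sided.  Group comparisons: Student's t / Mann–Whitney U for
two groups, one-way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn (BH-adjusted
rank z statistics with tie correction) for more; Pearson's χ² without
continuity correction (flag available) for contingency tables.

## Meta-analysis

Inverse-variance pooling on the log-HR scale.  Published HR + 95% CI rows
convert via log_hr = ln(HR), se = (ln(U) − ln(L)) / (2 × 1.959964); the
two-sided 95% normal quantile 1.959964 is used for every CI conversion in
the package.  Fixed effects: w_i = 1/se_i².  Random effects:
DerSimonian–Laird τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) with re-weighting
w*_i = 1/(se_i² + τ²).  Q, df, and I² = max(0, (Q − df)/Q)·100 are always
reported from the fixed-effect weights.  CIs use normal quantiles (no
Knapp–Hartung).  Both models are always computed; random-DL is the primary
report, the usual choice for clinically heterogeneous observational
studies.  Subgroups are a study-level tag filter.  Egger's test regresses
the standardized effect (y_i/se_i) on precision (1/se_i) by OLS and tests
the intercept against t at k − 2 df; it requires k ≥ 3 and non-constant
standard errors.

## Synthetic cohorts: what they emulate

`generate_expression_cohort` plants, per sample:

* a metabolic subtype (quiescent / glycolytic / cholesterol, evenly
  assigned) with module activities of ±effect/2 — quiescent is low on both
  modules, the other two high on exactly their own module — plus a
  per-sample N(0, 0.5²) latent jitter shared by all genes of a module (this
  jitter is what makes module genes co-expressed rather than merely
  mean-shifted; 0.5 = half the default gene noise keeps planted labels
  recoverable at the stated effect sizes);
* an immune phenotype (hot/cold, ⌈n/2⌉ hot) shifting the 18 GEP panel genes
  by ±immune_effect/2 around a shared latent;
* gene values = per-gene baseline (N(6, 1), a log₂-like scale) + activity +
  N(0, noise_sd);
* an EGFR-mutant flag at probability 77/881 ≈ 0.087, independent of
  subtype;
* null survival columns (see below) from a derived sub-seed.

Defaults — module effect 3, immune effect 2, noise SD 1, 200 unstructured
noise genes plus every packaged signature's genes as additional noise — are
the package's standing study conditions: separated but noisy subtypes of
the kind the quadrant rule is meant for.  Strong-signal checks use effect 5.

`generate_survival_times` draws exponential event times at rate
baseline_rate · exp(group log-HR) — the simplest proportional-hazards-
consistent model, giving closed-form checks (median = ln 2 / λ) — with
independent censoring: with probability censor_prob the time is replaced by
Uniform(0, event time) and the event flag cleared.  Defaults
baseline_rate = 0.02/month (median ≈ 35 months, a realistic NSCLC OS
scale) and censor_prob = 0.3.

`generate_meta_studies` draws per-study truth θ_i = true_log_hr +
N(0, τ²), study sizes uniform on n_range, se_i = 2/√n_i (a stated
decreasing function of size, roughly the log-HR SE at a ~25% event
fraction), and observed effects θ_i + N(0, se_i²).

All generators are pure functions of their config including the seed:
repeated calls are bit-identical; sub-streams derive from one seeded
generator per call.

**What passing tests do not show.** The generators use Gaussian noise on a
log scale — no negative-binomial count noise, library-size or batch
effects, no copy-number/mutation structure, and module membership is known
and disjoint.  Calibration and recovery results therefore validate the
*algorithms* under the stated model, not the biological correctness of any
particular gene list on real tumors.  The packaged signature files are
synthetic stand-ins: plausible member genes of the public panels they
emulate, but not the original curated lists or weights.

## Numerical choices and degenerate inputs

* Ranks: average ranks at ties everywhere (Spearman, ssGSEA).
* ssGSEA normalization with a zero score range is skipped with a warning.
* Consensus entries for never-co-sampled pairs are 0 with a warning (not an
  error); Ward merge heights are monotone (nn-chain on a reducible method).
* χ² on a table with an all-zero row/column, log-rank with an empty group,
  pooling an empty (sub)set, Egger with k < 3 or constant se — all errors.
* DL τ² truncates at 0; with Q ≤ df the random-effects result equals the
  fixed-effect result exactly.
* Problem sizes in the calibration checks (1,000 null survival cohorts of
  n = 100; 2,000 simulated meta-analyses of k = 16; 200 ssGSEA toys;
  300-sample recovery cohorts) were chosen to keep Monte-Carlo error well
  below the tolerances being checked while remaining quick to rerun.

## Known limitations

* Only Ward.D2 linkage and Spearman distance are implemented for consensus
  clustering; no automatic choice of k (no PAC/elbow machinery).
* No Cox regression or multivariable adjustment; survival comparisons are
  unadjusted KM/log-rank by design.
* The ESTIMATE purity formula is applied to log-normalized RNA-Seq input as
  published even though it was calibrated on microarray data; out-of-range
  purity is flagged rather than corrected.
* Gene symbols match exactly (after whitespace trimming); no alias
  resolution — determinism is preferred over recall.
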