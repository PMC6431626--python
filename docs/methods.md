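# Methods

## Scope and model

`mirscreen` implements a biomarker discovery-and-validation pipeline for a
circulating miRNA in a case/control setting. The discovery arm operates on
microarray-style expression data and a literature-derived miRNA→mRNA
interaction network; the validation arm operates on plasma RT-qPCR
measurements in a three-group cohort (cases, healthy controls, disease
controls). Because the original external inputs (public expression series,
interaction database dumps, subject-level qPCR data) cannot be redistributed
or re-downloaded, a synthetic-data module defines the study conditions and
every analysis is exercised against it.

## Differential expression

Each feature is tested with a two-sample t-test between cases and controls.
The default is Welch's unequal-variance statistic; a pooled-variance Student
t is available via `equal_var=True`. On log2-scale matrices the fold change
is the difference of group means; on linear-scale input it is the log2 ratio
of group means, and features with a nonpositive group mean are flagged and
excluded. Features with zero variance in both groups are flagged degenerate
(t = 0, p = 1) and never enter a DE list.

Raw p-values are adjusted by Benjamini–Hochberg step-up (via
`statsmodels.stats.multitest`; an explicit sort/cumulative-min oracle lives
in the test suite). When a probe→gene map is supplied, probes are collapsed
to one row per gene *after* testing and *before* adjustment: the probe with
the smallest raw p wins, ties broken by larger |log2FC|, then lexicographic
probe id. Collapsing on raw p keeps the rule independent of the adjustment;
adjusting after collapsing controls the FDR over genes. Selection uses
strict inequalities: adjusted p < 0.05 and |log2FC| > 1. BH is applied
separately within the miRNA and mRNA datasets, which come from different
platforms.

## Reference and disease networks

Interaction records carry an evidence type (`validated_low_throughput`,
`validated_high_throughput`, `predicted`) and a source label. A (miRNA,
gene) pair is retained when it has at least one low-throughput validated
record, or predicted records from at least 2 of the 3 prediction databases.
Pairs supported only by high-throughput validation are dropped: low-
throughput validation is the stated false-positive guard, and anything
outside the two stated channels is conservatively excluded. The retention
rule is a union over channels, order-independent and idempotent.

The disease network maps the DE sets onto the reference. The default
`strict` mode keeps an edge only when both endpoints are DE — matching the
notion of a disease-specific miRNA–mRNA *pair* network — with an `either`
mode for sensitivity analysis. TF annotation travels on the gene records of
the edge list, keeping the input self-contained.

## Vulnerability screen

For each miRNA *m* in the disease network:

* `nsr = |single-line targets| / |targets|`, a single-line target being a
  gene with in-degree 1;
* `tsp` = TF fraction among the single-line targets (undefined, reported as
  0 with a flag, when there are none).

The null model is degree-preserving bipartite rewiring: each replicate
copies the observed edge list and applies 10·|E| double-edge swap attempts
(a proposed swap is rejected if it would duplicate an edge). Swaps preserve
every miRNA out-degree and every gene in-degree, so the scores' degree
structure is held fixed and the *set* of single-line genes is identical in
every replicate — only their attachment varies, which makes per-replicate
scoring O(|E|).

P-values are one-sided upper-tail with the small-sample correction
`(1 + #{null ≥ obs}) / (N + 1)`, hence in (0, 1]. The NSR p-value compares
single-line *counts* (same denominator as the observed ratio). The TSP
p-value compares the *count* of TF-annotated single-line targets, not the
fraction: with few single-line targets the fraction saturates — a null
replicate whose one single-line target happens to be a TF already reaches
fraction 1.0 — so a fraction-based p-value plateaus near 0.1 regardless of
how strong the observed TF enrichment is, while the count accumulates the
evidence. `tsp` itself is still reported as a fraction.

Candidates must clear both thresholds (default α = 0.05 each, requiring
enough permutations for p below α; the default N = 1000). Ranking is the
deterministic total order (p_nsr asc, p_tsp asc, nsr desc, id), so outputs
are reproducible and ties cannot reorder across runs.

## Validation statistics

Relative expression is 2^−ΔCt, ΔCt = Ct(target) − Ct(reference). Subjects
with a missing Ct are excluded listwise from expression analyses and kept
for demographics. Group summaries report n, mean, SEM (sample sd over √n),
and median; a singleton group reports SEM 0 with a warning. Percent ratios
are `round(100·mean_a/mean_b)`, half away from zero.

Two-group comparisons default to Mann–Whitney: exact enumeration when the
combined sample is ≤ 12 and tie-free, otherwise the normal approximation
with tie and continuity corrections; Welch's t is available. When more than
two groups are compared, Kruskal–Wallis (the nonparametric ANOVA) runs
first; no multiplicity correction is applied to pairwise p-values, matching
the reporting convention the cohort tables follow. Sex distributions use
Pearson chi-square without continuity correction; correlations use Spearman
rho with average ranks and the t approximation.

Stratified analyses: age bins [40, 59], [60, 69], [70, 79], [80, ∞) and
disease-duration bins [1, 3], [4, 6], [7, 20] are closed on both ends with
values binned by integer truncation; subjects outside all bins are excluded
with a logged count. Age and sex strata compare cases to each control group
within the stratum; duration, severity (Hoehn–Yahr) and medication are
case-only attributes, so each case stratum is compared to the whole
healthy-control group. Empty comparisons are reported as absent rather than
erroring.

## ROC evaluation

AUC is the rank statistic P(case > control) + ½P(tie) (midrank convention),
dual to Mann–Whitney U/(n₁n₀) to machine precision. The confidence interval
and the test against 0.5 use the DeLong placement-variance estimator with a
Wald interval clipped to [0, 1]; degenerate variance (perfect separation)
collapses the interval to a point with a warning. A stratified bootstrap is
deliberately not the default — DeLong matches the convention of the
epidemiological tooling this mirrors. Thresholds are all midpoints between
consecutive distinct scores plus ±∞ sentinels; subjects at or above the
threshold are called positive. Sensitivity and specificity carry exact
Clopper–Pearson intervals (beta-quantile form, closed forms at k = 0 and
k = n). The reported operating point maximises the Youden index, a choice
made here because no criterion is standard across tools.

## Synthetic data: what it emulates, and what it does not

**Expression matrices** are generated directly on the log2 scale (so fold
change is a mean difference): per-feature baselines uniform on [6, 12] log2
units, i.i.d. Gaussian noise (default sd 0.5), and a planted subset shifted
by the effect size (default 2.0 log2 units) in cases. Default shapes follow
the study design: 19 cases / 13 controls (miRNA arm) and 50 / 23 (mRNA
arm). Feature counts are not part of the published design; 300 and 1000 are
desk-scale defaults. Not emulated: probe-level artifacts, normalisation,
batch effects, inter-feature correlation. Passing recovery tests therefore
show the inference machinery is correct under the stated noise model, not
that real microarray preprocessing is handled.

**Interaction lists** contain one planted biomarker miRNA with (by default)
10 exclusively regulated targets TF-annotated at rate 0.8 against a 0.1
background, plus Poisson-degree background edges (mean 8 targets across 30
miRNAs and 90 genes). Half of the retainable pairs carry low-throughput
validation and half carry 2-of-3 predictions; 20% of background pairs carry
evidence the filter must drop. The gene pool is kept small relative to the
edge count so background genes are mostly shared — in a sparser world every
miRNA looks "unique" and the vulnerability signal disappears, which is also
why the pipeline's simulated DE fractions over network nodes default to
0.5 (miRNAs) and 0.6 (genes): the strict disease network then retains the
shared-regulation background the null needs.

**The plasma cohort** draws each subject's 2^−ΔCt from a log-normal
moment-matched to the published group mean ± SEM (population sd taken as
SEM·√n): `sigma² = ln(1 + (sd/mean)²)`, `mu = ln(mean) − sigma²/2`.
Log-normality is an assumption — positive support and right skew are all
the published summaries imply — not a published fact. The reference Ct is
drawn first (Normal, default 20 ± 1 cycles, a plausible housekeeping
signal) and the target Ct derived as `ct_ref − log2(expression)`, so the
Ct pair reconstructs the drawn expression exactly. The six small NDC
subdiagnosis groups without published expression rows are simulated at the
NDC-wide mean with the NDC-wide sd rescaled to their size. Ages are uniform
over mean ± sd of the published group ages; sex is Bernoulli at the
published ratios; IPD-only fields (duration uniform on [1, 20] years,
Hoehn–Yahr uniform on 1–5, medication at the published category
frequencies 80/91/85 with the unexplained remainder of 63 labelled
`none_recorded`) are drawn independently of expression. Real cohorts
correlate covariates with outcome; this generator deliberately does not,
so stratified analyses are calibrated under the null rather than
reproducing published subgroup effect sizes.

## Seeds and determinism

Every generator and every permutation test takes one explicit integer seed
(`numpy.random.default_rng`); there is no global state. The pipeline derives
stage seeds as master seed + stage index, so reports (excluding timestamps)
are byte-identical across reruns.

## Problem sizes

Simulation-backed checks run at desk scale: 100-seed batteries for cohort
reproduction, DE sensitivity/FDR, planted-biomarker recovery and null
candidate calibration; 200 permutations per screened network in those
batteries (1000 in single runs); 10⁶ draws for moment-matching
verification; 10⁴ replicates for interval coverage. These sizes put
Monte-Carlo error comfortably below the tested margins.

## Known limitations

* The published discovery-arm tallies (reference-network size, DE counts,
  cohort AUCs) depend on specific database and array versions and on
  unpublished subject-level data; they are out of reach by construction,
  and the suite verifies the machinery by property instead.
* The vulnerability score internals (NSR/TSP, thresholds, null) reconstruct
  a briefly described "unique regulatory activity" model; they are
  configurable because no published operationalisation exists to pin them.
* DeLong intervals are asymptotic; for very small groups the bootstrap
  alternative would be preferable.
* The Mann–Whitney exact branch is limited to combined n ≤ 12; beyond that
  the corrected normal approximation is used (checked against the exact
  branch exhaustively at the boundary).
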