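# mirscreen

Circulating microRNAs are attractive disease biomarkers: they are stable in
plasma, measurable by RT-qPCR, and dysregulated in many conditions, including
neurodegenerative disease. `mirscreen` implements a two-arm pipeline for
discovering and validating such a biomarker, modelled on studies of idiopathic
Parkinson's disease (IPD):

1. **Discovery arm — network vulnerability analysis.** Differentially
   expressed (DE) miRNAs and mRNAs are extracted from two-group expression
   matrices (per-feature Welch t-test, Benjamini–Hochberg FDR,
   most-significant-probe collapsing, adjusted p < 0.05 and |log2FC| > 1).
   An evidence-filtered miRNA→mRNA reference network is assembled from
   interaction records — a pair is kept if it has low-throughput experimental
   validation or appears in at least two of three prediction databases — and
   the DE sets induce a disease-specific subnetwork. Each miRNA *m* in that
   network is scored for regulatory uniqueness:

   - NSR(m) = |single-line targets of m| / |targets of m|, where a single-line
     target is a gene regulated by exactly one miRNA in the network;
   - TSP(m) = fraction of those single-line targets annotated as
     transcription factors.

   Both are referred to a degree-preserving rewiring null (double-edge swaps
   preserving all miRNA out-degrees and gene in-degrees), giving permutation
   p-values `p = (1 + #{null ≥ obs}) / (N + 1)`. miRNAs clearing both
   thresholds are biomarker candidates, ranked by (p_nsr, p_tsp, −NSR, id).

2. **Validation arm — plasma qPCR cohort.** Relative expression is
   2^−ΔCt with ΔCt = Ct(target) − Ct(miR-16 reference). The engine produces
   group summaries (mean ± SEM, median), Mann–Whitney/Welch comparisons with
   percent ratios of group means, chi-square demographics, Spearman
   correlations, stratified analyses (age bins, sex, disease duration,
   Hoehn–Yahr stage, medication), and ROC/AUC with DeLong confidence
   intervals plus exact Clopper–Pearson intervals for sensitivity and
   specificity.

A synthetic-data module generates every input: expression matrices with
planted DE structure, evidence-coded edge lists with a planted biomarker
miRNA, and a 897-subject cohort (319 IPD / 273 HC / 305 neurological disease
controls) whose per-group 2^−ΔCt distributions are log-normals
moment-matched to the published group summaries (IPD 0.163 ± 0.018,
HC 0.065 ± 0.011, NDC 0.047 ± 0.007).

## Worked example

```python
from mirscreen import (RunConfig, run_discovery, default_cohort_config,
                       generate_plasma_cohort, compare_groups, roc_analysis)

# validation arm at the published group parameters
subjects = generate_plasma_cohort(default_cohort_config(seed=1))
ipd = [s.expression for s in subjects if s.group == "IPD"]
hc = [s.expression for s in subjects if s.group == "HC"]
cmp_ = compare_groups(ipd, hc, label_a="IPD", label_b="HC")
print(cmp_.n_a, cmp_.mean_a, cmp_.p_two_sided, cmp_.ratio_percent)
roc = roc_analysis(ipd + hc, [True] * len(ipd) + [False] * len(hc))
print(roc.auc, roc.ci_low, roc.ci_high)

# discovery arm, fully synthetic
report = run_discovery(RunConfig(seed=1))
print(report.stages["screen"]["summary"]["candidates"])
```

With seed 1 this prints an IPD group of n=319 with sample mean 0.176
(target 0.163 ± 0.018), Mann–Whitney p ≈ 2.5 × 10⁻³⁴ and a sample percent
ratio of 362% (the ratio of the *configured* population means is 251%);
the ROC gives AUC 0.791 (95% CI 0.755–0.828). The discovery run builds a
reference network of 30 miRNAs / 87 genes / 207 pairs, finds 15 DE miRNAs
and 52 DE mRNAs, extracts a 14-miRNA disease network, and reports the
planted biomarker `miR-105-5p` as the single screened candidate.

Numbers for other seeds differ by sampling noise; every stage is
deterministic given its seed.

## Command line

```sh
mirscreen simulate cohort --seed 1 --out out/
mirscreen validate roc --cohort out/cohort.csv
mirscreen run-all --seed 1 --out out/
```

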