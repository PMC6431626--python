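"""Validation-arm statistics for the plasma qPCR cohort.

Relative expression is 2^-ΔCt with ΔCt = Ct(target) − Ct(reference miR-16).
Group summaries follow the reporting convention mean ± SEM plus median;
two-group comparisons default to the Mann–Whitney U-test (exact enumeration
for small tie-free samples, otherwise the normal approximation with tie and
continuity corrections), with Welch's t available. Demographics are
compared by Pearson chi-square (sex) and the stratified analyses rerun the
case/control comparison inside age, sex, disease-duration, severity and
medication strata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)

MANN_WHITNEY = "mann_whitney"
STUDENT_T = "student_t"
#: largest combined sample size for which the exact Mann–Whitney null is used
EXACT_MW_LIMIT = 12

AGE_BINS = [(40, 59), (60, 69), (70, 79), (80, math.inf)]
DURATION_BINS = [(1, 3), (4, 6), (7, 20)]


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^−ΔCt with ΔCt = target Ct − reference Ct."""
    if ct_target is None or ct_reference is None or \
            not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("both Ct values must be present and finite")
    return 2.0 ** (-(ct_target - ct_reference))


def cohort_expression(subjects: list[SubjectRecord]) -> tuple[dict[str, float], int]:
    """Per-subject relative expression; subjects with a missing Ct are
    excluded listwise with a logged count. Returns (id→value, n_excluded)."""
    values: dict[str, float] = {}
    excluded = 0
    for s in subjects:
        if s.ct_target is None or s.ct_reference is None:
            excluded += 1
            continue
        values[s.subject_id] = relative_expression(s.ct_target, s.ct_reference)
    if excluded:
        logger.info("%d subjects excluded from expression analyses (missing Ct)", excluded)
    return values, excluded


def group_summary(values) -> tuple[int, float, float, float]:
    """(n, mean, SEM, median); SEM uses the n−1 sample sd. n=1 gives SEM 0
    by convention (with a warning)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty group")
    if v.size == 1:
        logger.warning("group of size 1: SEM reported as 0 by convention")
        return 1, float(v[0]), 0.0, float(v[0])
    return (int(v.size), float(v.mean()),
            float(v.std(ddof=1) / math.sqrt(v.size)), float(np.median(v)))


def ratio_percent(mean_a: float, mean_b: float) -> int:
    """round(100·mean_a/mean_b), half away from zero."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    x = 100.0 * mean_a / mean_b
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    median_a: float
    mean_b: float
    sem_b: float
    median_b: float
    test_name: str
    statistic: float
    p_two_sided: float
    ratio_percent: int


def compare_groups(values_a, values_b, method: str = MANN_WHITNEY,
                   label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-sided two-group comparison with the reporting summary attached.

    Mann–Whitney uses exact enumeration when n_a+n_b <= 12 and there are no
    ties, otherwise the normal approximation with tie correction and
    continuity correction. ``student_t`` is Welch's t. Identical samples in
    both groups give p = 1.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    n_a, mean_a, sem_a, med_a = group_summary(a)
    n_b, mean_b, sem_b, med_b = group_summary(b)

    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
        if method == MANN_WHITNEY:
            stat = a.size * b.size / 2.0
    elif method == MANN_WHITNEY:
        ties = np.unique(pooled).size < pooled.size
        use_exact = (a.size + b.size) <= EXACT_MW_LIMIT and not ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if use_exact else "asymptotic",
                                 use_continuity=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == STUDENT_T:
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    return GroupComparison(
        group_a=label_a, group_b=label_b, n_a=n_a, n_b=n_b,
        mean_a=mean_a, sem_a=sem_a, median_a=med_a,
        mean_b=mean_b, sem_b=sem_b, median_b=med_b,
        test_name=method, statistic=stat, p_two_sided=min(p, 1.0),
        ratio_percent=ratio_percent(mean_a, mean_b),
    )


def mann_whitney_auc(values_a, values_b) -> float:
    """U/(n_a·n_b): the probability a random case outscores a random control
    (midrank tie convention). Dual to the ROC AUC."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    u = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic
    return float(u) / (a.size * b.size)


def kruskal_groups(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H and p over ≥2 groups (the nonparametric ANOVA run
    before pairwise tests when more than two groups are compared)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2 (df would be 0 otherwise)")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with the t-approximation p.
    Constant input yields (nan, nan) with a warning."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Stratified analyses

STRATIFIERS = ("age_bins", "sex", "duration_bins", "hy_stage", "medication")


@dataclass
class StratumComparison:
    stratifier: str
    stratum: str
    comparisons: dict[str, GroupComparison | None] = field(default_factory=dict)
    n_excluded: int = 0


def _bin_label(lo: float, hi: float) -> str:
    return f"{int(lo)}+" if math.isinf(hi) else f"{int(lo)}-{int(hi)}"


def _assign_bin(value: float | None, bins) -> str | None:
    """Closed-interval binning by integer truncation; None when outside."""
    if value is None:
        return None
    v = int(value)
    for lo, hi in bins:
        if lo <= v <= hi:
            return _bin_label(lo, hi)
    return None


def stratified_comparisons(subjects: list[SubjectRecord],
                           stratifier: str,
                           method: str = MANN_WHITNEY) -> list[StratumComparison]:
    """IPD-vs-control comparisons within each stratum.

    ``age_bins`` and ``sex`` stratify every group and compare IPD vs HC and
    IPD vs NDC within the stratum. ``duration_bins``, ``hy_stage`` and
    ``medication`` are IPD-only attributes: each IPD stratum is compared to
    the whole HC group. Subjects outside all bins are excluded with a logged
    count; empty comparisons are reported as absent (None).
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    expr, _ = cohort_expression(subjects)
    usable = [s for s in subjects if s.subject_id in expr]

    def values(subset) -> list[float]:
        return [expr[s.subject_id] for s in subset]

    hc_all = values([s for s in usable if s.group == "HC"])

    def key(s: SubjectRecord) -> str | None:
        if stratifier == "age_bins":
            return _assign_bin(s.age_years, AGE_BINS)
        if stratifier == "sex":
            return s.sex
        if s.group != "IPD":
            return None
        if stratifier == "duration_bins":
            return _assign_bin(s.duration_years, DURATION_BINS)
        if stratifier == "hy_stage":
            return None if s.hy_stage is None else str(s.hy_stage)
        return s.medication

    within_stratum_controls = stratifier in ("age_bins", "sex")
    strata: dict[str, list[SubjectRecord]] = {}
    n_excluded = 0
    for s in usable:
        if not within_stratum_controls and s.group != "IPD":
            continue
        k = key(s)
        if k is None:
            n_excluded += 1
            continue
        strata.setdefault(k, []).append(s)
    if n_excluded:
        logger.info("%d subjects fall outside every %s stratum", n_excluded, stratifier)

    results = []
    for stratum in sorted(strata):
        members = strata[stratum]
        ipd = values([s for s in members if s.group == "IPD"])
        comparisons: dict[str, GroupComparison | None] = {}
        if within_stratum_controls:
            for ctrl_group in ("HC", "NDC"):
                ctrl = values([s for s in members if s.group == ctrl_group])
                comparisons[f"IPD_vs_{ctrl_group}"] = (
                    compare_groups(ipd, ctrl, method=method, label_a="IPD", label_b=ctrl_group)
                    if ipd and ctrl else None
                )
        else:
            comparisons["IPD_vs_HC"] = (
                compare_groups(ipd, hc_all, method=method, label_a="IPD", label_b="HC")
                if ipd and hc_all else None
            )
        results.append(StratumComparison(stratifier=stratifier, stratum=stratum,
                                         comparisons=comparisons, n_excluded=n_excluded))
    return results


# ---------------------------------------------------------------------------
# Table-style reporting and I/O

def expression_table(subjects: list[SubjectRecord],
                     method: str = MANN_WHITNEY) -> pd.DataFrame:
    """Group/subgroup summary table with p-values vs HC and vs IPD."""
    expr, _ = cohort_expression(subjects)
    usable = [s for s in subjects if s.subject_id in expr]

    def values(pred) -> list[float]:
        return [expr[s.subject_id] for s in usable if pred(s)]

    hc = values(lambda s: s.group == "HC")
    ipd = values(lambda s: s.group == "IPD")

    rows = []
    blocks: list[tuple[str, str | None]] = [("HC", None), ("IPD", None), ("NDC", None)]
    subgroups = sorted({s.subgroup for s in usable if s.group == "NDC" and s.subgroup},
                       key=lambda sg: -len([s for s in usable
                                            if s.group == "NDC" and s.subgroup == sg]))
    blocks += [("NDC", sg) for sg in subgroups]
    for group, subgroup in blocks:
        if subgroup is None:
            vals = values(lambda s, g=group: s.group == g)
        else:
            vals = values(lambda s, g=group, sg=subgroup: s.group == g and s.subgroup == sg)
        if not vals:
            continue
        n, mean, sem, median = group_summary(vals)
        p_hc = None if group == "HC" else \
            compare_groups(vals, hc, method=method).p_two_sided
        p_ipd = None if group == "IPD" else \
            compare_groups(vals, ipd, method=method).p_two_sided
        rows.append({"group": group, "subgroup": subgroup or "", "n": n,
                     "mean": mean, "sem": sem, "median": median,
                     "p_vs_HC": p_hc, "p_vs_IPD": p_ipd})
    return pd.DataFrame(rows)


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)

    def opt(v, cast=float):
        return None if pd.isna(v) else cast(v)

    return [
        SubjectRecord(
            subject_id=str(r.subject_id), group=str(r.group),
            subgroup=opt(r.subgroup, str), sex=str(r.sex),
            age_years=float(r.age_years),
            duration_years=opt(r.duration_years),
            hy_stage=opt(r.hy_stage, lambda v: int(float(v))),
            medication=opt(r.medication, str),
            ct_target=opt(r.ct_target), ct_reference=opt(r.ct_reference),
            expression=(None if pd.isna(r.ct_target) or pd.isna(r.ct_reference)
                        else relative_expression(float(r.ct_target), float(r.ct_reference))),
        )
        for r in df.itertuples(index=False)
    ]
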