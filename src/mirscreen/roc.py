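"""ROC/AUC diagnostic evaluation with DeLong and exact binomial intervals.

AUC is the probability a random case outscores a random control (midrank
tie convention), computed from the rank statistic; its confidence interval
and the test against AUC = 0.5 use the DeLong placement-variance
estimator. Per-threshold sensitivity and specificity carry exact
Clopper–Pearson 95% intervals, and the reported operating point maximises
the Youden index J = sensitivity + specificity − 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    cases = scores[labels]
    controls = scores[~labels]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def auc(scores, labels) -> float:
    """P(score_case > score_control) + ½·P(equal), by the rank statistic.

    Orientation: cases are expected to score higher.
    """
    cases, controls = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    n1 = cases.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * controls.size))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """(auc, variance) via DeLong placement values."""
    n1, n0 = cases.size, controls.size
    # placement of each case among controls and vice versa (midrank ties)
    gt = (cases[:, None] > controls[None, :]).astype(float)
    eq = (cases[:, None] == controls[None, :])
    win = gt + 0.5 * eq
    v10 = win.mean(axis=1)
    v01 = win.mean(axis=0)
    a = float(v10.mean())
    var = 0.0
    if n1 > 1:
        var += v10.var(ddof=1) / n1
    if n0 > 1:
        var += v01.var(ddof=1) / n0
    return a, var


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """DeLong Wald interval clipped to [0, 1] and two-sided p for AUC = 0.5.

    Degenerate variance (e.g. perfect separation) collapses the interval to
    the point estimate with a warning; the p-value is then 0 for AUC ≠ 0.5
    and 1 at exactly 0.5.
    """
    cases, controls = _split(scores, labels)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("need at least 2 observations per class for a CI")
    a, var = _delong_variance(cases, controls)
    if var <= 0:
        logger.warning("degenerate DeLong variance (perfect separation?): CI collapses to a point")
        return a, a, (1.0 if a == 0.5 else 0.0)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2)
    lo = max(0.0, a - z * se)
    hi = min(1.0, a + z * se)
    p = 2 * stats.norm.sf(abs(a - 0.5) / se)
    return float(lo), float(hi), float(min(p, 1.0))


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact interval for a binomial proportion."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def roc_points(scores, labels, level: float = 0.95) -> pd.DataFrame:
    """Sensitivity/specificity at every midpoint threshold (±inf sentinels).

    A subject is called positive when its score is >= the threshold (cases
    score high). Each sensitivity/specificity carries its Clopper–Pearson
    interval.
    """
    cases, controls = _split(scores, labels)
    distinct = np.unique(np.concatenate([cases, controls]))
    mids = (distinct[:-1] + distinct[1:]) / 2 if distinct.size > 1 else np.array([])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    rows = []
    n1, n0 = cases.size, controls.size
    for t in thresholds:
        tp = int((cases >= t).sum())
        tn = int((controls < t).sum())
        sens, spec = tp / n1, tn / n0
        sens_ci = exact_binomial_ci(tp, n1, level)
        spec_ci = exact_binomial_ci(tn, n0, level)
        rows.append({"threshold": t, "sensitivity": sens, "specificity": spec,
                     "sens_ci_low": sens_ci[0], "sens_ci_high": sens_ci[1],
                     "spec_ci_low": spec_ci[0], "spec_ci_high": spec_ci[1]})
    return pd.DataFrame(rows)


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    points: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci": [self.ci_low, self.ci_high],
                "p": self.p_vs_half, "youden_threshold": self.youden_threshold,
                "sens": self.sensitivity, "spec": self.specificity,
                "sens_ci": list(self.sens_ci), "spec_ci": list(self.spec_ci)}


def roc_analysis(scores, labels, level: float = 0.95) -> ROCResult:
    """Full ROC report: AUC with DeLong CI and the Youden operating point."""
    a = auc(scores, labels)
    lo, hi, p = auc_ci(scores, labels, level)
    pts = roc_points(scores, labels, level)
    j = pts["sensitivity"] + pts["specificity"] - 1
    best = pts.iloc[int(j.to_numpy().argmax())]
    return ROCResult(
        auc=a, ci_low=lo, ci_high=hi, p_vs_half=p,
        youden_threshold=float(best["threshold"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        sens_ci=(float(best["sens_ci_low"]), float(best["sens_ci_high"])),
        spec_ci=(float(best["spec_ci_low"]), float(best["spec_ci_high"])),
        points=pts,
    )
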