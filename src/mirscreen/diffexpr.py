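"""Two-group differential expression for microarray-style matrices.

The discovery arm starts from log2-scale expression matrices (features in
rows, samples in columns) with a binary case/control design. Each feature
is tested with a two-sample t-test (Welch by default), raw p-values are
adjusted with the Benjamini–Hochberg step-up procedure, probes mapping to
the same gene are collapsed to the most significant probe, and features
are called differentially expressed when adjusted p < 0.05 and
|log2 fold change| > 1 (both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: default selection cut-offs (adjusted p strictly below, |log2FC| strictly above)
DEFAULT_ALPHA = 0.05
DEFAULT_LFC_CUTOFF = 1.0


@dataclass
class ExpressionMatrix:
    """A features × samples expression matrix with a two-group design.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique row and column identifiers.
    values
        2-D array, shape ``(n_features, n_samples)``.
    condition
        Per-sample label, each ``"case"`` or ``"control"``.
    scale_flag
        ``"log2"`` (microarray convention; fold change is a mean difference)
        or ``"linear"`` (fold change is a log-ratio of group means).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: list[str]
    scale_flag: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.scale_flag not in ("log2", "linear"):
            raise ValueError(f"scale_flag must be 'log2' or 'linear', got {self.scale_flag!r}")
        bad = set(self.condition) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        cond = np.asarray(self.condition)
        if (cond == CASE).sum() < 2 or (cond == CONTROL).sum() < 2:
            raise ValueError("need at least 2 samples per condition")

    @property
    def case_mask(self) -> np.ndarray:
        return np.asarray(self.condition) == CASE

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def read_expression_matrix(matrix_tsv: str | Path, conditions_tsv: str | Path,
                           scale_flag: str = "log2") -> ExpressionMatrix:
    """Read the TSV dialect written by :mod:`mirscreen.synthetic`.

    ``matrix_tsv``: features in rows, first column feature id, header sample ids.
    ``conditions_tsv``: two columns ``sample_id``, ``condition`` (no header required
    beyond those names).
    """
    mat = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_tsv, sep="\t")
    cond_map = dict(zip(cond["sample_id"].astype(str), cond["condition"]))
    missing = [s for s in mat.columns if s not in cond_map]
    if missing:
        raise ValueError(f"samples without a condition label: {missing[:5]}")
    return ExpressionMatrix(
        feature_ids=[str(f) for f in mat.index],
        sample_ids=[str(s) for s in mat.columns],
        values=mat.to_numpy(dtype=float),
        condition=[cond_map[str(s)] for s in mat.columns],
        scale_flag=scale_flag,
    )


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe→gene TSV (columns ``probe_id``, ``gene_id``)."""
    df = pd.read_csv(path, sep="\t")
    if df["probe_id"].duplicated().any():
        raise ValueError("probe map contains duplicated probe ids")
    return dict(zip(df["probe_id"].astype(str), df["gene_id"].astype(str)))


def feature_t_test(matrix: ExpressionMatrix, equal_var: bool = False) -> pd.DataFrame:
    """Per-feature two-sample t-test (Welch unless ``equal_var``).

    Returns a DataFrame with columns ``feature_id``, ``log2_fold_change``,
    ``t_statistic``, ``raw_p``, ``degenerate``. Fold change is
    case mean − control mean on the log2 scale, or log2 of the ratio of group
    means for linear-scale input. Features with zero variance in both groups
    (and, on the linear scale, nonpositive group means) are flagged degenerate
    with t = 0 and p = 1; they never enter a DE list.
    """
    case = matrix.values[:, matrix.case_mask]
    ctrl = matrix.values[:, ~matrix.case_mask]
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)

    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)

    if matrix.scale_flag == "log2":
        lfc = mean_case - mean_ctrl
    else:
        nonpos = (mean_case <= 0) | (mean_ctrl <= 0)
        if nonpos.any():
            logger.warning("%d linear-scale features with nonpositive group mean flagged degenerate",
                           int(nonpos.sum()))
        degenerate = degenerate | nonpos
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(mean_case / mean_ctrl)
        lfc = np.where(nonpos, 0.0, lfc)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    # zero variance in one group only: scipy yields inf t / p=0, which is fine

    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "log2_fold_change": lfc,
        "t_statistic": t,
        "raw_p": p,
        "degenerate": degenerate,
    })


def bh_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order preserved.

    Guarantees elementwise ``adj_p >= raw_p`` and ``adj_p <= 1``; raises on
    values outside [0, 1].
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def collapse_probes(results: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level results to one row per gene.

    Keeps the probe with the smallest raw p; ties broken by larger
    |log2 fold change|, then lexicographically smaller probe id. Probes absent
    from the map pass through keyed by their own id (with a logged warning).
    The retained probe id is kept in a ``probe_id`` column and ``feature_id``
    becomes the gene id.
    """
    if results.empty:
        out = results.copy()
        out["probe_id"] = pd.Series(dtype=str)
        return out
    df = results.copy()
    df["probe_id"] = df["feature_id"]
    unmapped = ~df["feature_id"].isin(probe_map)
    if unmapped.any():
        logger.warning("%d probes not in the probe map pass through unmapped", int(unmapped.sum()))
    df["gene_id"] = df["feature_id"].map(lambda f: probe_map.get(f, f))
    df = df.sort_values(
        by=["raw_p", "log2_fold_change", "probe_id"],
        key=lambda col: -col.abs() if col.name == "log2_fold_change" else col,
    )
    df = df.drop_duplicates(subset="gene_id", keep="first")
    df["feature_id"] = df["gene_id"]
    return df.drop(columns="gene_id").sort_index().reset_index(drop=True)


def select_de(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
              lfc_cutoff: float = DEFAULT_LFC_CUTOFF) -> list[str]:
    """Features with ``adj_p < alpha`` and ``|log2FC| > lfc_cutoff`` (strict)."""
    keep = (
        (results["adj_p"] < alpha)
        & (results["log2_fold_change"].abs() > lfc_cutoff)
        & ~results["degenerate"]
    )
    return list(results.loc[keep, "feature_id"])


def differential_expression(matrix: ExpressionMatrix,
                            probe_map: Mapping[str, str] | None = None,
                            alpha: float = DEFAULT_ALPHA,
                            lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
                            equal_var: bool = False) -> pd.DataFrame:
    """Full DE table: test, collapse (if a probe map is given), adjust, select.

    BH adjustment is applied after probe collapsing so the FDR is controlled
    over genes, and collapsing uses raw p so it does not depend on the
    adjustment. Returns the collapsed table with ``adj_p`` and ``is_de``.
    """
    res = feature_t_test(matrix, equal_var=equal_var)
    if probe_map is not None:
        res = collapse_probes(res, probe_map)
    res = res.copy()
    res["adj_p"] = bh_adjust(res["raw_p"].to_numpy())
    res["is_de"] = (
        (res["adj_p"] < alpha)
        & (res["log2_fold_change"].abs() > lfc_cutoff)
        & ~res["degenerate"]
    )
    return res


def write_de_table(results: pd.DataFrame, path: str | Path) -> None:
    cols = ["feature_id", "log2_fold_change", "t_statistic", "raw_p", "adj_p", "is_de"]
    results[[c for c in cols if c in results.columns]].to_csv(path, sep="\t", index=False)
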