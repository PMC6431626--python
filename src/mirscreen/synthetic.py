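"""Synthetic inputs for both arms of the biomarker study.

Three generators stand in for the data the real study drew from public
repositories and a hospital cohort:

* two-group log2-scale expression matrices with a planted differentially
  expressed subset (microarray stand-in; default shapes 19 PD / 13 HC for
  the miRNA matrix and 50 PD / 23 HC for the mRNA matrix);
* an evidence-coded miRNA→gene interaction list with one planted biomarker
  miRNA given exclusively regulated, TF-enriched targets (interaction
  database stand-in);
* a plasma qPCR cohort whose per-group relative-expression (2^-ΔCt)
  distributions are log-normals moment-matched to the published group
  mean ± SEM summaries, with demographics drawn at the published ratios.

All randomness flows from one explicit integer seed per call; there is no
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import CASE, CONTROL, ExpressionMatrix
from .netbuild import EvidenceEdge, PREDICTED, VALIDATED_HIGH, VALIDATED_LOW

# ---------------------------------------------------------------------------
# Study-condition constants (group sizes and summaries from the validation
# cohort's published tables; used as generator defaults)

#: (group, subgroup, n, mean of 2^-dCt, SEM of 2^-dCt); subgroup None = whole group
TABLE_GROUPS: list[tuple[str, str | None, int, float, float]] = [
    ("IPD", None, 319, 0.163, 0.018),
    ("HC", None, 273, 0.065, 0.011),
    ("NDC", "epilepsy", 69, 0.031, 0.009),
    ("NDC", "cerebrovascular_disease", 57, 0.028, 0.008),
    ("NDC", "alzheimers_disease", 49, 0.035, 0.013),
    ("NDC", "parkinsonian_syndrome", 47, 0.053, 0.012),
    ("NDC", "essential_tremor", 22, 0.069, 0.051),
    ("NDC", "myasthenia_gravis", 14, 0.020, 0.014),
    ("NDC", "motor_neuron_disease", 14, 0.031, 0.011),
    ("NDC", "peripheral_neuropathy", 11, 0.074, 0.039),
]

#: NDC whole-group summary; subgroups without a published expression row are
#: simulated at this mean with the group-level sd held fixed (sem rescaled to n)
NDC_OVERALL = (305, 0.047, 0.007)

#: NDC subdiagnoses enumerated in the study without their own expression row
NDC_UNREPORTED_SUBGROUPS: list[tuple[str, int]] = [
    ("dementia", 7),
    ("restless_legs_syndrome", 6),
    ("migraine", 3),
    ("multiple_sclerosis", 3),
    ("myelopathy", 2),
    ("chorea_minor", 1),
]

#: per-group (male count, female count) and age mean ± sd in years
DEMOGRAPHICS: dict[str, dict] = {
    "HC": {"sex": (147, 126), "age": (68.3, 9.6)},
    "IPD": {"sex": (176, 143), "age": (67.6, 9.6)},
    "NDC": {"sex": (166, 139), "age": (63.6, 14.7)},
}

#: IPD medication state counts (naive / L-dopa / L-dopa + dopamine-receptor
#: agonist); the remainder of the 319 patients carries no recorded state
MEDICATION_COUNTS = {"naive": 80, "l_dopa": 91, "l_dopa_plus_dr": 85, "none_recorded": 63}

VALIDATED_SOURCE_NAMES = ("miRTarBase", "TarBase", "miRecords", "miR2Disease")
PREDICTED_SOURCE_NAMES = ("HOCTAR", "ExprTargetDB", "starBase")


# ---------------------------------------------------------------------------
# Configs

@dataclass
class ExpressionSimConfig:
    """Two-group log2-scale matrix with a planted DE subset."""

    n_features: int = 300
    n_cases: int = 19
    n_controls: int = 13
    de_fraction: float = 0.1
    de_log2_effect: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_features < 1:
            raise ValueError("need at least one feature")


def mirna_expression_config(seed: int = 0, **overrides) -> ExpressionSimConfig:
    """Default miRNA matrix shape: 19 cases / 13 controls."""
    kwargs = {"n_features": 300, "n_cases": 19, "n_controls": 13, "seed": seed}
    kwargs.update(overrides)
    return ExpressionSimConfig(**kwargs)


def mrna_expression_config(seed: int = 0, **overrides) -> ExpressionSimConfig:
    """Default mRNA matrix shape: 50 cases / 23 controls."""
    kwargs = {"n_features": 1000, "n_cases": 50, "n_controls": 23, "seed": seed}
    kwargs.update(overrides)
    return ExpressionSimConfig(**kwargs)


@dataclass
class NetworkSimConfig:
    """Evidence-coded interaction list with one planted biomarker miRNA."""

    n_mirnas: int = 30
    n_genes: int = 90
    mean_targets_per_mirna: float = 8.0
    tf_fraction: float = 0.1
    planted_biomarker_id: str = "miR-105-5p"
    planted_single_line_count: int = 10
    planted_tf_enrichment: float = 0.8
    validated_sources: tuple[str, ...] = VALIDATED_SOURCE_NAMES
    predicted_sources: tuple[str, ...] = PREDICTED_SOURCE_NAMES
    #: fraction of background pairs emitted with evidence the filter drops
    droppable_fraction: float = 0.2
    #: when False the planted miRNA regulates only its exclusive targets
    planted_background_targets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_single_line_count > self.n_genes:
            raise ValueError("planted_single_line_count cannot exceed n_genes")
        if len(self.predicted_sources) != 3:
            raise ValueError("exactly 3 prediction databases are required (2-of-3 rule)")
        if len(self.validated_sources) < 1:
            raise ValueError("at least one validated-type source label is required")
        if self.mean_targets_per_mirna <= 0:
            raise ValueError("mean_targets_per_mirna must be positive")
        for name, v in (("tf_fraction", self.tf_fraction),
                        ("planted_tf_enrichment", self.planted_tf_enrichment),
                        ("droppable_fraction", self.droppable_fraction)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroupSpec:
    """One cohort group (or subdiagnosis) with its target 2^-ΔCt moments."""

    group: str
    subgroup: str | None
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.mean <= 0:
            raise ValueError("target mean must be positive")
        if self.sem < 0:
            raise ValueError("target SEM must be nonnegative")


@dataclass
class CohortSimConfig:
    """Plasma qPCR cohort generator settings."""

    group_specs: list[GroupSpec]
    reference_ct_mean: float = 20.0
    reference_ct_sd: float = 1.0
    #: per top-level group, (low, high) age range in years (uniform draw)
    age_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: per top-level group, probability a subject is male
    sex_male_prob: dict[str, float] = field(default_factory=dict)
    #: fraction of subjects whose Ct pair is emitted missing
    missing_ct_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_specs:
            raise ValueError("at least one group spec is required")
        if self.reference_ct_sd < 0:
            raise ValueError("reference_ct_sd must be nonnegative")
        if not (0 <= self.missing_ct_rate < 1):
            raise ValueError("missing_ct_rate must lie in [0, 1)")


def default_cohort_config(seed: int = 0, missing_ct_rate: float = 0.0) -> CohortSimConfig:
    """The published study conditions: 319 IPD / 273 HC / 305 NDC.

    NDC subdiagnoses with a published expression row use it directly; the six
    enumerated subdiagnoses without one are generated at the NDC-wide mean
    with the NDC-wide sd (SEM rescaled to the subgroup size).
    """
    specs = [GroupSpec(g, sg, n, m, s) for g, sg, n, m, s in TABLE_GROUPS]
    n_ndc, ndc_mean, ndc_sem = NDC_OVERALL
    ndc_sd = ndc_sem * math.sqrt(n_ndc)
    for name, n in NDC_UNREPORTED_SUBGROUPS:
        specs.append(GroupSpec("NDC", name, n, ndc_mean, ndc_sd / math.sqrt(n)))
    age_ranges = {}
    sex_male_prob = {}
    for group, d in DEMOGRAPHICS.items():
        mean, sd = d["age"]
        age_ranges[group] = (mean - sd, mean + sd)
        male, female = d["sex"]
        sex_male_prob[group] = male / (male + female)
    return CohortSimConfig(group_specs=specs, age_ranges=age_ranges,
                           sex_male_prob=sex_male_prob,
                           missing_ct_rate=missing_ct_rate, seed=seed)


# ---------------------------------------------------------------------------
# Log-normal moment matching

@dataclass(frozen=True)
class LogNormalParams:
    """Log-scale location and shape of a log-normal distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma ** 2 / 2)

    @property
    def sd(self) -> float:
        s2 = self.sigma ** 2
        return math.sqrt((math.exp(s2) - 1)) * math.exp(self.mu + s2 / 2)


def lognormal_params_from_mean_sem(mean: float, sem: float, n: int) -> LogNormalParams:
    """Log-normal parameters whose population mean and sd match a printed
    ``mean ± SEM`` summary of a sample of size ``n`` (sd = SEM·√n).

    Closed form: ``sigma² = ln(1 + (sd/mean)²)``, ``mu = ln(mean) − sigma²/2``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sem < 0:
        raise ValueError("sem must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    sd = sem * math.sqrt(n)
    sigma2 = math.log1p((sd / mean) ** 2)
    return LogNormalParams(mu=math.log(mean) - sigma2 / 2, sigma=math.sqrt(sigma2))


# ---------------------------------------------------------------------------
# Expression matrices

def generate_expression_dataset(
    config: ExpressionSimConfig,
    feature_ids: Sequence[str] | None = None,
    planted_features: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Log2-scale matrix with ``round(de_fraction * n_features)`` planted
    case-shifted features.

    Per-feature baselines are uniform on [6, 12] log2 units (typical
    microarray intensity range); every value carries i.i.d. Gaussian noise of
    sd ``noise_sd``; planted features are shifted by ``de_log2_effect`` in
    cases. ``feature_ids`` overrides the default naming (``F0001`` …) and
    ``planted_features`` forces specific ids into the planted set (the rest
    is filled up at random).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    if feature_ids is None:
        feature_ids = [f"F{i:04d}" for i in range(1, n + 1)]
    else:
        feature_ids = [str(f) for f in feature_ids]
        if len(feature_ids) != n:
            raise ValueError("feature_ids length must equal n_features")

    n_planted = round(config.de_fraction * n)
    forced = list(planted_features or [])
    unknown = set(forced) - set(feature_ids)
    if unknown:
        raise ValueError(f"planted_features not among feature_ids: {sorted(unknown)[:5]}")
    if len(forced) > n_planted:
        n_planted = len(forced)
    pool = [f for f in feature_ids if f not in set(forced)]
    extra = rng.choice(len(pool), size=n_planted - len(forced), replace=False) if n_planted > len(forced) else []
    planted = sorted(set(forced) | {pool[i] for i in np.asarray(extra, dtype=int)})

    n_samples = config.n_cases + config.n_controls
    baseline = rng.uniform(6.0, 12.0, size=n)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n, n_samples))
    planted_idx = [feature_ids.index(f) for f in planted]
    values[np.asarray(planted_idx, dtype=int)[:, None], :config.n_cases] += config.de_log2_effect

    sample_ids = [f"case{i:02d}" for i in range(1, config.n_cases + 1)] + \
                 [f"ctrl{i:02d}" for i in range(1, config.n_controls + 1)]
    condition = [CASE] * config.n_cases + [CONTROL] * config.n_controls
    matrix = ExpressionMatrix(feature_ids=list(feature_ids), sample_ids=sample_ids,
                              values=values, condition=condition, scale_flag="log2")
    return matrix, planted


# ---------------------------------------------------------------------------
# Reference edge list

def generate_reference_edges(config: NetworkSimConfig) -> list[EvidenceEdge]:
    """Evidence-coded interaction records with one planted biomarker miRNA.

    The planted miRNA receives ``planted_single_line_count`` exclusive targets
    (genes no other miRNA touches) that are TF-annotated at
    ``planted_tf_enrichment``, plus ordinary background targets. Every planted
    edge carries evidence the retention rule keeps; background pairs carry a
    mix of retainable and droppable evidence so the filter has work to do.
    """
    rng = np.random.default_rng(config.seed)
    mirna_ids = [config.planted_biomarker_id] + [
        f"miR-{i:03d}" for i in range(1, config.n_mirnas)
    ]
    gene_ids = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]

    k = config.planted_single_line_count
    exclusive = gene_ids[:k]            # reserved for the planted miRNA
    background_pool = gene_ids[k:]
    if not background_pool:
        raise ValueError("n_genes leaves no background gene pool")

    is_tf = {g: bool(rng.random() < config.tf_fraction) for g in gene_ids}
    for g in exclusive:
        is_tf[g] = bool(rng.random() < config.planted_tf_enrichment)

    records: list[EvidenceEdge] = []

    def emit(mirna: str, gene: str, retainable: bool) -> None:
        """Emit the evidence records for one (mirna, gene) pair."""
        if retainable:
            if rng.random() < 0.5:
                source = config.validated_sources[rng.integers(len(config.validated_sources))]
                records.append(EvidenceEdge(mirna, gene, VALIDATED_LOW, source, is_tf[gene]))
            else:
                n_src = 2 if rng.random() < 0.7 else 3
                srcs = rng.choice(3, size=n_src, replace=False)
                for s in srcs:
                    records.append(EvidenceEdge(mirna, gene, PREDICTED,
                                                config.predicted_sources[s], is_tf[gene]))
        else:
            if rng.random() < 0.5:
                source = config.validated_sources[rng.integers(len(config.validated_sources))]
                records.append(EvidenceEdge(mirna, gene, VALIDATED_HIGH, source, is_tf[gene]))
            else:
                s = rng.integers(3)
                records.append(EvidenceEdge(mirna, gene, PREDICTED,
                                            config.predicted_sources[s], is_tf[gene]))

    for g in exclusive:
        emit(config.planted_biomarker_id, g, retainable=True)

    for mirna in mirna_ids:
        if mirna == config.planted_biomarker_id and not config.planted_background_targets:
            continue
        deg = max(1, int(rng.poisson(config.mean_targets_per_mirna)))
        deg = min(deg, len(background_pool))
        targets = rng.choice(len(background_pool), size=deg, replace=False)
        for t in targets:
            gene = background_pool[int(t)]
            retain = bool(rng.random() >= config.droppable_fraction)
            # the planted miRNA's background edges are ordinary in every way
            emit(mirna, gene, retainable=retain)

    return records


# ---------------------------------------------------------------------------
# Plasma cohort

@dataclass
class SubjectRecord:
    """One cohort participant with a target/reference Ct pair."""

    subject_id: str
    group: str
    subgroup: str | None
    sex: str
    age_years: float
    duration_years: float | None
    hy_stage: int | None
    medication: str | None
    ct_target: float | None
    ct_reference: float | None
    #: the drawn relative expression 2^-(ct_target - ct_reference)
    expression: float | None


def generate_plasma_cohort(config: CohortSimConfig) -> list[SubjectRecord]:
    """Draw one subject list per the config's group specs.

    Each subject's relative expression is a draw from the log-normal
    moment-matched to the group's mean ± SEM; the reference Ct is a plausible
    housekeeping signal (Normal around ``reference_ct_mean``) and the target
    Ct is derived so that ``2^(ct_reference − ct_target)`` reproduces the
    drawn expression exactly.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    med_labels = list(MEDICATION_COUNTS)
    med_probs = np.array(list(MEDICATION_COUNTS.values()), dtype=float)
    med_probs /= med_probs.sum()
    idx = 0
    for spec in config.group_specs:
        params = lognormal_params_from_mean_sem(spec.mean, spec.sem, spec.n)
        lo, hi = config.age_ranges.get(spec.group, (40.0, 85.0))
        p_male = config.sex_male_prob.get(spec.group, 0.5)
        for _ in range(spec.n):
            idx += 1
            expr = float(rng.lognormal(params.mu, params.sigma)) if params.sigma > 0 \
                else params.mean
            ct_ref = float(rng.normal(config.reference_ct_mean, config.reference_ct_sd))
            ct_tgt = ct_ref - math.log2(expr)
            missing = bool(rng.random() < config.missing_ct_rate)
            if spec.group == "IPD":
                duration = float(rng.uniform(1.0, 20.0))
                hy = int(rng.integers(1, 6))
                medication = med_labels[int(rng.choice(len(med_labels), p=med_probs))]
            else:
                duration, hy, medication = None, None, None
            records.append(SubjectRecord(
                subject_id=f"S{idx:04d}",
                group=spec.group,
                subgroup=spec.subgroup,
                sex="male" if rng.random() < p_male else "female",
                age_years=float(rng.uniform(lo, hi)),
                duration_years=duration,
                hy_stage=hy,
                medication=medication,
                ct_target=None if missing else ct_tgt,
                ct_reference=None if missing else ct_ref,
                expression=None if missing else expr,
            ))
    return records


# ---------------------------------------------------------------------------
# Writers (TSV/CSV dialects shared with the reader modules)

def write_expression_matrix(matrix: ExpressionMatrix, out_dir: str | Path,
                            prefix: str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_path = out_dir / f"{prefix}_matrix.tsv"
    cond_path = out_dir / f"{prefix}_conditions.tsv"
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample_id": matrix.sample_ids, "condition": matrix.condition}) \
        .to_csv(cond_path, sep="\t", index=False)
    return matrix_path, cond_path


def write_edges_tsv(edges: list[EvidenceEdge], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        {"mirna_id": e.mirna_id, "gene_id": e.gene_id, "evidence_type": e.evidence_type,
         "source": e.source, "gene_is_tf": int(e.gene_is_tf)}
        for e in edges
    ]).to_csv(path, sep="\t", index=False)
    return path


COHORT_COLUMNS = ["subject_id", "group", "subgroup", "sex", "age_years",
                  "duration_years", "hy_stage", "medication", "ct_target", "ct_reference"]


def write_cohort_csv(records: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        {c: getattr(r, c) for c in COHORT_COLUMNS} for r in records
    ]).to_csv(path, index=False)
    return path
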