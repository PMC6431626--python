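"""End-to-end orchestration of the discovery and validation arms.

Discovery: simulate (or load) expression matrices and the interaction edge
list → differential expression → evidence-filtered reference network →
disease-specific subnetwork → vulnerability screen → ROC of the top
candidate's expression on the discovery matrix.

Validation: simulate (or load) the plasma cohort → group summary table
with pairwise tests and percent ratios → demographics → the five
stratified analyses → ROC of IPD vs HC and vs each sizeable NDC
subdiagnosis.

One master seed drives everything; each stage derives its own seed as
``master + stage index`` so stages are reproducible independently.
Reports serialise to JSON; the payload excluding timestamps is
byte-identical across reruns of the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import cohort as cohort_mod
from . import diffexpr, netbuild, roc, screen, synthetic

logger = logging.getLogger(__name__)

DONE, SKIPPED, FAILED = "done", "skipped", "failed"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    # discovery inputs; any left None is simulated
    edges_tsv: str | None = None
    mirna_matrix: str | None = None
    mirna_conditions: str | None = None
    mrna_matrix: str | None = None
    mrna_conditions: str | None = None
    probe_map: str | None = None
    # validation input; None is simulated at the published group parameters
    cohort_csv: str | None = None
    # stage parameters
    de_alpha: float = diffexpr.DEFAULT_ALPHA
    de_lfc_cutoff: float = diffexpr.DEFAULT_LFC_CUTOFF
    network_mode: str = "strict"
    min_predicted_sources: int = 2
    screen_permutations: int = screen.DEFAULT_N_PERMUTATIONS
    alpha_nsr: float = 0.05
    alpha_tsp: float = 0.05
    # simulation-only knobs: planted DE rates among network nodes; high
    # enough that the strict disease network keeps its shared structure
    sim_de_mirna_fraction: float = 0.5
    sim_de_gene_fraction: float = 0.6

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_FLOAT_KEYS = {"de_alpha", "de_lfc_cutoff", "alpha_nsr", "alpha_tsp",
               "sim_de_mirna_fraction", "sim_de_gene_fraction"}
_INT_KEYS = {"seed", "min_predicted_sources", "screen_permutations"}


def parse_flat_config(path: str | Path) -> RunConfig:
    """Read the flat ``key = value`` config dialect ('#' starts a comment)."""
    values: dict[str, object] = {}
    known = set(RunConfig.__dataclass_fields__)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in _FLOAT_KEYS:
            values[key] = float(value)
        elif key in _INT_KEYS:
            values[key] = int(value)
        else:
            values[key] = value
    return RunConfig(**values)


@dataclass
class RunReport:
    arm: str
    seed: int
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    timestamp: str = ""

    def stage(self, name: str, status: str, **summary) -> None:
        self.stages[name] = {"status": status, "summary": summary}

    def payload(self, include_timestamp: bool = False) -> dict:
        d = {"arm": self.arm, "seed": self.seed, "config_hash": self.config_hash,
             "version": self.version, "stages": self.stages}
        if include_timestamp:
            d["timestamp"] = self.timestamp
        return d

    @property
    def failed(self) -> bool:
        return any(s["status"] == FAILED for s in self.stages.values())

    def write(self, out_dir: str | Path, name: str) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"{name}.json"
        path.write_text(json.dumps(self.payload(include_timestamp=True),
                                   indent=2, default=_jsonable))
        return path


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------------------
# Discovery arm

def run_discovery(config: RunConfig) -> RunReport:
    report = RunReport(arm="discovery", seed=config.seed,
                       config_hash=config.config_hash(), version=__version__,
                       timestamp=_now())
    seed = config.seed

    # stage 1: interaction edge list
    t0 = time.perf_counter()
    try:
        if config.edges_tsv:
            edges = netbuild.read_edges_tsv(config.edges_tsv)
            netcfg = None
        else:
            netcfg = synthetic.NetworkSimConfig(seed=seed + 1)
            edges = synthetic.generate_reference_edges(netcfg)
        report.stage("edges", DONE, n_records=len(edges))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        logger.exception("edge stage failed")
        report.stage("edges", FAILED, error=str(exc))
        _skip_rest(report, ["reference", "expression", "de_mirna", "de_mrna",
                            "disease_network", "screen", "roc"], "upstream failure")
        return report
    logger.info("edges: %d records in %.2fs", len(edges), time.perf_counter() - t0)

    # stage 2: evidence-filtered reference network
    predicted = netcfg.predicted_sources if netcfg else synthetic.PREDICTED_SOURCE_NAMES
    try:
        ref = netbuild.build_reference_network(edges, predicted,
                                               config.min_predicted_sources)
        report.stage("reference", DONE, summary=netbuild.network_summary(ref))
    except Exception as exc:  # noqa: BLE001
        logger.exception("reference stage failed")
        report.stage("reference", FAILED, error=str(exc))
        _skip_rest(report, ["expression", "de_mirna", "de_mrna",
                            "disease_network", "screen", "roc"], "upstream failure")
        return report

    # stage 3: expression matrices
    try:
        if config.mirna_matrix:
            mirna_mat = diffexpr.read_expression_matrix(config.mirna_matrix,
                                                        config.mirna_conditions)
            mrna_mat = diffexpr.read_expression_matrix(config.mrna_matrix,
                                                       config.mrna_conditions)
            planted_mirnas = planted_genes = None
        else:
            mirna_mat, planted_mirnas, mrna_mat, planted_genes = \
                _simulate_discovery_expression(config, ref, netcfg, seed)
        report.stage("expression", DONE,
                     mirna_shape=list(mirna_mat.values.shape),
                     mrna_shape=list(mrna_mat.values.shape))
    except Exception as exc:  # noqa: BLE001
        logger.exception("expression stage failed")
        report.stage("expression", FAILED, error=str(exc))
        _skip_rest(report, ["de_mirna", "de_mrna", "disease_network",
                            "screen", "roc"], "upstream failure")
        return report

    # stages 4-5: differential expression, per platform (BH within each)
    probe_map = diffexpr.read_probe_map(config.probe_map) if config.probe_map else None
    de_mirna_table = diffexpr.differential_expression(
        mirna_mat, alpha=config.de_alpha, lfc_cutoff=config.de_lfc_cutoff)
    de_mirnas = set(de_mirna_table.loc[de_mirna_table["is_de"], "feature_id"])
    report.stage("de_mirna", DONE, n_tested=len(de_mirna_table), n_de=len(de_mirnas))

    de_mrna_table = diffexpr.differential_expression(
        mrna_mat, probe_map=probe_map,
        alpha=config.de_alpha, lfc_cutoff=config.de_lfc_cutoff)
    de_genes = set(de_mrna_table.loc[de_mrna_table["is_de"], "feature_id"])
    report.stage("de_mrna", DONE, n_tested=len(de_mrna_table), n_de=len(de_genes))

    # stage 6: disease-specific network
    disease = netbuild.extract_disease_network(ref, de_mirnas, de_genes,
                                               mode=config.network_mode)
    report.stage("disease_network", DONE, summary=netbuild.network_summary(disease))

    # stage 7: vulnerability screen
    if not disease.edges:
        report.stage("screen", SKIPPED, reason="empty disease network")
        report.stage("roc", SKIPPED, reason="no candidate to evaluate")
        return report
    scores = screen.vulnerability_scores(disease, config.screen_permutations,
                                         seed=seed + 7)
    candidates = screen.screen_candidates(scores, config.alpha_nsr, config.alpha_tsp)
    report.stage("screen", DONE,
                 n_scored=len(scores),
                 candidates=[c.mirna_id for c in candidates],
                 top_ranked=scores[0].mirna_id)

    # stage 8: discovery ROC on the top-ranked miRNA's expression
    top = candidates[0].mirna_id if candidates else scores[0].mirna_id
    if top not in mirna_mat.feature_ids:
        report.stage("roc", SKIPPED, reason=f"{top} not in discovery matrix")
        return report
    row = mirna_mat.values[mirna_mat.feature_ids.index(top)]
    result = roc.roc_analysis(row, mirna_mat.case_mask)
    report.stage("roc", DONE, mirna=top, **result.to_dict())

    if config.out_dir:
        _write_discovery_artifacts(config.out_dir, de_mirna_table, de_mrna_table,
                                   ref, disease, scores, report)
    return report


def _simulate_discovery_expression(config: RunConfig, ref, netcfg, seed: int):
    """Matrices whose feature sets cover the reference network nodes, with
    the planted biomarker's regulon forced into the planted DE sets."""
    rng = np.random.default_rng(seed + 3)
    mirnas = sorted(ref.mirnas)
    genes = sorted(ref.genes)
    biomarker = netcfg.planted_biomarker_id

    if config.sim_de_mirna_fraction > 0:
        others = [m for m in mirnas if m != biomarker]
        n_extra = max(0, round(config.sim_de_mirna_fraction * len(mirnas)) - 1)
        forced_mirnas = [biomarker] + [others[i] for i in
                                       rng.choice(len(others), size=min(n_extra, len(others)),
                                                  replace=False)]
    else:
        forced_mirnas = []
    n_mirna_features = max(300, len(mirnas))
    mirna_features = mirnas + [f"F{i:04d}" for i in range(1, n_mirna_features - len(mirnas) + 1)]
    mirna_cfg = synthetic.mirna_expression_config(seed=seed + 3, de_fraction=0.0,
                                                  n_features=len(mirna_features))
    mirna_mat, planted_mirnas = synthetic.generate_expression_dataset(
        mirna_cfg, feature_ids=mirna_features, planted_features=forced_mirnas)

    # the biomarker's exclusively regulated targets respond in the disease state
    if config.sim_de_gene_fraction > 0:
        exclusive = sorted(_exclusive_targets(ref, biomarker))
        other_genes = [g for g in genes if g not in set(exclusive)]
        n_extra_g = max(0, round(config.sim_de_gene_fraction * len(genes)) - len(exclusive))
        forced_genes = exclusive + [other_genes[i] for i in
                                    rng.choice(len(other_genes),
                                               size=min(n_extra_g, len(other_genes)),
                                               replace=False)]
    else:
        forced_genes = []
    n_gene_features = max(1000, len(genes))
    gene_features = genes + [f"G{i:04d}" for i in range(1, n_gene_features - len(genes) + 1)]
    mrna_cfg = synthetic.mrna_expression_config(seed=seed + 4, de_fraction=0.0,
                                                n_features=len(gene_features))
    mrna_mat, planted_genes = synthetic.generate_expression_dataset(
        mrna_cfg, feature_ids=gene_features, planted_features=forced_genes)
    return mirna_mat, planted_mirnas, mrna_mat, planted_genes


def _exclusive_targets(ref, mirna_id: str) -> set[str]:
    indeg: dict[str, int] = {}
    for _, g in ref.edges:
        indeg[g] = indeg.get(g, 0) + 1
    return {g for m, g in ref.edges if m == mirna_id and indeg[g] == 1}


def _skip_rest(report: RunReport, names: list[str], reason: str) -> None:
    for name in names:
        report.stage(name, SKIPPED, reason=reason)


def _write_discovery_artifacts(out_dir, de_mirna_table, de_mrna_table,
                               ref, disease, scores, report) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diffexpr.write_de_table(de_mirna_table, out / "de_mirna.tsv")
    diffexpr.write_de_table(de_mrna_table, out / "de_mrna.tsv")
    netbuild.write_network_tsv(ref, out / "reference_network.tsv")
    netbuild.write_network_tsv(disease, out / "disease_network.tsv")
    screen.write_scores_tsv(scores, out / "vulnerability_scores.tsv")
    screen.write_candidates_json(scores, out / "candidates.json")
    report.write(out, "discovery_report")


# ---------------------------------------------------------------------------
# Validation arm

#: smallest NDC subdiagnosis given its own ROC comparison
MIN_SUBGROUP_ROC_N = 10


def run_validation(config: RunConfig) -> RunReport:
    report = RunReport(arm="validation", seed=config.seed,
                       config_hash=config.config_hash(), version=__version__,
                       timestamp=_now())
    seed = config.seed

    configured_means: dict[str, float] = {}
    if config.cohort_csv:
        subjects = cohort_mod.read_cohort_csv(config.cohort_csv)
    else:
        sim_cfg = synthetic.default_cohort_config(seed=seed + 1)
        subjects = synthetic.generate_plasma_cohort(sim_cfg)
        for spec in sim_cfg.group_specs:
            if spec.subgroup is None:
                configured_means[spec.group] = spec.mean
        # NDC is configured through its subdiagnoses; its whole-group mean
        # is the published NDC-wide summary
        configured_means.setdefault("NDC", synthetic.NDC_OVERALL[1])
    known = {"IPD", "HC", "NDC"}
    unknown = sorted({s.group for s in subjects} - known)
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    report.stage("cohort", DONE, n=len(subjects),
                 per_group={g: sum(s.group == g for s in subjects) for g in sorted(known)})

    expr, n_excluded = cohort_mod.cohort_expression(subjects)
    usable = [s for s in subjects if s.subject_id in expr]

    def group_values(group: str) -> list[float]:
        return [expr[s.subject_id] for s in usable if s.group == group]

    present = [g for g in ("IPD", "HC", "NDC") if group_values(g)]
    if len(present) < 2:
        report.stage("group_comparisons", SKIPPED, reason="fewer than two groups present")
        report.stage("demographics", SKIPPED, reason="fewer than two groups present")
        report.stage("stratified", SKIPPED, reason="fewer than two groups present")
        report.stage("roc", SKIPPED, reason="fewer than two groups present")
        return report

    # group summary table, omnibus test, pairwise comparisons with ratios
    table = cohort_mod.expression_table(subjects)
    h, kw_p = cohort_mod.kruskal_groups(*[group_values(g) for g in present])
    comparisons = {}
    ratios = {}
    if "IPD" in present:
        for ctrl in ("HC", "NDC"):
            if ctrl in present:
                cmp_ = cohort_mod.compare_groups(group_values("IPD"), group_values(ctrl),
                                                 label_a="IPD", label_b=ctrl)
                comparisons[f"IPD_vs_{ctrl}"] = {
                    "p": cmp_.p_two_sided, "U": cmp_.statistic,
                    "ratio_percent": cmp_.ratio_percent,
                }
                ratios[f"IPD_vs_{ctrl}"] = cmp_.ratio_percent
    ratios_configured = {}
    if configured_means:
        for ctrl in ("HC", "NDC"):
            ratios_configured[f"IPD_vs_{ctrl}"] = cohort_mod.ratio_percent(
                configured_means["IPD"], configured_means[ctrl])
    report.stage("group_comparisons", DONE,
                 n_excluded_missing_ct=n_excluded,
                 kruskal={"H": h, "p": kw_p},
                 pairwise=comparisons,
                 ratio_percent=ratios,
                 ratio_percent_configured=ratios_configured,
                 table=_table_records(table))

    # demographics: sex chi-square and age comparisons across groups
    sex_table = [[sum(1 for s in subjects if s.group == g and s.sex == "male"),
                  sum(1 for s in subjects if s.group == g and s.sex == "female")]
                 for g in present]
    chi2, dof, chi_p = cohort_mod.chi_square_independence(sex_table)
    ages = {g: [s.age_years for s in subjects if s.group == g] for g in present}
    age_kw = cohort_mod.kruskal_groups(*ages.values())
    hy_subjects = [s for s in usable if s.group == "IPD" and s.hy_stage is not None]
    hy_corr = (cohort_mod.spearman_correlation(
        [s.hy_stage for s in hy_subjects],
        [expr[s.subject_id] for s in hy_subjects])
        if len(hy_subjects) >= 3 else (float("nan"), float("nan")))
    report.stage("demographics", DONE,
                 sex_chi_square={"chi2": chi2, "df": dof, "p": chi_p},
                 age_kruskal={"H": age_kw[0], "p": age_kw[1]},
                 hy_spearman={"rho": hy_corr[0], "p": hy_corr[1]})

    # the five stratified analyses
    strat = {}
    for stratifier in cohort_mod.STRATIFIERS:
        results = cohort_mod.stratified_comparisons(subjects, stratifier)
        strat[stratifier] = [
            {"stratum": r.stratum,
             "comparisons": {k: (None if c is None else
                                 {"p": c.p_two_sided, "n_a": c.n_a, "n_b": c.n_b})
                             for k, c in r.comparisons.items()}}
            for r in results
        ]
    report.stage("stratified", DONE, **strat)

    # ROC: IPD vs HC and IPD vs each sizeable NDC subdiagnosis
    roc_results = {}
    if "IPD" in present:
        ipd = group_values("IPD")
        if "HC" in present:
            roc_results["IPD_vs_HC"] = _roc_dict(ipd, group_values("HC"))
        subgroup_sizes: dict[str, int] = {}
        for s in usable:
            if s.group == "NDC" and s.subgroup:
                subgroup_sizes[s.subgroup] = subgroup_sizes.get(s.subgroup, 0) + 1
        for sg, n in sorted(subgroup_sizes.items()):
            if n < MIN_SUBGROUP_ROC_N:
                continue
            ctrl = [expr[s.subject_id] for s in usable
                    if s.group == "NDC" and s.subgroup == sg]
            roc_results[f"IPD_vs_{sg}"] = _roc_dict(ipd, ctrl)
    report.stage("roc", DONE, **roc_results)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "expression_table.tsv", sep="\t", index=False)
        report.write(out, "validation_report")
    return report


def _table_records(table) -> list[dict]:
    records = table.to_dict(orient="records")
    for r in records:
        for k, v in r.items():
            if isinstance(v, float) and math.isnan(v):
                r[k] = None
    return records


def _roc_dict(case_values, control_values) -> dict:
    scores = list(case_values) + list(control_values)
    labels = [True] * len(case_values) + [False] * len(control_values)
    return roc.roc_analysis(scores, labels).to_dict()
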