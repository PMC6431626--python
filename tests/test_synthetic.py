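"""Generators: moment matching, planted structure, determinism, round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirscreen import (
    CohortSimConfig,
    ExpressionSimConfig,
    GroupSpec,
    NetworkSimConfig,
    build_reference_network,
    default_cohort_config,
    generate_expression_dataset,
    generate_plasma_cohort,
    generate_reference_edges,
    lognormal_params_from_mean_sem,
)
from mirscreen.screen import single_line_targets
from mirscreen.synthetic import DEMOGRAPHICS, mirna_expression_config


class TestLogNormalMomentMatching:
    def test_degenerate_zero_sem_is_point_mass(self):
        p = lognormal_params_from_mean_sem(1.0, 0.0, 10)
        assert p.mu == 0.0 and p.sigma == 0.0

    def test_closed_form_matches_published_group_summary(self):
        # IPD row: mean 0.163, SEM 0.018, n=319 -> population sd 0.018*sqrt(319)
        p = lognormal_params_from_mean_sem(0.163, 0.018, 319)
        sd = 0.018 * math.sqrt(319)
        assert p.mean == pytest.approx(0.163, rel=1e-12)
        assert p.sd == pytest.approx(sd, rel=1e-12)

    def test_monte_carlo_confirms_moments(self, rng):
        # 1e6 draws: sample mean within 4 MC standard errors of the target
        p = lognormal_params_from_mean_sem(0.163, 0.018, 319)
        sd = 0.018 * math.sqrt(319)
        n = 1_000_000
        draws = rng.lognormal(p.mu, p.sigma, n)
        assert abs(draws.mean() - 0.163) < 4 * sd / math.sqrt(n)
        # sd of a lognormal sample sd is inflated by the excess kurtosis
        kurt = math.exp(4 * p.sigma**2) + 2 * math.exp(3 * p.sigma**2) \
            + 3 * math.exp(2 * p.sigma**2) - 6
        se_sd = sd * math.sqrt((kurt + 2) / (4 * n))
        assert abs(draws.std(ddof=1) - sd) < 4 * se_sd

    @pytest.mark.parametrize("mean,sem", [(-0.1, 0.01), (0.0, 0.01), (1.0, -0.1)])
    def test_domain_errors(self, mean, sem):
        with pytest.raises(ValueError):
            lognormal_params_from_mean_sem(mean, sem, 10)

    @given(mean=st.floats(1e-3, 1e3), cv=st.floats(0.0, 5.0),
           n=st.integers(1, 1000))
    def test_round_trip_property(self, mean, cv, n):
        sem = mean * cv / math.sqrt(n)
        p = lognormal_params_from_mean_sem(mean, sem, n)
        assert p.mean == pytest.approx(mean, rel=1e-9)
        assert p.sd == pytest.approx(sem * math.sqrt(n), rel=1e-9, abs=1e-12)


class TestExpressionGenerator:
    def test_default_mirna_shape_matches_study_design(self):
        matrix, planted = generate_expression_dataset(mirna_expression_config(seed=1))
        assert matrix.values.shape == (300, 32)  # 19 PD + 13 HC columns
        assert len(planted) == round(0.1 * 300)

    def test_planted_features_carry_the_case_shift(self):
        cfg = ExpressionSimConfig(n_features=50, n_cases=30, n_controls=30,
                                  de_fraction=0.2, de_log2_effect=3.0,
                                  noise_sd=0.3, seed=7)
        matrix, planted = generate_expression_dataset(cfg)
        case = matrix.values[:, matrix.case_mask].mean(axis=1)
        ctrl = matrix.values[:, ~matrix.case_mask].mean(axis=1)
        diff = dict(zip(matrix.feature_ids, case - ctrl))
        for f in planted:
            assert diff[f] == pytest.approx(3.0, abs=0.5)
        for f in set(matrix.feature_ids) - set(planted):
            assert abs(diff[f]) < 1.0

    def test_zero_de_fraction_plants_nothing(self):
        cfg = ExpressionSimConfig(n_features=40, de_fraction=0.0, seed=3)
        _, planted = generate_expression_dataset(cfg)
        assert planted == []

    def test_same_seed_reproduces_matrix(self):
        cfg = ExpressionSimConfig(seed=11)
        m1, p1 = generate_expression_dataset(cfg)
        m2, p2 = generate_expression_dataset(cfg)
        assert p1 == p2
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_forced_planted_features_are_included(self):
        cfg = ExpressionSimConfig(n_features=30, de_fraction=0.1, seed=5)
        ids = [f"X{i}" for i in range(30)]
        _, planted = generate_expression_dataset(cfg, feature_ids=ids,
                                                 planted_features=["X3"])
        assert "X3" in planted and len(planted) == 3

    @pytest.mark.parametrize("kwargs", [
        {"n_cases": 1}, {"de_fraction": 1.0}, {"noise_sd": 0.0}, {"n_features": 0},
    ])
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            ExpressionSimConfig(**kwargs)


class TestNetworkGenerator:
    def test_planted_mirna_has_exclusive_targets(self, predicted_sources):
        cfg = NetworkSimConfig(seed=2)
        edges = generate_reference_edges(cfg)
        targets = {}
        for e in edges:
            targets.setdefault(e.gene_id, set()).add(e.mirna_id)
        exclusive = [g for g, ms in targets.items()
                     if ms == {cfg.planted_biomarker_id}]
        assert len(exclusive) >= cfg.planted_single_line_count

    def test_exclusive_targets_tf_enriched_over_background(self):
        cfg = NetworkSimConfig(seed=4, n_genes=200, planted_single_line_count=40,
                               planted_tf_enrichment=0.9, tf_fraction=0.05)
        edges = generate_reference_edges(cfg)
        targets = {}
        tf = {}
        for e in edges:
            targets.setdefault(e.gene_id, set()).add(e.mirna_id)
            tf[e.gene_id] = e.gene_is_tf
        exclusive = [g for g, ms in targets.items() if ms == {cfg.planted_biomarker_id}]
        others = [g for g in tf if g not in exclusive]
        tf_rate_excl = np.mean([tf[g] for g in exclusive])
        tf_rate_bg = np.mean([tf[g] for g in others])
        assert tf_rate_excl > 0.6 > 0.3 > tf_rate_bg

    def test_all_exclusive_planted_mirna_has_nsr_one(self, predicted_sources):
        cfg = NetworkSimConfig(seed=6, planted_background_targets=False)
        edges = generate_reference_edges(cfg)
        ref = build_reference_network(edges, predicted_sources)
        singles = single_line_targets(ref, cfg.planted_biomarker_id)
        n_targets = len([e for e in ref.edges if e[0] == cfg.planted_biomarker_id])
        assert len(singles) == n_targets == cfg.planted_single_line_count

    def test_seed_reproducibility_byte_identical(self):
        cfg = NetworkSimConfig(seed=9)
        assert generate_reference_edges(cfg) == generate_reference_edges(cfg)

    def test_config_errors(self):
        with pytest.raises(ValueError):
            NetworkSimConfig(n_genes=5, planted_single_line_count=6)
        with pytest.raises(ValueError):
            NetworkSimConfig(predicted_sources=("a", "b"))


class TestCohortGenerator:
    def test_published_group_sizes_total_897(self):
        records = generate_plasma_cohort(default_cohort_config(seed=1))
        assert len(records) == 897
        per_group = {g: sum(r.group == g for r in records) for g in ("IPD", "HC", "NDC")}
        assert per_group == {"IPD": 319, "HC": 273, "NDC": 305}

    def test_ct_pair_round_trip_equals_drawn_expression(self):
        records = generate_plasma_cohort(default_cohort_config(seed=3))
        for r in records:
            assert 2 ** (r.ct_reference - r.ct_target) == pytest.approx(
                r.expression, rel=1e-9)

    def test_ipd_sample_mean_near_target(self):
        records = generate_plasma_cohort(default_cohort_config(seed=5))
        ipd = [r.expression for r in records if r.group == "IPD"]
        assert abs(np.mean(ipd) - 0.163) < 3 * 0.018

    def test_ipd_only_clinical_fields(self):
        records = generate_plasma_cohort(default_cohort_config(seed=7))
        for r in records:
            if r.group == "IPD":
                assert r.duration_years is not None and r.hy_stage in range(1, 6)
            else:
                assert r.duration_years is None and r.hy_stage is None

    def test_missing_ct_rate_plants_missing_pairs(self):
        cfg = default_cohort_config(seed=9, missing_ct_rate=0.1)
        records = generate_plasma_cohort(cfg)
        n_missing = sum(r.ct_target is None for r in records)
        assert 0 < n_missing < len(records)
        for r in records:
            assert (r.ct_target is None) == (r.ct_reference is None) == (r.expression is None)

    def test_invalid_group_spec_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("IPD", None, 10, -0.1, 0.01)
        with pytest.raises(ValueError):
            CohortSimConfig(group_specs=[])

    def test_demographics_bookkeeping(self):
        # published counts: 489 males of 897
        males = sum(d["sex"][0] for d in DEMOGRAPHICS.values())
        females = sum(d["sex"][1] for d in DEMOGRAPHICS.values())
        assert males == 489 and males + females == 897
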