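import numpy as np
import pandas as pd
import pytest

from renometh.multisite import (
    AlphaSelection,
    FoldResult,
    MultisiteModel,
    aggregate_site_weights,
    apply_bic_rule,
    apply_cross_cohort,
    apply_one_sd_rule,
    bic_select_n,
    classify_selected_sites,
    fit_final_model,
    fit_multisite_pipeline,
    predict_and_evaluate,
    run_repeated_nested_cv,
    select_alpha,
)
from renometh.preprocess import filter_probes, standardize_features


def brute_force_alpha(grid, r2):
    """Literal scan of the alpha rule: largest alpha within one SD of best."""
    grid = np.asarray(grid, float)
    r2 = np.asarray(r2, float)
    sd = np.std(r2, ddof=1) if len(r2) > 1 else 0.0
    best = max(r2)
    return max(a for a, r in zip(grid, r2) if r >= best - sd)


def brute_force_n(sizes, bic):
    """Literal scan of the size rule: largest n within 0.1 SD of min BIC."""
    sd = np.std(bic, ddof=1) if len(bic) > 1 else 0.0
    lo = min(bic)
    return max(n for n, b in zip(sizes, bic) if b <= lo + 0.1 * sd)


class TestAlphaRule:
    def test_three_point_profile_hand_evaluated(self):
        grid = [0.1, 0.5, 1.0]
        r2 = [0.80, 0.78, 0.50]
        # SD(ddof=1) of the profile is ~0.168, so 0.78 >= 0.80 - SD holds
        # and 0.50 does not: the rule picks 0.5
        alpha, sd = apply_one_sd_rule(grid, r2)
        assert alpha == 0.5
        assert alpha == brute_force_alpha(grid, r2)

    def test_rule_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(60)
        for _ in range(200):
            k = int(rng.integers(2, 12))
            grid = np.sort(rng.uniform(0.01, 2.0, k))
            r2 = rng.uniform(-0.5, 1.0, k)
            alpha, _ = apply_one_sd_rule(grid, r2)
            assert alpha == brute_force_alpha(grid, r2)

    def test_degenerate_zero_sd_picks_argmax(self):
        grid = [0.1, 0.5, 1.0]
        r2 = [0.9, 0.9, 0.9]
        alpha, sd = apply_one_sd_rule(grid, r2)
        assert sd == 0.0
        assert alpha == 1.0  # all tie: largest eligible alpha

    def test_single_value_grid_chosen(self):
        sel = select_alpha(np.random.default_rng(0).normal(size=(30, 5)),
                           np.random.default_rng(1).normal(size=30), grid=[0.3])
        assert sel.alpha_star == 0.3


class TestBicRule:
    def test_three_point_profile_hand_evaluated(self):
        sizes = [5, 10, 20]
        bic = [100.0, 101.0, 130.0]
        # SD ~17.04, tolerance 1.704: 101 <= 101.7 -> n* = 10
        assert apply_bic_rule(sizes, bic) == 10
        assert apply_bic_rule(sizes, bic) == brute_force_n(sizes, bic)

    def test_rule_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(61)
        for _ in range(200):
            k = int(rng.integers(1, 15))
            sizes = np.sort(rng.choice(np.arange(1, 100), size=k, replace=False))
            bic = rng.uniform(-50, 400, k)
            assert apply_bic_rule(sizes, bic) == brute_force_n(sizes, bic)

    def test_flat_profile_picks_max_size(self):
        assert apply_bic_rule([1, 5, 9], [50.0, 50.0, 50.0]) == 9

    def test_single_size_chosen(self):
        assert apply_bic_rule([7], [123.4]) == 7


class TestWeightAggregation:
    def test_hand_sum(self):
        folds = [
            FoldResult(0, 0, ("a",), 0.5, 0.1),
            FoldResult(0, 1, ("a", "b"), 0.5, 0.1),
            FoldResult(1, 0, ("a",), 0.2, 0.1),
        ]
        w = aggregate_site_weights(folds).weights
        assert w["a"] == pytest.approx(1.2)
        assert w["b"] == pytest.approx(0.5)

    def test_signed_correlations_sum_as_printed(self):
        folds = [
            FoldResult(0, 0, ("a",), -0.1, 0.1),
            FoldResult(0, 1, ("a",), 0.5, 0.1),
        ]
        assert aggregate_site_weights(folds).weights["a"] == pytest.approx(0.4)

    def test_never_selected_probe_absent_hence_zero(self):
        folds = [FoldResult(0, 0, ("a",), 0.5, 0.1)]
        w = aggregate_site_weights(folds).weights
        assert "zzz" not in w.index

    def test_matches_naive_double_loop_on_100_results(self):
        rng = np.random.default_rng(62)
        probes = [f"cg{i:03d}" for i in range(50)]
        folds = []
        for j in range(10):
            for i in range(10):
                sel = tuple(rng.choice(probes, size=rng.integers(0, 12), replace=False))
                folds.append(FoldResult(j, i, sel, float(rng.uniform(-0.3, 0.9)), 0.1))
        w = aggregate_site_weights(folds).weights
        naive = {}
        for fr in folds:
            for k in probes:
                if k in fr.selected:
                    naive[k] = naive.get(k, 0.0) + fr.rho
        for k, v in naive.items():
            assert w[k] == pytest.approx(v, abs=1e-12)

    def test_ranking_tie_break_deterministic(self):
        folds = [FoldResult(0, 0, ("b", "a"), 0.5, 0.1)]
        sw = aggregate_site_weights(folds)
        assert sw.ranked() == ["a", "b"]  # equal weight: ascending ID


@pytest.fixture(scope="module")
def planted(small_cohort_module):
    c = small_cohort_module
    filt, _ = filter_probes(c.matrix, c.manifest)
    feats, _ = standardize_features(filt.values)
    return c, filt, feats


@pytest.fixture(scope="module")
def small_cohort_module():
    from renometh.synthdata import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_samples=150, n_probes=300, n_causal_baseline=8, n_causal_slope=0,
        effect_size_sd=3.0, seed=63,
    )
    return simulate_cohort(cfg)


class TestNestedCv:
    def test_cardinality_and_determinism(self, planted):
        c, filt, feats = planted
        trait = c.phenotypes["baseline_egfr"]
        kw = dict(outer_folds=5, repeats=2, n_alphas=8, seed=3)
        a = run_repeated_nested_cv(feats, trait, **kw)
        b = run_repeated_nested_cv(feats, trait, **kw)
        assert len(a) == 10
        for fa, fb in zip(a, b):
            assert fa.selected == fb.selected
            assert fa.rho == fb.rho
            assert fa.alpha_star == fb.alpha_star

    def test_causal_probes_selected_in_majority_of_folds(self, planted):
        c, filt, feats = planted
        trait = c.phenotypes["baseline_egfr"]
        folds = run_repeated_nested_cv(
            feats, trait, outer_folds=5, repeats=4, n_alphas=10, seed=4
        )
        counts = {p: 0 for p in c.truth.causal_probes_baseline}
        for fr in folds:
            for p in fr.selected:
                if p in counts:
                    counts[p] += 1
        n_models = len(folds)
        frac_majority = np.mean([v >= n_models / 2 for v in counts.values()])
        assert frac_majority >= 0.75

    def test_tiny_outer_folds_rejected(self, planted):
        _, _, feats = planted
        trait = pd.Series(np.arange(len(feats), dtype=float), index=feats.index)
        with pytest.raises(ValueError, match="folds"):
            run_repeated_nested_cv(feats.iloc[:20], trait.iloc[:20], outer_folds=10)


class TestFinalModel:
    def test_refit_identical(self, planted):
        c, filt, feats = planted
        trait = c.phenotypes["baseline_egfr"]
        ranked = list(c.truth.causal_probes_baseline)
        m1 = fit_final_model(filt.values, trait, ranked, 5, seed=5)
        m2 = fit_final_model(filt.values, trait, ranked, 5, seed=5)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        assert m1.intercept == m2.intercept

    def test_covariate_toggle_changes_coefficients_not_probes(self, planted):
        c, filt, feats = planted
        trait = c.phenotypes["baseline_egfr"]
        cov = c.phenotypes[["age", "hba1c"]].astype(float)
        ranked = list(c.truth.causal_probes_baseline)
        with_cov = fit_final_model(filt.values, trait, ranked, 5, covariates=cov,
                                   with_covariates=True, seed=5)
        without = fit_final_model(filt.values, trait, ranked, 5, seed=5)
        assert with_cov.probes == without.probes
        assert len(with_cov.covariate_coefficients) == 2
        assert len(without.covariate_coefficients) == 0

    def test_serialization_round_trip_exact(self, planted):
        c, filt, feats = planted
        trait = c.phenotypes["baseline_egfr"]
        model = fit_final_model(
            filt.values, trait, list(c.truth.causal_probes_baseline), 5, seed=5
        )
        back = MultisiteModel.from_json(model.to_json())
        assert back.probes == model.probes
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        pred_a = model.predict(filt.values)
        pred_b = back.predict(filt.values)
        pd.testing.assert_series_equal(pred_a, pred_b)

    def test_bic_path_scans_requested_sizes(self, planted):
        c, filt, feats = planted
        trait = c.phenotypes["baseline_egfr"]
        ranked = list(c.truth.causal_probes_baseline)
        path = bic_select_n(feats, trait, ranked, sizes=[2, 4, 8], seed=6, n_alphas=8)
        assert path.sizes.tolist() == [2, 4, 8]
        assert path.n_star in (2, 4, 8)
        assert path.n_star == brute_force_n(path.sizes, path.bic)

    def test_empty_sizes_rejected(self, planted):
        c, filt, feats = planted
        with pytest.raises(ValueError, match="size"):
            bic_select_n(feats, c.phenotypes["baseline_egfr"],
                         list(feats.columns[:5]), sizes=[])


class TestEvaluation:
    def test_perfect_predictions(self, planted):
        c, filt, _ = planted
        trait = c.phenotypes["baseline_egfr"]
        model = fit_final_model(
            filt.values, trait, list(c.truth.causal_probes_baseline), 5, seed=7
        )
        out = predict_and_evaluate(model, filt.values, model.predict(filt.values))
        assert out["pcc"] == pytest.approx(1.0)
        assert out["scc"] == pytest.approx(1.0)
        assert out["mae"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_unit_correlation_mae_equals_offset(self, planted):
        c, filt, _ = planted
        trait = c.phenotypes["baseline_egfr"]
        model = fit_final_model(
            filt.values, trait, list(c.truth.causal_probes_baseline), 5, seed=7
        )
        pred = model.predict(filt.values)
        out = predict_and_evaluate(model, filt.values, pred + 3.5)
        assert out["pcc"] == pytest.approx(1.0)
        assert out["mae"] == pytest.approx(3.5, abs=1e-9)


class TestClassification:
    def test_separable_labels_high_auroc(self, planted):
        c, filt, _ = planted
        probes = list(c.truth.causal_probes_baseline)
        z, _ = standardize_features(filt.values[probes])
        score = z.sum(axis=1)
        labels = (score > score.median()).astype(int)
        out = classify_selected_sites(filt.values, labels, probes, seed=8)
        assert out["mean_auroc"] > 0.9

    def test_permuted_labels_near_chance(self, planted):
        c, filt, _ = planted
        rng = np.random.default_rng(9)
        labels = pd.Series(
            rng.permutation([0, 1] * (len(filt.values) // 2 + 1))[: len(filt.values)],
            index=filt.values.index,
        )
        out = classify_selected_sites(
            filt.values, labels, list(c.truth.causal_probes_baseline), seed=8
        )
        assert abs(out["mean_auroc"] - 0.5) < 0.15

    def test_empty_probe_set_rejected(self, planted):
        c, filt, _ = planted
        labels = pd.Series(0, index=filt.values.index)
        with pytest.raises(ValueError, match="empty"):
            classify_selected_sites(filt.values, labels, [])


class TestCrossCohort:
    def test_identity_transfer_equals_within_cohort(self, planted):
        c, filt, _ = planted
        trait = c.phenotypes["baseline_egfr"]
        model = fit_final_model(
            filt.values, trait, list(c.truth.causal_probes_baseline), 5, seed=10
        )
        within = predict_and_evaluate(model, filt.values, trait)
        transfer = apply_cross_cohort(
            filt.values, trait, filt.values, trait, model, retrain=False
        )
        assert transfer["pcc"] == pytest.approx(within["pcc"])
        assert transfer["mae"] == pytest.approx(within["mae"])

    def test_zero_fill_contract(self, planted):
        """Dropping probes with zero coefficients leaves direct-mode
        predictions unchanged; dropping an active probe changes them."""
        c, filt, _ = planted
        trait = c.phenotypes["baseline_egfr"]
        model = fit_final_model(
            filt.values, trait, list(c.truth.causal_probes_baseline), 5, seed=10
        )
        active = [p for p, b in zip(model.probes, model.coefficients) if b != 0]
        inactive = [p for p, b in zip(model.probes, model.coefficients) if b == 0]
        base_pred = model.predict(filt.values)
        if inactive:
            dropped = filt.values.drop(columns=inactive)
            pred = model.predict(dropped, zero_fill_missing=True)
            np.testing.assert_allclose(pred, base_pred, atol=1e-12)
        dropped_active = filt.values.drop(columns=active[:1])
        pred2 = model.predict(dropped_active, zero_fill_missing=True)
        assert not np.allclose(pred2, base_pred)

    def test_disjoint_probe_sets_rejected(self, planted):
        c, filt, _ = planted
        trait = c.phenotypes["baseline_egfr"]
        model = fit_final_model(
            filt.values, trait, list(c.truth.causal_probes_baseline), 5, seed=10
        )
        other = filt.values.copy()
        other.columns = [f"x_{c}" for c in other.columns]
        with pytest.raises(ValueError, match="no probes"):
            apply_cross_cohort(filt.values, trait, other, trait, model)


class TestPipeline:
    def test_pipeline_recovers_planted_signal(self, planted):
        c, filt, _ = planted
        res = fit_multisite_pipeline(
            filt.values,
            c.phenotypes["baseline_egfr"],
            repeats=3,
            outer_folds=5,
            n_alphas=10,
            max_size=40,
            seed=11,
            with_covariates=False,
        )
        causal = set(c.truth.causal_probes_baseline)
        assert len(causal & set(res.model.probes)) >= len(causal) - 2
        assert res.test_metrics["pcc"] > 0.5
        # test split genuinely excised
        assert len(res.test_samples) == round(0.1 * len(filt.values))
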