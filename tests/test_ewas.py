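import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from renometh.ewas import (
    CollinearityError,
    bh_fdr,
    bonferroni_adjust,
    genomic_inflation,
    pc_clinical_association,
    run_single_site_ewas,
)
from renometh.preprocess import MethylationMatrix, beta_to_m


def _matrix_from(arr, scale="M"):
    arr = np.asarray(arr, dtype=float)
    return MethylationMatrix(
        pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=[f"p{i}" for i in range(arr.shape[1])],
        ),
        scale=scale,
    )


class TestSingleSiteEwas:
    def test_planted_signal_found_with_correct_coefficient(self):
        rng = np.random.default_rng(41)
        M = rng.standard_normal((100, 20))
        trait = pd.Series(2.0 * M[:, 3] + rng.normal(0, 1e-6, 100),
                          index=[f"s{i}" for i in range(100)])
        res = run_single_site_ewas(_matrix_from(M), trait)
        assert res.table.loc["p3", "p"] < 1e-20
        assert res.table.loc["p3", "coefficient"] == pytest.approx(2.0, abs=1e-4)

    def test_null_pvalues_uniform(self, null_cohort):
        res = run_single_site_ewas(
            null_cohort.matrix, null_cohort.phenotypes["baseline_egfr"]
        )
        ks = stats.kstest(res.table["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_ols_exactly(self):
        """Residualized per-probe fit equals the full OLS on 20 random designs."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(30, 60)
            M = rng.standard_normal((n, 3))
            cov = pd.DataFrame(
                {"age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n).astype(float)}
            )
            y = pd.Series(
                0.5 * M[:, 0] - 0.2 * cov["age"].to_numpy() + rng.standard_normal(n)
            )
            mat = _matrix_from(M)
            cov.index = y.index = mat.sample_ids
            res = run_single_site_ewas(mat, y, cov)
            for j, pid in enumerate(mat.probe_ids):
                X = sm.add_constant(
                    np.column_stack([cov.to_numpy(), M[:, j]])
                )
                fit = sm.OLS(y.to_numpy(), X).fit()
                assert res.table.loc[pid, "coefficient"] == pytest.approx(
                    fit.params[-1], rel=1e-8
                )
                assert res.table.loc[pid, "p"] == pytest.approx(
                    fit.pvalues[-1], rel=1e-6
                )

    def test_duplicate_covariate_reported_as_collinear(self):
        rng = np.random.default_rng(43)
        M = rng.standard_normal((40, 5))
        mat = _matrix_from(M)
        cov = pd.DataFrame(
            {"a": rng.normal(size=40), "b": rng.normal(size=40)}, index=mat.sample_ids
        )
        cov["a_copy"] = cov["a"]
        y = pd.Series(rng.normal(size=40), index=mat.sample_ids)
        with pytest.raises(CollinearityError):
            run_single_site_ewas(mat, y, cov)

    def test_sign_convention_positive_means_higher_trait(self):
        rng = np.random.default_rng(44)
        M = rng.standard_normal((80, 2))
        y = pd.Series(3.0 * M[:, 0], index=[f"s{i}" for i in range(80)])
        res = run_single_site_ewas(_matrix_from(M), y)
        assert res.table.loc["p0", "coefficient"] > 0


class TestMultiplicity:
    def test_hand_enumerated_bonferroni_and_bh(self):
        p = np.array([0.01, 0.04, 0.03])
        np.testing.assert_allclose(bonferroni_adjust(p), [0.03, 0.12, 0.09])
        # BH step-up: sorted p (.01,.03,.04) vs (q/3, 2q/3, q): all pass
        assert bh_fdr(p, q=0.05).tolist() == [True, True, True]

    def test_bh_matches_exhaustive_definition_on_small_vectors(self):
        rng = np.random.default_rng(45)
        for _ in range(50):
            m = int(rng.integers(1, 11))
            p = np.round(rng.uniform(0, 1, size=m), 3)
            q = 0.1
            flags = bh_fdr(p, q=q)
            # brute force: largest k with p_(k) <= qk/m, flag the k smallest
            order = np.argsort(p, kind="stable")
            ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= q * k / m]
            expected = np.zeros(m, dtype=bool)
            if ks:
                expected[order[: max(ks)]] = True
            assert flags.tolist() == expected.tolist()

    def test_all_ones_no_flags(self):
        assert not bh_fdr(np.ones(5), q=0.05).any()
        np.testing.assert_allclose(bonferroni_adjust(np.ones(5)), 1.0)

    def test_boundary_p_equal_q_is_flagged(self):
        assert bh_fdr(np.array([0.05]), q=0.05).tolist() == [True]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.2]))
        with pytest.raises(ValueError):
            bonferroni_adjust(np.array([-0.1]))

    def test_bh_flags_form_step_up_set(self):
        rng = np.random.default_rng(46)
        p = rng.uniform(0, 1, 200) ** 2
        flags = bh_fdr(p, q=0.2)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() or not (~flags).any()


class TestInflation:
    def test_uniform_pvalues_lambda_near_one(self):
        # average over replicate draws so the check measures calibration
        # of the statistic rather than Monte-Carlo noise of one draw
        rng = np.random.default_rng(47)
        lams = [genomic_inflation(rng.uniform(size=100_000)) for _ in range(10)]
        assert np.mean(lams) == pytest.approx(1.0, abs=0.02)

    def test_all_half_is_exactly_one(self):
        assert genomic_inflation(np.full(11, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_concentration_near_zero_inflates(self):
        rng = np.random.default_rng(48)
        lam = genomic_inflation(rng.uniform(0, 0.01, size=1000))
        assert lam > 1.0

    def test_zero_pvalues_handled(self):
        lam = genomic_inflation(np.array([0.0, 0.5, 0.5]))
        assert np.isfinite(lam)


class TestPcClinical:
    def test_label_aligned_with_pc1_is_separable(self):
        rng = np.random.default_rng(49)
        scores = rng.standard_normal(120)
        load = rng.uniform(0.2, 0.8, 30)
        vals = np.clip(
            0.5 + 0.3 * np.outer(scores, load) + rng.normal(0, 0.01, (120, 30)), 0.01, 0.99
        )
        mat = MethylationMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(120)],
                         columns=[f"p{i}" for i in range(30)])
        )
        labels = pd.Series((scores > 0).astype(int), index=mat.sample_ids)
        out = pc_clinical_association(mat, labels, n_pcs=5, seed=0)
        assert out["mean_auroc"] > 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(50)
        vals = rng.uniform(0.05, 0.95, size=(300, 50))
        mat = MethylationMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(300)],
                         columns=[f"p{i}" for i in range(50)])
        )
        # the null statement is about the expectation over label
        # permutations, so average several
        aurocs = []
        for s in range(5):
            labels = pd.Series(rng.permutation([0, 1] * 150), index=mat.sample_ids)
            aurocs.append(
                pc_clinical_association(mat, labels, n_pcs=5, seed=s)["mean_auroc"]
            )
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_npcs_beyond_rank_rejected(self, toy_matrix):
        labels = pd.Series([0, 1, 0, 1], index=toy_matrix.sample_ids)
        with pytest.raises(ValueError, match="rank"):
            pc_clinical_association(toy_matrix, labels, n_pcs=50)
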