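"""CPM steps, cross-validation, permutation inference, and correlation
statistics, checked against literal brute-force references and simulated
null calibrations."""

import numpy as np
import pytest
from scipy import stats

import motioncpm as mc
from motioncpm.exceptions import (DegenerateDataError, FitError,
                                  InvalidResultError, ValidationError)


def brute_loo_cpm(edges, scores, selection_p=0.01, variant="bilinear"):
    """Literal per-fold reference: per-edge scipy pearsonr, explicit OLS."""
    n, E = edges.shape
    preds = np.empty(n)
    for k in range(n):
        tr = [i for i in range(n) if i != k]
        Xtr, ytr = edges[tr], scores[np.array(tr)]
        pos = np.zeros(E, bool)
        neg = np.zeros(E, bool)
        for e in range(E):
            if np.ptp(Xtr[:, e]) == 0:
                continue
            r, p = stats.pearsonr(Xtr[:, e], ytr)
            if p < selection_p and r > 0:
                pos[e] = True
            elif p < selection_p and r < 0:
                neg[e] = True
        Xs = edges[:, pos].sum(axis=1)
        Ys = edges[:, neg].sum(axis=1)
        cols = {"bilinear": [Xs, Ys], "positive_only": [Xs],
                "negative_only": [Ys]}[variant]
        cols = [c for c in cols if np.ptp(c[tr]) > 0]
        if not cols:
            preds[k] = ytr.mean()
            continue
        D = np.column_stack([np.ones(n - 1)] + [c[tr] for c in cols])
        beta, *_ = np.linalg.lstsq(D, ytr, rcond=None)
        preds[k] = beta @ np.concatenate([[1.0], [c[k] for c in cols]])
    return preds


class TestSelectFeatures:
    def test_score_edge_lands_in_positive_mask(self, rng):
        scores = rng.normal(0, 1, 30)
        edges = rng.normal(0, 1, (30, 10))
        edges[:, 3] = scores
        edges[:, 7] = -scores
        masks = mc.select_features(edges, scores, selection_p=0.01)
        assert masks.positive[3] and masks.negative[7]
        assert not masks.positive[7] and not masks.negative[3]

    def test_null_selection_rate_matches_threshold(self):
        rng = np.random.default_rng(42)
        edges, scores = mc.null_edge_cohort(50, 10_000, rng)
        masks = mc.select_features(edges, scores, selection_p=0.05)
        frac = (masks.positive.sum() + masks.negative.sum()) / masks.n_edges
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(frac - 0.05) < 3 * se

    def test_invariant_to_monotone_affine_score_rescaling(self, rng):
        edges, scores = mc.null_edge_cohort(40, 200, rng)
        m1 = mc.select_features(edges, scores, 0.05)
        m2 = mc.select_features(edges, 3.7 * scores + 11.0, 0.05)
        np.testing.assert_array_equal(m1.positive, m2.positive)
        np.testing.assert_array_equal(m1.negative, m2.negative)

    def test_constant_scores_rejected(self, rng):
        edges = rng.normal(0, 1, (20, 5))
        with pytest.raises(DegenerateDataError):
            mc.select_features(edges, np.ones(20), 0.05)

    def test_constant_edges_excluded(self, rng):
        edges, scores = mc.null_edge_cohort(30, 20, rng)
        edges[:, 4] = 2.0
        masks = mc.select_features(edges, scores, 0.5)
        assert not masks.positive[4] and not masks.negative[4]


class TestStrengthsAndModel:
    def test_empty_masks_give_zero_strengths(self):
        masks = mc.FeatureMasks(np.zeros(6, bool), np.zeros(6, bool), 0.01, 10)
        assert mc.network_strengths(np.arange(6.0), masks) == (0.0, 0.0)

    def test_single_edge_mask(self):
        pos = np.zeros(6, bool)
        pos[2] = True
        masks = mc.FeatureMasks(pos, np.zeros(6, bool), 0.01, 10)
        X, Y = mc.network_strengths(np.arange(6.0), masks)
        assert X == 2.0 and Y == 0.0

    def test_strengths_match_loop_sum(self, rng):
        r = rng.random(50)
        masks = mc.FeatureMasks(r > 0.6, r < 0.3, 0.01, 20)
        v = rng.normal(0, 1, 50)
        X, Y = mc.network_strengths(v, masks)
        assert X == pytest.approx(sum(v[i] for i in range(50)
                                      if masks.positive[i]), abs=1e-12)
        assert Y == pytest.approx(sum(v[i] for i in range(50)
                                      if masks.negative[i]), abs=1e-12)

    def test_exact_linear_recovery(self, rng):
        X = rng.normal(0, 1, 20)
        model = mc.fit_model(X, np.zeros(20), 2.0 + 3.0 * X,
                             variant="positive_only")
        assert model.a == pytest.approx(2.0, abs=1e-10)
        assert model.b == pytest.approx(3.0, abs=1e-10)
        assert model.c == 0.0

    def test_constant_scores_give_intercept(self, rng):
        X = rng.normal(0, 1, 15)
        model = mc.fit_model(X, np.zeros(15), np.full(15, 4.2),
                             variant="positive_only")
        assert model.a == pytest.approx(4.2, abs=1e-10)
        assert model.b == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_match_normal_equations(self, rng):
        X, Y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        scores = rng.normal(0, 1, 30)
        model = mc.fit_model(X, Y, scores, "bilinear")
        D = np.column_stack([np.ones(30), X, Y])
        beta = np.linalg.solve(D.T @ D, D.T @ scores)
        np.testing.assert_allclose([model.a, model.b, model.c], beta,
                                   atol=1e-10)

    def test_collinear_strengths_rejected(self, rng):
        X = rng.normal(0, 1, 20)
        with pytest.raises(FitError):
            mc.fit_model(X, 2.0 * X, rng.normal(0, 1, 20), "bilinear")

    def test_predict_bilinear_coefficients(self):
        model = mc.CPMModel("bilinear", a=0.016, b=0.005, c=-0.010)
        assert mc.predict(model, 10.0, 5.0) == pytest.approx(0.016)
        flat = mc.CPMModel("bilinear", a=1.5, b=0.0, c=0.0)
        assert mc.predict(flat, 123.0, -7.0) == 1.5


class TestAccuracy:
    def test_perfect_and_inverted(self, rng):
        y = rng.normal(0, 1, 10)
        assert mc.accuracy(y, y).pearson_r == pytest.approx(1.0)
        assert mc.accuracy(y, y).spearman_rho == pytest.approx(1.0)
        assert mc.accuracy(y, -y).pearson_r == pytest.approx(-1.0)
        assert mc.accuracy(y, -y).spearman_rho == pytest.approx(-1.0)

    def test_matches_moment_and_rank_references(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        res = mc.accuracy(a, b)
        ac, bc = a - a.mean(), b - b.mean()
        r_ref = (ac @ bc) / np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        rac, rbc = ra - ra.mean(), rb - rb.mean()
        rho_ref = (rac @ rbc) / np.sqrt((rac ** 2).sum() * (rbc ** 2).sum())
        assert res.pearson_r == pytest.approx(r_ref, abs=1e-12)
        assert res.spearman_rho == pytest.approx(rho_ref, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidResultError):
            mc.accuracy(np.ones(5), np.arange(5.0))


class TestCriticalR:
    def test_degenerate_limit_is_zero(self):
        assert mc.critical_r(100, alpha=1.0, m_comparisons=1) == pytest.approx(0.0)

    @pytest.mark.parametrize("n,m", [(207, 16), (207, 14), (50, 5), (1000, 91)])
    def test_agrees_with_numeric_root_finding(self, n, m):
        from scipy.optimize import brentq
        alpha = 0.05

        def pvalue_of_r(r):
            t = r * np.sqrt((n - 2) / (1 - r ** 2))
            return 2 * stats.t.sf(t, n - 2)

        root = brentq(lambda r: pvalue_of_r(r) - alpha / m, 1e-9, 1 - 1e-9,
                      xtol=1e-12)
        assert mc.critical_r(n, alpha, m) == pytest.approx(root, abs=1e-6)


class TestDependentCorrelationTests:
    def test_williams_equal_correlations(self):
        t, p = mc.williams_test(0.4, 0.4, 0.3, 50)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_williams_sign_antisymmetry(self):
        t1, _ = mc.williams_test(0.5, 0.2, 0.3, 80)
        t2, _ = mc.williams_test(0.2, 0.5, 0.3, 80)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert t1 > 0

    def test_williams_type_i_calibration(self):
        rng = np.random.default_rng(7)
        n, reps, rho = 100, 2000, 0.4
        cov = np.array([[1, rho, rho], [rho, 1, 0.2], [rho, 0.2, 1]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal((3, n))
            d = L @ x
            r12 = np.corrcoef(d[0], d[1])[0, 1]
            r13 = np.corrcoef(d[0], d[2])[0, 1]
            r23 = np.corrcoef(d[1], d[2])[0, 1]
            _, p = mc.williams_test(r12, r13, r23, n)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_steiger_symmetric_equality(self):
        z, p = mc.steiger_test(0.4, 0.4, 0.2, 0.2, 0.2, 0.2, 60)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_steiger_independence_limit(self):
        r12, r34, n = 0.5, 0.2, 80
        z, _ = mc.steiger_test(r12, r34, 0.0, 0.0, 0.0, 0.0, n)
        z_ref = (np.arctanh(r12) - np.arctanh(r34)) / np.sqrt(2 / (n - 3))
        assert z == pytest.approx(z_ref, abs=1e-10)

    def test_steiger_type_i_calibration(self):
        rng = np.random.default_rng(13)
        n, reps, rho = 100, 2000, 0.3
        cov = np.full((4, 4), 0.1)
        np.fill_diagonal(cov, 1.0)
        cov[0, 1] = cov[1, 0] = rho
        cov[2, 3] = cov[3, 2] = rho
        L = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            d = L @ rng.standard_normal((4, n))
            c = np.corrcoef(d)
            _, p = mc.steiger_test(c[0, 1], c[2, 3], c[0, 2], c[0, 3],
                                   c[1, 2], c[1, 3], n)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_invalid_correlation_matrices_rejected(self):
        with pytest.raises(ValidationError):
            mc.williams_test(0.9, -0.9, 0.9, 50)
        with pytest.raises(ValidationError):
            mc.steiger_test(0.9, 0.9, 0.9, -0.9, 0.9, 0.9, 50)


class TestCrossValidation:
    def _toy_cohort(self, seed=5, n=6, E=30):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, n)
        edges = rng.normal(0, 1, (n, E))
        edges[:, 0] = scores + 0.05 * rng.normal(0, 1, n)
        edges[:, 1] = -scores + 0.05 * rng.normal(0, 1, n)
        return edges, scores

    def test_loo_matches_brute_force_reference(self, cfg):
        edges, scores = self._toy_cohort()
        run_cfg = cfg.replace(selection_p=0.05)
        res = mc.loo_cv(edges, scores, run_cfg)
        ref = brute_loo_cpm(edges, scores, selection_p=0.05)
        np.testing.assert_allclose(res.predicted, ref, atol=1e-10)

    @pytest.mark.parametrize("variant", ["positive_only", "negative_only"])
    def test_loo_restricted_variants_match_reference(self, cfg, variant):
        edges, scores = self._toy_cohort(seed=8)
        run_cfg = cfg.replace(selection_p=0.05, model_variant=variant)
        res = mc.loo_cv(edges, scores, run_cfg)
        ref = brute_loo_cpm(edges, scores, 0.05, variant)
        np.testing.assert_allclose(res.predicted, ref, atol=1e-10)

    def test_loo_constant_scores_invalid(self, cfg, rng):
        edges = rng.normal(0, 1, (10, 20))
        with pytest.raises(InvalidResultError):
            mc.loo_cv(edges, np.ones(10), cfg)

    def test_all_degenerate_folds_flagged(self, cfg):
        rng = np.random.default_rng(0)
        edges, scores = mc.null_edge_cohort(8, 5, rng)
        res = mc.loo_cv(edges, scores, cfg.replace(selection_p=1e-9))
        assert not res.valid and res.n_degenerate_folds == 8

    def test_leaked_selection_is_optimistic(self, cfg):
        # pooled (un-nested) selection must not underperform the nested CV
        rng = np.random.default_rng(3)
        n, E = 40, 400
        scores = rng.normal(0, 1, n)
        edges = rng.normal(0, 1, (n, E))
        edges[:, :5] += 0.4 * scores[:, None]
        run_cfg = cfg.replace(selection_p=0.01)
        nested = mc.loo_cv(edges, scores, run_cfg)
        leaked = mc.loo_cv(edges, scores, run_cfg, leak_selection=True)
        assert leaked.pearson_r >= nested.pearson_r - 1e-9

    def test_twofold_self_prediction_beats_loo(self, cfg, planted_edges,
                                               planted_cohort):
        scores = planted_cohort.scores_rms_dd
        loo = mc.loo_cv(planted_edges, scores, cfg)
        self_pred, _ = mc.twofold_cv(planted_edges, scores, planted_edges,
                                     scores, cfg)
        assert self_pred.pearson_r >= loo.pearson_r

    def test_twofold_shuffled_test_scores_near_null(self, cfg):
        rng = np.random.default_rng(11)
        n, E = 100, 300
        scores = rng.normal(0, 1, n)
        edges = rng.normal(0, 1, (n, E))
        edges[:, :10] += 0.5 * scores[:, None]
        test_scores = rng.normal(0, 1, n)
        test_edges = rng.normal(0, 1, (n, E))
        test_edges[:, :10] += 0.5 * test_scores[:, None]
        shuffled = rng.permutation(test_scores)
        res, _ = mc.twofold_cv(edges, scores, test_edges, shuffled, cfg)
        # fixed model, exchangeable scores: R ~ N(0, 1/n)
        assert abs(res.pearson_r) < 4.0 / np.sqrt(n)

    def test_twofold_empty_masks_flagged(self, cfg, rng):
        edges, scores = mc.null_edge_cohort(12, 8, rng)
        res, _ = mc.twofold_cv(edges, scores, edges, scores,
                               cfg.replace(selection_p=1e-9))
        assert not res.valid

    def test_twofold_edge_count_mismatch(self, cfg, rng):
        with pytest.raises(mc.DimensionError):
            mc.twofold_cv(rng.normal(0, 1, (10, 5)), rng.normal(0, 1, 10),
                          rng.normal(0, 1, (10, 6)), rng.normal(0, 1, 10),
                          cfg)


class TestPermutationNull:
    def test_deterministic_under_fixed_seed(self, cfg):
        rng = np.random.default_rng(2)
        edges, scores = mc.null_edge_cohort(20, 60, rng)
        run_cfg = cfg.replace(rng_seed=77, selection_p=0.05)
        n1 = mc.permutation_null(edges, scores, run_cfg, n_permutations=100)
        n2 = mc.permutation_null(edges, scores, run_cfg, n_permutations=100)
        np.testing.assert_array_equal(n1.accuracies, n2.accuracies)

    def test_null_mean_not_positively_biased(self, cfg):
        rng = np.random.default_rng(4)
        edges, scores = mc.null_edge_cohort(40, 300, rng)
        null = mc.permutation_null(edges, scores,
                                   cfg.replace(rng_seed=5, selection_p=0.05),
                                   n_permutations=150)
        se = null.sd / np.sqrt(null.accuracies.size)
        assert null.mean <= 0 + 3 * se

    def test_empirical_p_never_zero(self, cfg):
        rng = np.random.default_rng(6)
        edges, scores = mc.null_edge_cohort(20, 60, rng)
        null = mc.permutation_null(edges, scores,
                                   cfg.replace(selection_p=0.05),
                                   n_permutations=100)
        p = null.empirical_p(np.inf)
        assert 0 < p <= 1
        assert p == pytest.approx(1 / 101)
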