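"""NIPALS PLS-LDA: decomposition identities, diagnostics, CV metrics."""

import numpy as np
import pytest

from echinomet import (
    confidence_ellipse,
    cross_validate,
    fit_discriminant,
    fit_nipals_pls,
    permutation_test,
    roc_auc,
    scale,
    tp_loadings,
    vip,
)
from echinomet.plslda import diagnostics
from echinomet.preprocess import FeatureMatrix
from echinomet.synthetic import CohortConfig, simulate_cohort, true_bin_indices
from echinomet import bin_spectra, build_metabolite_library, normalize_total_area

from oracles import auc_by_pair_counting, svd_pls


def random_problem(rng, n=6, p=4):
    X = rng.normal(size=(n, p))
    y = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
    return X, y


class TestNIPALS:
    def test_rank_one_identity(self, rng):
        t = rng.normal(size=8)
        pvec = rng.normal(size=5)
        X = np.outer(t, pvec)
        y = 2.0 * t
        model = fit_nipals_pls(scale(X, "centre"), y, 1)
        assert model.r2x_cum[-1] == pytest.approx(1.0, abs=1e-10)
        assert model.r2y_cum[-1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        """NIPALS agrees with a closed-form SVD-based PLS on random data."""
        for _ in range(50):
            X, y = random_problem(rng)
            model = fit_nipals_pls(scale(X, "centre"), y, 2)
            W, T, P = svd_pls(X, y, 2)
            for a in range(2):
                sign = np.sign(model.W[:, a] @ W[:, a])
                assert model.W[:, a] == pytest.approx(sign * W[:, a], abs=1e-8)
                assert model.T[:, a] == pytest.approx(sign * T[:, a], abs=1e-8)
                assert model.P[:, a] == pytest.approx(sign * P[:, a], abs=1e-8)

    def test_score_orthogonality_and_monotone_r2(self, rng):
        X, y = random_problem(rng, n=12, p=9)
        model = fit_nipals_pls(scale(X, "centre"), y, 4)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms) + 1e-12)
        assert np.all(np.diff(model.r2x_cum) >= -1e-12)
        assert np.all(np.diff(model.r2y_cum) >= -1e-12)

    def test_prediction_equivalence_regression_vector(self, rng):
        """X b reproduces the score-space prediction T r."""
        X, y = random_problem(rng, n=10, p=7)
        model = fit_nipals_pls(scale(X, "centre"), y, 3)
        yhat_b = model.X_ @ model.b
        yhat_t = model.T @ model.r
        assert yhat_b == pytest.approx(yhat_t, abs=1e-8)

    def test_a_exceeding_rank_limit_rejected(self, rng):
        X, y = random_problem(rng, n=4, p=6)
        with pytest.raises(ValueError, match="rank-permitting"):
            fit_nipals_pls(scale(X, "centre"), y, 4)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            fit_nipals_pls(np.zeros((4, 3)), [1, 1, -1, -1], 1)

    def test_truncation_when_not_strict(self, rng):
        t = rng.normal(size=8)
        X = np.outer(t, rng.normal(size=5))
        model = fit_nipals_pls(scale(X, "centre"), 2.0 * t, 3, strict=False)
        assert model.A == 1
        assert model.W.shape == (5, 1)

    def test_agrees_with_sklearn_regression_vector(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_problem(rng, n=14, p=9)
        model = fit_nipals_pls(scale(X, "centre"), y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert model.b == pytest.approx(sk.coef_.ravel(), abs=1e-8)


class TestDiagnostics:
    def test_vip_uniform_weights_all_one(self):
        n, p = 8, 5
        rng = np.random.default_rng(0)
        t = rng.normal(size=n)
        # one-component model with equal weights on every bin
        X = np.outer(t, np.ones(p)) / np.sqrt(p)
        fitted = fit_nipals_pls(scale(X, "none"), t, 1)
        assert vip(fitted) == pytest.approx(np.ones(p), abs=1e-8)

    def test_vip_single_active_bin(self, rng):
        t = rng.normal(size=8)
        p = 6
        X = np.zeros((8, p))
        X[:, 2] = t
        fitted = fit_nipals_pls(scale(X, "none"), t, 1)
        v = vip(fitted)
        assert v[2] == pytest.approx(np.sqrt(p), abs=1e-8)
        assert np.delete(v, 2) == pytest.approx(np.zeros(p - 1), abs=1e-8)

    def test_vip_matches_direct_formula(self, rng):
        X, y = random_problem(rng, n=10, p=7)
        model = fit_nipals_pls(scale(X, "centre"), y, 3)
        p = 7
        ssy = np.array([model.r[a] ** 2 * model.T[:, a] @ model.T[:, a] for a in range(3)])
        expected = np.sqrt(p * sum(ssy[a] * model.W[:, a] ** 2 for a in range(3)) / ssy.sum())
        assert vip(model) == pytest.approx(expected, abs=1e-10)
        assert float(np.sum(vip(model) ** 2)) == pytest.approx(p, rel=1e-6)

    def test_tp_loadings_single_component_proportional_to_loading(self, rng):
        X, y = random_problem(rng, n=9, p=5)
        model = fit_nipals_pls(scale(X, "centre"), y, 1)
        tp = tp_loadings(model)
        ratio = tp / model.P[:, 0]
        assert np.allclose(ratio, ratio[0], rtol=1e-8)

    def test_tp_loadings_antisymmetric_in_y(self, rng):
        X, y = random_problem(rng, n=10, p=6)
        m1 = fit_nipals_pls(scale(X, "centre"), y, 2)
        m2 = fit_nipals_pls(scale(X, "centre"), -y, 2)
        assert tp_loadings(m2) == pytest.approx(-tp_loadings(m1), abs=1e-10)

    def test_tp_loadings_recover_injected_bins(self):
        """Injected bins rank within the top 1.5x truth-set size by |tpLoading|.

        Checked over 20 cohort seeds at the default effect size; the 1.5x
        slack covers bins whose signal is diluted by a shared-metabolite
        overlap in the same bucket.
        """
        library = build_metabolite_library()
        hits = 0
        for seed in range(1, 21):
            cfg = CohortConfig(seed=seed)
            spectra, truth = simulate_cohort(cfg, library, bin_width_ppm=0.05)
            fm = normalize_total_area(bin_spectra(spectra, 0.05, labels=truth.labels))
            tb = true_bin_indices(library, fm.bin_edges)
            model = fit_nipals_pls(scale(fm, "centre"), truth.labels, 3)
            order = np.argsort(-np.abs(tp_loadings(model)))
            top = set(order[: int(1.5 * len(tb))].tolist())
            hits += tb <= top
        assert hits >= 19  # >= 95% of runs


class TestDiscriminant:
    def test_symmetric_clouds_boundary_through_origin(self, rng):
        pts = rng.normal(size=(20, 2))
        T = np.vstack([pts + [3, 0], -(pts + [3, 0])])
        y = np.array([1] * 20 + [-1] * 20)
        bnd = fit_discriminant(T, y)
        assert abs(bnd.intercept) <= 1e-8

    def test_separated_clouds_zero_training_error(self, rng):
        T = np.vstack([rng.normal(size=(10, 3)) + 10, rng.normal(size=(10, 3)) - 10])
        y = np.array([1] * 10 + [-1] * 10)
        bnd = fit_discriminant(T, y)
        assert np.array_equal(bnd.classify(T), y)

    def test_equal_mean_clouds_error_near_chance(self):
        errs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            T = rng.normal(size=(40, 2))
            y = np.array([1] * 20 + [-1] * 20)
            bnd = fit_discriminant(T, y)
            holdout = rng.normal(size=(40, 2))
            y_h = np.array([1] * 20 + [-1] * 20)
            errs.append(np.mean(bnd.classify(holdout) != y_h))
        assert np.mean(errs) == pytest.approx(0.5, abs=0.1)

    def test_singular_covariance_is_regularized(self):
        T = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([-1, -1, 1, 1])
        bnd = fit_discriminant(T, y)  # rank-deficient pooled covariance
        assert np.all(np.isfinite(bnd.coefficients))
        assert np.array_equal(bnd.classify(T), y)


class TestAUC:
    def test_pair_counting_example(self):
        y = [1, 1, -1, -1]
        d = [0.9, 0.3, 0.8, 0.4]
        assert roc_auc(y, d) == pytest.approx(0.5)
        assert roc_auc(y, d) == pytest.approx(auc_by_pair_counting(y, d))

    def test_all_tied_scores_give_half(self):
        assert roc_auc([1, 1, -1, -1], [2.0] * 4) == pytest.approx(0.5)

    def test_invariance_under_monotone_transform_and_sign_flip(self, rng):
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:2] = [1, -1]
        d = rng.normal(size=30)
        a = roc_auc(y, d)
        assert roc_auc(y, np.exp(3 * d)) == pytest.approx(a, abs=1e-12)
        assert roc_auc(y, -d) == pytest.approx(1.0 - a, abs=1e-12)


class TestCrossValidation:
    def test_perfect_separation_on_default_cohort(self, fm_default):
        cv = cross_validate(fm_default, A=3, folds=5, repeats=3, seed=0)
        assert cv.error == 0.0
        assert cv.sensitivity == 1.0 and cv.specificity == 1.0
        assert cv.auc == 1.0

    def test_pooled_scores_have_expected_size(self, fm_small):
        cv = cross_validate(fm_small, A=2, folds=5, repeats=4, seed=1)
        assert cv.cv_scores.size == 4 * len(fm_small.sample_ids)

    def test_requires_two_folds(self, fm_small):
        with pytest.raises(ValueError):
            cross_validate(fm_small, A=2, folds=1)

    def test_permutation_floor_attained_on_strong_effect(self, fm_small):
        p, obs, perm = permutation_test(fm_small, A=2, n_perm=99, seed=3)
        assert obs == 1.0
        assert p == pytest.approx(1.0 / 100.0)

    def test_permutation_p_uninformative_data_not_significant(self):
        """Label-free data gives p spread over (0, 1], not clustered low."""
        rng = np.random.default_rng(9)
        ps = []
        for rep in range(10):
            X = rng.normal(size=(12, 15))
            y = np.array([1] * 6 + [-1] * 6)
            fm = FeatureMatrix(X, y, [(15.0 - j, 14.0 - j) for j in range(15)],
                               [f"S{i}" for i in range(12)])
            p, _, _ = permutation_test(fm, A=2, n_perm=99, folds=3, seed=rep)
            ps.append(p)
        assert np.mean(ps) > 0.2
        assert max(ps) > 0.5


class TestConfidenceEllipse:
    def test_isotropic_scores_give_equal_axes(self):
        ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        T = np.column_stack([np.cos(ang), np.sin(ang)])
        ell = confidence_ellipse(T)
        ratio = ell["semi_axes"][0] / ell["semi_axes"][1]
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_chi2_scale_matches_closed_form(self):
        """For 2 df, chi2.ppf(q, 2) = -2 ln(1 - q)."""
        rng = np.random.default_rng(4)
        T = rng.normal(size=(50, 2))
        ell = confidence_ellipse(T, level=0.95)
        assert ell["chi2_scale"] == pytest.approx(-2.0 * np.log(0.05), rel=1e-12)

    def test_rotation_equivariance(self, rng):
        T = rng.normal(size=(40, 2)) @ np.diag([3.0, 1.0])
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        e1 = confidence_ellipse(T)
        e2 = confidence_ellipse(T @ R.T)
        assert e2["semi_axes"] == pytest.approx(e1["semi_axes"], rel=1e-9)
        diff = (e2["angle_deg"] - e1["angle_deg"]) % 180
        assert min(diff, 180 - diff) == pytest.approx(30, abs=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))
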