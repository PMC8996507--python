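"""PCA-CVA engine: reduction, discrimination, tests, back-projection,
confusion summaries, SMA regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from wingmorph import (PCACVADiscriminant, back_project,
                       classify_and_summarize, cva_two_group,
                       displacement_field, fit_pca_cva, hotelling_t2_boot,
                       jackknife_loo, pca_reduce, pixel_difference_map,
                       sma_regression)
from wingmorph.discriminant import (InsufficientDataError,
                                    SingularWithinGroupError,
                                    ZeroVarianceError, mcc_from_counts)


def two_clouds(rng, n=20, p=6, gap=8.0):
    a = rng.normal(size=(n, p))
    b = rng.normal(size=(n, p))
    a[:, 0] += gap
    X = np.vstack([a, b])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestPCA:
    def test_variance_in_one_coordinate_retains_one_component(self, rng):
        X = np.zeros((10, 4))
        X[:, 2] = rng.normal(size=10)
        model, scores = pca_reduce(X, 0.95)
        assert model.n_retained == 1
        assert model.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        model, _ = pca_reduce(rng.normal(size=(15, 7)), 0.95)
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(model.basis.T @ model.basis,
                           np.eye(model.n_retained), atol=1e-9)

    def test_full_retention_reconstructs_centered_data(self, rng):
        X = rng.normal(size=(12, 5))
        model, scores = pca_reduce(X, 1.0)
        recon = scores @ model.basis.T
        assert np.linalg.norm((X - X.mean(axis=0)) - recon) < 1e-8

    def test_constant_data_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pca_reduce(np.ones((5, 3)))


class TestCVA:
    def test_separable_clouds_sign_separate(self, rng):
        X, y = two_clouds(rng)
        model = cva_two_group(X, y)
        assert (model.scores[y == "A"] > 0).all()
        assert (model.scores[y == "B"] < 0).all()
        # conventions: grand mean 0, pooled within-group variance 1
        assert model.scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_null_means_stay_close(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array(["A", "B"] * 20)
        model = cva_two_group(X, y)
        diff = abs(model.scores[y == "A"].mean() - model.scores[y == "B"].mean())
        assert diff < 3.0   # unit within-group variance scale

    def test_direction_matches_random_search_oracle(self, rng):
        """w maximizes between/within variance ratio; compare with 10^4
        random directions on a 3-component toy."""
        X, y = two_clouds(rng, n=15, p=3, gap=3.0)
        model = cva_two_group(X, y)

        def ratio(v):
            s = X @ v
            a, b = s[y == "A"], s[y == "B"]
            within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return (a.mean() - b.mean()) ** 2 / within

        dirs = rng.normal(size=(10000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        best = dirs[np.argmax([ratio(v) for v in dirs])]
        cos = abs(best @ model.w / np.linalg.norm(model.w))
        assert cos > 0.999

    def test_singular_within_group_refused(self):
        X = np.array([[0.0, 0], [0, 0], [1, 1], [1, 1]])
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(SingularWithinGroupError):
            cva_two_group(X, y)


class TestHotelling:
    def test_identical_groups_give_zero_t2_p_one(self):
        X = np.tile(np.arange(8.0)[:, None], (2, 2))
        X[:, 1] *= -0.5
        X = X + np.arange(16)[:, None] * 0.0
        y = np.array(["A"] * 8 + ["B"] * 8)
        X[8:] = X[:8]   # duplicate the data across groups
        res = hotelling_t2_boot(X, y, B=99, seed=0)
        assert res.T2_observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_univariate_t2_equals_squared_t(self, rng):
        x = np.concatenate([rng.normal(0, 1, 12), rng.normal(1.2, 1, 9)])
        y = np.array(["A"] * 12 + ["B"] * 9)
        res = hotelling_t2_boot(x, y, B=9, seed=0)
        from scipy import stats
        t, _ = stats.ttest_ind(x[:12], x[12:], equal_var=True)
        assert res.T2_observed == pytest.approx(t ** 2, abs=1e-9)

    def test_singleton_group_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(InsufficientDataError):
            hotelling_t2_boot(X, np.array(["A", "B", "B", "B"]), B=9)


class TestBackProjection:
    def test_zero_score_is_grand_mean(self, rng):
        X, y = two_clouds(rng)
        model = fit_pca_cva(X, y)
        np.testing.assert_allclose(back_project(0.0, model), X.mean(axis=0),
                                   atol=1e-9)

    def test_group_mean_round_trip(self, rng):
        X, y = two_clouds(rng)
        model = fit_pca_cva(X, y)
        tA = model.group_mean_scores[0]
        recon = back_project(tA, model)
        u = model.w / np.linalg.norm(model.w)
        proj_recon = model.pc_model.transform(recon[None])[0] @ u
        proj_meanA = model.pc_model.transform(X[y == "A"]).mean(axis=0) @ u
        assert proj_recon == pytest.approx(proj_meanA, abs=1e-9)

    def test_rescore_recovers_t(self, rng):
        X, y = two_clouds(rng)
        model = fit_pca_cva(X, y)
        for t in (-1.3, 0.0, 2.4):
            s = model.score_data(back_project(t, model)[None])[0]
            assert s == pytest.approx(t, abs=1e-9)


class TestModelContrasts:
    def test_identical_models_zero_field_and_scaling(self):
        m = np.arange(76.0)
        base, vec = displacement_field(m, m)
        assert np.all(vec == 0.0)
        lo, hi = np.zeros(76), np.arange(76.0)
        _, v4 = displacement_field(lo, hi, exaggeration=4)
        _, v1 = displacement_field(lo, hi, exaggeration=1)
        np.testing.assert_allclose(v4, 4 * v1)

    def test_template_construction_shows_up_in_displacements(self):
        """Synthetic groups built with the narrowing template differ most at
        the template's largest-displacement (costal / posterior-margin)
        points."""
        from wingmorph.template import NARROWING_TEMPLATE, wing_template
        base = wing_template("forewing").base_config
        lo = (base - 0.02 * NARROWING_TEMPLATE).reshape(-1)
        hi = (base + 0.02 * NARROWING_TEMPLATE).reshape(-1)
        _, vec = displacement_field(lo, hi)
        mags = np.linalg.norm(vec, axis=1)
        tmpl_mags = np.linalg.norm(NARROWING_TEMPLATE, axis=1)
        assert np.argmax(mags) == np.argmax(tmpl_mags)

    def test_pixel_difference_map_symmetric_and_zero_on_identity(self, rng):
        a = rng.uniform(0, 255, 12 * 5)
        b = rng.uniform(0, 255, 12 * 5)
        d0, _ = pixel_difference_map(a, a, frame=(12, 5))
        assert np.all(d0 == 0.0)
        dab, _ = pixel_difference_map(a, b, frame=(12, 5))
        dba, _ = pixel_difference_map(b, a, frame=(12, 5))
        np.testing.assert_allclose(dab, dba)


class TestConfusion:
    def test_perfect_and_chance_summaries(self, rng):
        X, y = two_clouds(rng, n=10)
        model = fit_pca_cva(X, y)
        summ = classify_and_summarize(model, model.pc_model.transform(X), y)
        assert summ.accuracy == 1.0 and summ.mcc == 1.0
        assert mcc_from_counts(np.array([[5, 5], [5, 5]])) == 0.0

    def test_mcc_formula_oracle(self):
        counts = np.array([[8, 2], [3, 7]])
        # direct evaluation: (8*7 - 2*3) / sqrt(10*11*9*10)
        assert mcc_from_counts(counts) == pytest.approx(0.5025, abs=1e-4)
        # cross-check against sklearn on expanded label vectors
        true = ["A"] * 10 + ["B"] * 10
        pred = ["A"] * 8 + ["B"] * 2 + ["A"] * 3 + ["B"] * 7
        assert mcc_from_counts(counts) == pytest.approx(
            matthews_corrcoef(true, pred))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15))
    def test_mcc_bounded_and_transpose_symmetric(self, tp, fn, fp, tn):
        counts = np.array([[tp, fn], [fp, tn]])
        m = mcc_from_counts(counts)
        assert -1.0 <= m <= 1.0
        assert m == pytest.approx(mcc_from_counts(counts.T))


class TestJackknife:
    def test_separable_groups_reach_perfect_jackknife(self, rng):
        X, y = two_clouds(rng, n=12, gap=10.0)
        assert jackknife_loo(X, y).accuracy == 1.0

    def test_matches_explicit_loop_oracle_on_12_specimen_toy(self, rng):
        X, y = two_clouds(rng, n=6, p=4, gap=1.5)
        result = jackknife_loo(X, y, var_threshold=0.95)
        counts = np.zeros((2, 2), dtype=int)
        groups = ["A", "B"]
        for i in range(12):
            mask = np.arange(12) != i
            model = fit_pca_cva(X[mask], y[mask], 0.95)
            pred = model.classify(model.score_data(X[i][None]))[0]
            counts[groups.index(y[i]), groups.index(pred)] += 1
        np.testing.assert_array_equal(result.counts, counts)

    def test_posthoc_beats_jackknife_on_average(self, rng):
        post, jack = [], []
        for rep in range(10):
            r = np.random.default_rng(rep)
            X, y = two_clouds(r, n=8, p=10, gap=1.0)
            model = fit_pca_cva(X, y)
            post.append(classify_and_summarize(
                model, model.pc_model.transform(X), y).accuracy)
            jack.append(jackknife_loo(X, y).accuracy)
        assert np.mean(post) >= np.mean(jack)


class TestSMA:
    def test_exact_linear_relations(self):
        x = np.linspace(0, 5, 20)
        res = sma_regression(x, 2 * x, B=9, seed=0)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)
        res2 = sma_regression(x, -x + 1, B=9, seed=0)
        assert res2.slope == pytest.approx(-1.0)
        assert res2.intercept == pytest.approx(1.0)

    def test_slope_is_sd_ratio_under_correlation(self):
        slopes, ratios = [], []
        for s in range(200):
            r = np.random.default_rng(s)
            x = r.normal(size=100)
            y = 0.6 * x + np.sqrt(1 - 0.36) * r.normal(size=100)
            res = sma_regression(x, y, B=1, seed=0)
            slopes.append(res.slope)
            ratios.append(y.std(ddof=1) / x.std(ddof=1))
        assert np.mean(slopes) == pytest.approx(np.mean(ratios), rel=0.1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            sma_regression(np.ones(5), np.arange(5.0), B=1)


class TestPipelineInvariance:
    def test_scores_invariant_under_orthogonal_rotation_of_variables(self, rng):
        X, y = two_clouds(rng, n=10, p=6, gap=2.0)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        s1 = fit_pca_cva(X, y).scores
        s2 = fit_pca_cva(X @ Q, y).scores
        assert np.abs(s1 - s2).max() < 1e-6


class TestEstimator:
    def test_fit_predict_and_decision_function(self, rng):
        X, y = two_clouds(rng, n=10, gap=8.0)
        est = PCACVADiscriminant().fit(X, y)
        assert (est.predict(X) == y).all()
        assert est.decision_function(X).shape == (20,)
        assert list(est.classes_) == ["A", "B"]
        assert est.get_params() == {"var_threshold": 0.95}
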