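"""Column filtering, NIPALS PLS, LOO cross-validation, internal statistics."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from trpa1_qsar import pls


def _loo_ols_press(X, y):
    """Closed-form leave-one-out PRESS of ordinary least squares (with
    intercept) via the hat-matrix identity: e_(-i) = e_i / (1 - h_ii)."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X])
    H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    resid = y - H @ y
    return float(((resid / (1.0 - np.diag(H))) ** 2).sum())


class TestFilterColumns:
    def test_constant_column_dropped_at_any_positive_threshold(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        mask = pls.filter_columns(X, 1e-6)
        assert mask.tolist() == [False, True]

    def test_zero_threshold_keeps_everything(self):
        X = np.zeros((4, 3))
        assert pls.filter_columns(X, 0.0).all()

    def test_threshold_compares_sample_std(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(50)
        base = (base - base.mean()) / base.std(ddof=1)
        X = np.column_stack([1.9 * base, 2.1 * base])
        assert pls.filter_columns(X, 2.0).tolist() == [False, True]

    def test_everything_dropped_is_an_error(self):
        X = np.random.default_rng(1).normal(0, 0.01, (5, 4))
        with pytest.raises(ValueError, match="threshold"):
            pls.filter_columns(X, 2.0)


class TestFitPls:
    def test_single_relevant_column_fits_exactly_with_one_component(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 1))
        y = 3.0 * X[:, 0] + 1.0
        m = pls.fit_pls(X, y, 1)
        assert np.abs(m.fitted - y).max() < 1e-8

    def test_full_components_equal_ordinary_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 4))
        y = rng.standard_normal(6)
        m = pls.fit_pls(X, y, 4)
        Z = np.column_stack([np.ones(6), X])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(m.fitted, Z @ beta, atol=1e-8)

    def test_duplicating_columns_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 6))
        y = rng.standard_normal(10)
        m1 = pls.fit_pls(X, y, 3)
        m2 = pls.fit_pls(np.hstack([X, X]), y, 3)
        np.testing.assert_allclose(m1.fitted, m2.fitted, atol=1e-8)

    def test_agrees_with_sklearn_nipals(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 30))
        y = X[:, :3] @ [1.0, -2.0, 0.5] + rng.normal(0, 0.1, 15)
        for a in (1, 2, 4):
            mine = pls.fit_pls(X, y, a)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                mine.fitted, ref.predict(X).ravel(), atol=1e-8
            )

    def test_predict_reproduces_stored_fitted_values(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((9, 20))
        y = rng.standard_normal(9)
        m = pls.fit_pls(X, y, 3, scaling="comfa_std")
        np.testing.assert_allclose(m.predict(X), m.fitted, atol=1e-10)

    def test_zero_variance_y_rejected(self):
        X = np.random.default_rng(7).standard_normal((5, 3))
        with pytest.raises(ValueError, match="variance"):
            pls.fit_pls(X, np.ones(5), 1)

    def test_component_bounds_enforced(self):
        X = np.random.default_rng(8).standard_normal((5, 3))
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            pls.fit_pls(X, y, 5)


class TestLooQ2:
    def test_press_matches_explicit_sklearn_refits(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((8, 12))
        y = X[:, 0] - X[:, 5] + rng.normal(0, 0.3, 8)
        cv = pls.loo_q2(X, y, max_components=3)
        for a in (1, 2, 3):
            press = 0.0
            for i in range(8):
                keep = np.arange(8) != i
                ref = PLSRegression(n_components=a, scale=False).fit(X[keep], y[keep])
                press += (ref.predict(X[i : i + 1]).item() - y[i]) ** 2
            assert cv.press_by_ncomp[a - 1] == pytest.approx(press, abs=1e-10)

    def test_full_component_loo_equals_closed_form_ols_press(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        cv = pls.loo_q2(X, y, max_components=3)
        assert cv.press_by_ncomp[2] == pytest.approx(_loo_ols_press(X, y), abs=1e-10)

    def test_noiseless_linear_data_reaches_q2_of_one(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((15, 8))
        y = X @ rng.standard_normal(8)
        cv = pls.loo_q2(X, y, max_components=8)
        assert cv.q2_by_ncomp[-1] > 0.999
        assert cv.onc == int(np.argmax(cv.q2_by_ncomp)) + 1

    def test_onc_tie_breaks_to_smallest(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((9, 1))
        y = 2.0 * X[:, 0]
        cv = pls.loo_q2(X, y, max_components=5)  # clipped to 1 column
        assert cv.onc == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pls.loo_q2(np.zeros((2, 2)), np.array([0.0, 1.0]))


class TestInternalStats:
    def test_perfect_fit(self):
        y = np.arange(10.0)
        r2, see, f_val = pls.regression_stats(y, y, 2)
        assert r2 == pytest.approx(1.0)
        assert see == pytest.approx(0.0)

    def test_published_training_see_for_both_models(self, activity_table):
        train = activity_table[activity_table.subset == "train"]
        _, see_comfa, _ = pls.regression_stats(
            train.pec50_actual, train.pec50_pred_comfa, 6
        )
        _, see_comsia, _ = pls.regression_stats(
            train.pec50_actual, train.pec50_pred_comsia, 6
        )
        assert see_comfa == pytest.approx(0.154, abs=1e-3)
        assert see_comsia == pytest.approx(0.180, abs=1e-3)

    def test_too_few_samples_for_components_rejected(self):
        with pytest.raises(ValueError):
            pls.regression_stats(np.arange(5.0), np.arange(5.0), 4)

    def test_field_contributions_normalized(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((12, 10))
        y = X[:, 0] + 0.5 * X[:, 7] + rng.normal(0, 0.1, 12)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        m = pls.fit_pls(X, y, 2, scaling="comfa_std", channel_of_column=labels)
        stats = pls.internal_stats(m, X, y)
        contrib = stats.field_contributions
        assert set(contrib) == {"a", "b"}
        assert all(v >= 0 for v in contrib.values())
        assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-9)


class TestBlockScaling:
    def test_blocks_get_equal_pooled_variance(self):
        rng = np.random.default_rng(14)
        X = np.hstack([rng.normal(0, 10, (20, 4)), rng.normal(0, 0.1, (20, 4))])
        labels = np.array(["big"] * 4 + ["small"] * 4)
        scales = pls.block_scales(X, labels, "comfa_std")
        Xs = (X - X.mean(axis=0)) / scales
        v_big = Xs[:, :4].std(ddof=0)
        v_small = Xs[:, 4:].std(ddof=0)
        assert v_big == pytest.approx(v_small, rel=1e-9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pls.block_scales(np.ones((3, 2)), None, "bogus")
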