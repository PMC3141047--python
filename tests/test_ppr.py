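"""Projection pursuit regression: recovery, invariants, serialization."""

import numpy as np
import pytest

from gsppr import (
    DescriptorTable,
    PPRModel,
    ValidationError,
    fit_ols,
    fit_ppr,
    r2,
    term_importance,
)

from conftest import make_table


def ridge_table(n=200, p=5, seed=42, fn=lambda t: t**2, direction=None, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    a = np.zeros(p)
    a[0] = 1.0
    if direction is not None:
        a = np.asarray(direction, dtype=float)
        a = a / np.linalg.norm(a)
    y = fn(X @ a) + noise * rng.standard_normal(n)
    table = DescriptorTable(
        [f"c{i}" for i in range(n)], [f"d{j}" for j in range(p)], X, y
    )
    return table, a


class TestSingleRidgeRecovery:
    def test_planted_quadratic_ridge(self):
        table, a = ridge_table(n=200, p=5, seed=42)
        model = fit_ppr(table, nterms=1, df=10, seed=1)
        cos = abs(float(model.terms[0].direction @ a))
        assert cos >= 0.99
        assert r2(table.activity, model.predict(table)) >= 0.999

    def test_oblique_direction(self):
        table, a = ridge_table(
            n=250, p=4, seed=7, direction=[1.0, -1.0, 0.5, 0.0], fn=np.tanh
        )
        model = fit_ppr(table, nterms=1, df=6, seed=0)
        assert abs(float(model.terms[0].direction @ a)) >= 0.99

    def test_linear_limit_matches_ols(self):
        table = make_table(n=150, p=5, seed=3, coefficients=[1.0, -2.0, 0.5],
                           noise_sd=0.3)
        model = fit_ppr(table, nterms=1, df=4, seed=0)
        ols = fit_ols(table, list(table.descriptor_names))
        ppr_r2 = r2(table.activity, model.predict(table))
        assert ppr_r2 == pytest.approx(ols.r2, abs=1e-3)


class TestStructure:
    def test_exact_term_count_no_pruning(self):
        table, _ = ridge_table(n=100, p=3, seed=2, noise=0.2)
        model = fit_ppr(table, nterms=3, max_terms=3, df=4, seed=0)
        assert len(model.terms) == 3
        assert model.hyperparams.max_terms == 3

    def test_nterms_exceeding_max_terms_rejected(self):
        table, _ = ridge_table(n=50, p=3, seed=2)
        with pytest.raises(ValidationError):
            fit_ppr(table, nterms=4, max_terms=2, df=4)

    def test_directions_unit_norm(self):
        table, _ = ridge_table(n=120, p=6, seed=5, noise=0.3)
        model = fit_ppr(table, nterms=2, max_terms=4, df=5, seed=0)
        for term in model.terms:
            assert np.linalg.norm(term.direction) == pytest.approx(1.0, abs=1e-9)

    def test_residuals_orthogonal_to_term_outputs(self):
        table, _ = ridge_table(n=150, p=4, seed=9, noise=0.3)
        model = fit_ppr(table, nterms=2, max_terms=3, df=5, seed=0)
        resid = table.activity - model.predict(table)
        Xs = model.standardize(table.values)
        for term in model.terms:
            g = np.asarray(term.smoother(term.project(Xs)))
            assert abs(float(resid @ g)) / len(resid) < 1e-6


class TestPredict:
    def test_training_predictions_reproduce_fitted_values(self):
        table, _ = ridge_table(n=100, p=4, seed=11, noise=0.2)
        model = fit_ppr(table, nterms=2, max_terms=3, df=5, seed=0)
        np.testing.assert_allclose(
            model.predict(table), model.fitted_values, atol=1e-10
        )

    def test_all_zero_scales_predict_center(self):
        table, _ = ridge_table(n=60, p=3, seed=4, noise=0.1)
        model = fit_ppr(table, nterms=1, df=4, seed=0)
        for term in model.terms:
            term.scale = 0.0
        pred = model.predict(table)
        np.testing.assert_allclose(pred, model.response_center, atol=1e-12)

    def test_hand_evaluated_piecewise_smoother(self):
        # collinear knots make the natural spline the exact straight line,
        # so probe values (and linear extrapolation) are hand-computable
        from gsppr.smoothing import RidgeSmoother
        from gsppr.ppr import PPRHyperparams, RidgeTerm

        knots = np.array([-1.0, 0.0, 1.0, 2.0])
        sm = RidgeSmoother(knots=knots, values=3.0 * knots + 1.0)
        term = RidgeTerm(direction=np.array([1.0, 0.0]), smoother=sm, scale=2.0)
        model = PPRModel(
            terms=[term],
            descriptor_names=("a", "b"),
            x_mean=np.zeros(2),
            x_sd=np.ones(2),
            response_center=10.0,
            hyperparams=PPRHyperparams(nterms=1),
        )
        X = np.array([[0.5, 9.9], [-1.0, 0.0], [3.0, -5.0]])  # last row extrapolates
        expected = 10.0 + 2.0 * (3.0 * X[:, 0] + 1.0)
        pred, extrap = model.predict(X, return_extrapolated=True)
        np.testing.assert_allclose(pred, expected, atol=1e-12)
        assert list(extrap) == [False, False, True]

    def test_column_mismatch_errors(self):
        table, _ = ridge_table(n=60, p=3, seed=4)
        model = fit_ppr(table, nterms=1, df=4, seed=0)
        with pytest.raises(ValidationError):
            model.predict(np.ones((5, 7)))


class TestImportance:
    def test_single_term_share_is_one(self):
        table, _ = ridge_table(n=80, p=3, seed=6, noise=0.2)
        model = fit_ppr(table, nterms=1, df=4, seed=0)
        np.testing.assert_allclose(term_importance(model), [1.0], atol=1e-12)

    def test_two_equal_orthogonal_ridges_share_evenly(self):
        rng = np.random.default_rng(13)
        n, p = 400, 4
        X = rng.standard_normal((n, p))
        y = np.sin(2 * X[:, 0]) + np.sin(2 * X[:, 1]) + 0.05 * rng.standard_normal(n)
        table = DescriptorTable(
            [f"c{i}" for i in range(n)], [f"d{j}" for j in range(p)], X, y
        )
        model = fit_ppr(table, nterms=2, max_terms=2, df=8, seed=0)
        shares = term_importance(model)
        np.testing.assert_allclose(shares, [0.5, 0.5], atol=0.1)

    def test_shares_sum_to_one(self):
        table, _ = ridge_table(n=150, p=5, seed=8, noise=0.4)
        model = fit_ppr(table, nterms=3, max_terms=4, df=4, seed=2)
        assert float(term_importance(model).sum()) == pytest.approx(1.0, abs=1e-9)


class TestFitInvariants:
    def test_forward_rss_nonincreasing(self):
        rng = np.random.default_rng(17)
        n, p = 150, 5
        X = rng.standard_normal((n, p))
        y = np.tanh(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.3 * rng.standard_normal(n)
        table = DescriptorTable(
            [f"c{i}" for i in range(n)], [f"d{j}" for j in range(p)], X, y
        )
        rss = []
        for mt in (1, 2, 3, 4):
            model = fit_ppr(table, nterms=mt, max_terms=mt, df=5, seed=0, optlevel=0)
            resid = y - model.predict(table)
            rss.append(float(resid @ resid))
        assert all(b <= a + 1e-8 for a, b in zip(rss, rss[1:]))

    def test_more_refitting_never_hurts_training_fit(self):
        rng = np.random.default_rng(19)
        n, p = 120, 5
        X = rng.standard_normal((n, p))
        y = np.tanh(X[:, 0]) + X[:, 1] ** 2 + 0.3 * rng.standard_normal(n)
        table = DescriptorTable(
            [f"c{i}" for i in range(n)], [f"d{j}" for j in range(p)], X, y
        )
        rss = {}
        for level in (0, 2):
            model = fit_ppr(table, nterms=2, max_terms=4, df=5, seed=0, optlevel=level)
            resid = y - model.predict(table)
            rss[level] = float(resid @ resid)
        assert rss[2] <= rss[0] + 1e-8

    def test_optlevel_three_aliases_two(self):
        table, _ = ridge_table(n=100, p=4, seed=23, noise=0.3)
        m2 = fit_ppr(table, nterms=1, max_terms=3, df=4, seed=0, optlevel=2)
        m3 = fit_ppr(table, nterms=1, max_terms=3, df=4, seed=0, optlevel=3)
        np.testing.assert_allclose(m2.predict(table), m3.predict(table), atol=1e-12)

    def test_reproducible_given_seed(self):
        table, _ = ridge_table(n=100, p=4, seed=29, noise=0.4)
        m1 = fit_ppr(table, nterms=2, max_terms=3, df=5, seed=11)
        m2 = fit_ppr(table, nterms=2, max_terms=3, df=5, seed=11)
        np.testing.assert_allclose(m1.predict(table), m2.predict(table), atol=0)
        for t1, t2 in zip(m1.terms, m2.terms):
            np.testing.assert_allclose(t1.direction, t2.direction, atol=0)

    def test_invariant_to_affine_rescaling_of_one_column(self):
        table, _ = ridge_table(n=120, p=4, seed=31, noise=0.2)
        rescaled = DescriptorTable(
            list(table.compound_ids),
            list(table.descriptor_names),
            table.values.copy(),
            table.activity.copy(),
        )
        rescaled.values[:, 2] = 3.0 * rescaled.values[:, 2] + 5.0
        m1 = fit_ppr(table, nterms=1, df=5, seed=0)
        m2 = fit_ppr(rescaled, nterms=1, df=5, seed=0)
        np.testing.assert_allclose(
            m1.predict(table), m2.predict(rescaled), atol=1e-6
        )

    def test_needs_enough_rows_for_df(self):
        table, _ = ridge_table(n=8, p=2, seed=1)
        with pytest.raises(ValidationError):
            fit_ppr(table, nterms=1, df=7)


class TestSerialization:
    def test_json_round_trip_exact_predictions(self, tmp_path):
        table, _ = ridge_table(n=100, p=4, seed=37, noise=0.3)
        model = fit_ppr(table, nterms=2, max_terms=3, df=5, seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        back = PPRModel.load(path)
        np.testing.assert_allclose(back.predict(table), model.predict(table), atol=1e-12)
        assert back.hyperparams.to_dict() == model.hyperparams.to_dict()

    def test_unknown_format_version_rejected(self):
        with pytest.raises(ValidationError):
            PPRModel.from_dict({"format_version": 99})
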