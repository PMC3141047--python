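"""Metrics, k-fold CV, grid search and the PCA split diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsppr import (
    GridSpec,
    PPRHyperparams,
    ValidationError,
    grid_search,
    kfold_cv,
    loo_r2,
    make_folds,
    pca_diagnostic,
    r2,
    rmse,
    split_train_test,
)

from conftest import make_table


class TestMetrics:
    def test_rmse_identical_vectors_zero(self):
        v = np.arange(10.0)
        assert rmse(v, v) == 0.0

    def test_rmse_hand_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5), abs=1e-12)

    def test_rmse_constant_offset(self):
        v = np.arange(8.0)
        assert rmse(v, v + 1.7) == pytest.approx(1.7, abs=1e-12)

    def test_r2_affine_invariance(self):
        v = np.random.default_rng(0).standard_normal(20)
        assert r2(v, 2 * v + 1) == pytest.approx(1.0, abs=1e-12)

    def test_r2_large_sample_null(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert r2(a, b) < 0.01

    def test_r2_symmetric(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        assert r2(a, b) == pytest.approx(r2(b, a), abs=1e-12)

    def test_definitional_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            # brute-force loops
            acc = 0.0
            for x, y in zip(a, b):
                acc += (x - y) ** 2
            assert rmse(a, b) == pytest.approx(np.sqrt(acc / n), abs=1e-12)
            am, bm = sum(a) / n, sum(b) / n
            num = sum((x - am) * (y - bm) for x, y in zip(a, b))
            den = np.sqrt(
                sum((x - am) ** 2 for x in a) * sum((y - bm) ** 2 for y in b)
            )
            assert r2(a, b) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            r2(np.ones(5), np.arange(5.0))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        n=st.integers(min_value=3, max_value=50),
        scale=st.floats(min_value=0.01, max_value=100.0),
        offset=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_metric_invariances(self, seed, n, scale, offset):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        # rmse: symmetric, nonnegative, shift-equivariant in a common offset
        assert rmse(a, b) == pytest.approx(rmse(b, a), abs=1e-12)
        assert rmse(a, b) >= 0
        assert rmse(a + offset, b + offset) == pytest.approx(rmse(a, b), abs=1e-9)
        # r2: invariant under positive affine maps of either argument
        assert r2(a, scale * b + offset) == pytest.approx(r2(a, b), abs=1e-9)


class TestKFold:
    def test_folds_partition(self):
        folds = make_folds(23, 5, seed=3)
        joined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(joined, np.arange(23))
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_loo_equivalence_for_linear_model(self):
        table = make_table(n=30, p=3, seed=5, coefficients=[1.0, -0.5, 0.3],
                           noise_sd=0.8)
        names = list(table.descriptor_names)
        cv = kfold_cv(table, names, k=30, seed=0)
        press_cv = float(((table.activity - cv.predictions) ** 2).sum())
        sst = float(((table.activity - table.activity.mean()) ** 2).sum())
        assert 1 - press_cv / sst == pytest.approx(loo_r2(table, names), abs=1e-8)

    def test_noiseless_linear_data_perfect_cv(self):
        table = make_table(n=40, p=3, seed=6, coefficients=[2.0, 1.0])
        cv = kfold_cv(table, list(table.descriptor_names), k=5, seed=1)
        assert cv.r2_cv == pytest.approx(1.0, abs=1e-6)
        assert cv.rmse_cv == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_reproducible(self):
        table = make_table(n=50, p=4, seed=7, coefficients=[1.0], noise_sd=0.5)
        a = kfold_cv(table, ["d00"], k=5, seed=9)
        b = kfold_cv(table, ["d00"], k=5, seed=9)
        np.testing.assert_allclose(a.predictions, b.predictions, atol=0)

    def test_cv_restricted_to_training_rows(self):
        table = make_table(n=60, p=3, seed=8, coefficients=[1.0], noise_sd=0.3)
        labelled = split_train_test(table, test_fraction=0.25, seed=0)
        cv = kfold_cv(labelled, ["d00"], k=5, seed=0)
        assert len(cv.predictions) == int((labelled.split == "train").sum())

    def test_works_with_ppr_spec(self):
        table = make_table(n=60, p=3, seed=10, coefficients=[1.5], noise_sd=0.3)
        cv = kfold_cv(table, PPRHyperparams(nterms=1, df=3), k=4, seed=0)
        assert cv.r2_cv > 0.8


class TestGridSearch:
    @staticmethod
    def two_ridge_table(seed=0, n=100, p=5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = np.tanh(1.5 * X[:, 0]) + X[:, 1] ** 2 + 0.3 * rng.standard_normal(n)
        from gsppr import DescriptorTable

        return DescriptorTable(
            [f"c{i}" for i in range(n)], [f"d{j}" for j in range(p)], X, y
        )

    def test_single_cell_grid(self):
        table = self.two_ridge_table()
        grid = GridSpec(nterms=[2], max_terms=[2], df=[5.0], optlevel=[0])
        res = grid_search(table, grid, k=4, seed=0)
        assert res.best_cell.to_dict() == {
            "nterms": 2, "max_terms": 2, "df": 5.0, "optlevel": 0,
        }

    def test_best_matches_argmin_of_emitted_table(self):
        table = self.two_ridge_table(seed=2)
        grid = GridSpec(nterms=[1, 2], max_terms=[2, 3], df=[4.0], optlevel=[0])
        res = grid_search(table, grid, k=4, seed=1)
        frame = res.to_frame()
        row = frame.loc[frame["cv_rmse"].idxmin()]
        assert res.best_cell.nterms == int(row["nterms"])
        assert res.best_cell.max_terms == int(row["max_terms"])
        assert float(row["cv_rmse"]) == frame["cv_rmse"].min()

    def test_infeasible_cells_skipped(self):
        grid = GridSpec(nterms=[2, 3], max_terms=[2], df=[4.0], optlevel=[0])
        cells = grid.cells()
        assert all(c.nterms <= c.max_terms for c in cells)
        assert len(cells) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            GridSpec(nterms=[5], max_terms=[2], df=[4.0], optlevel=[0]).cells()

    def test_cell_count_matches_admissible_cells(self):
        table = self.two_ridge_table(seed=3)
        grid = GridSpec(nterms=[1, 2], max_terms=[1, 2], df=[4.0], optlevel=[0])
        res = grid_search(table, grid, k=3, seed=0)
        assert len(res.records) == 3  # (1,1), (1,2), (2,2)


class TestPCADiagnostic:
    def test_two_perfectly_correlated_descriptors(self):
        table = make_table(n=30, p=2, seed=1)
        table.values[:, 1] = 2.0 * table.values[:, 0] - 1.0
        res = pca_diagnostic(table, list(table.descriptor_names))
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_explained_variance_sums_to_100(self):
        table = make_table(n=50, p=6, seed=2)
        res = pca_diagnostic(table, list(table.descriptor_names))
        assert float(res.explained_pct.sum()) == pytest.approx(100.0, abs=1e-9)

    def test_scores_match_svd_oracle(self):
        table = make_table(n=40, p=5, seed=3)
        res = pca_diagnostic(table, list(table.descriptor_names))
        X = table.values
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        oracle = Z @ Vt[:2].T
        for k in range(2):
            got = res.scores[f"PC{k + 1}"].to_numpy()
            sign = np.sign(got @ oracle[:, k])
            np.testing.assert_allclose(got, sign * oracle[:, k], atol=1e-8)

    def test_constant_descriptor_rejected(self):
        table = make_table(n=20, p=3, seed=4)
        table.values[:, 1] = 1.0
        with pytest.raises(ValidationError, match="d01"):
            pca_diagnostic(table, list(table.descriptor_names))

    def test_split_labels_carried_into_scores(self):
        table = make_table(n=40, p=4, seed=5)
        labelled = split_train_test(table, test_fraction=0.25, seed=0)
        res = pca_diagnostic(labelled, list(table.descriptor_names))
        assert set(res.scores["split"]) == {"train", "test"}
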