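"""WMW screening, the LASSO-logistic coordinate descent, and lambda tuning."""

import numpy as np
import pytest

from gliorad.exceptions import SelectionEmpty
from gliorad.selection import (
    Standardizer,
    default_lambda_grid,
    lambda_max,
    lasso_fit,
    lasso_objective,
    select_features,
    tune_lambda,
    wmw_screen,
)

import oracles
from conftest import make_table


def _toy(seed=0, n=40, p=2, signal=(2.0, -1.5)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[: len(signal)] = signal
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(np.int64)
    if y.min() == y.max():  # force both classes
        y[0] = 1 - y[0]
    return X, y


class TestWmw:
    def test_exact_small_case_matches_enumeration(self):
        keep, p = wmw_screen(
            np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
            np.array([0, 0, 0, 1, 1, 1]),
        )
        assert abs(p[0] - 0.1) < 1e-12
        assert abs(p[0] - oracles.wmw_exact_p([1, 2, 3], [4, 5, 6])) < 1e-12
        assert not keep[0]

    def test_all_tied_gives_p_one(self):
        keep, p = wmw_screen(np.ones((10, 1)), np.array([0] * 5 + [1] * 5))
        assert p[0] == 1.0 and not keep[0]

    def test_perfect_separation_passes_screen(self):
        x = np.r_[np.arange(10.0), np.arange(100.0, 110.0)].reshape(-1, 1)
        y = np.array([0] * 10 + [1] * 10)
        keep, p = wmw_screen(x, y)
        assert p[0] < 1e-3 and keep[0]

    def test_exact_path_matches_enumeration_at_n8(self):
        """For min(n) <= 8 tie-free data the screen uses the exact p-value,
        which must equal full enumeration."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            vals = rng.permutation(np.arange(16.0) + rng.random(16) * 0.01)
            g0, g1 = vals[:8], vals[8:]
            exact = oracles.wmw_exact_p(list(g0), list(g1))
            X = np.r_[g0, g1].reshape(-1, 1)
            y = np.array([0] * 8 + [1] * 8)
            _, p = wmw_screen(X, y)
            assert abs(p[0] - exact) < 1e-12


class TestLasso:
    def test_all_zero_at_lambda_max(self):
        X, y = _toy()
        lm = lambda_max(X, y)
        beta, b0 = lasso_fit(X, y, lm * 1.000001)
        assert np.all(beta == 0.0)
        ybar = y.mean()
        assert abs(b0 - np.log(ybar / (1 - ybar))) < 1e-6

    def test_nonzero_just_below_lambda_max(self):
        X, y = _toy()
        lm = lambda_max(X, y)
        beta, _ = lasso_fit(X, y, lm * 0.9)
        assert np.any(beta != 0.0)

    def test_matches_unpenalized_oracle_at_tiny_lambda(self):
        from sklearn.linear_model import LogisticRegression

        X, y = _toy()
        beta, b0 = lasso_fit(X, y, 1e-6)
        sk = LogisticRegression(C=np.inf, max_iter=100000, tol=1e-10).fit(X, y)
        assert np.abs(beta - sk.coef_[0]).max() < 1e-3
        assert abs(b0 - sk.intercept_[0]) < 1e-3

    def test_objective_non_increasing_over_sweeps(self):
        X, y = _toy(seed=2)
        lam = 3.0
        objs = []
        for k in range(1, 12):
            beta, b0 = lasso_fit(X, y, lam, max_iter=k)
            objs.append(lasso_objective(X, y, beta, b0, lam))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_beats_brute_force_grid(self):
        """The CD solution's objective is at least as good as the best point
        of a dense brute-force grid over (beta1, beta2, intercept)."""
        X, y = _toy(seed=5)
        lam = 5.0
        beta, b0 = lasso_fit(X, y, lam)
        mine = lasso_objective(X, y, beta, b0, lam)
        grid = np.linspace(-2, 2, 41)
        best = np.inf
        for b1 in grid:
            for b2 in grid:
                for c in np.linspace(-1, 1, 21):
                    best = min(
                        best, lasso_objective(X, y, np.array([b1, b2]), c, lam)
                    )
        assert mine <= best + 1e-6

    def test_endpoint_sparsity_monotonicity(self):
        X, y = _toy(seed=7)
        lm = lambda_max(X, y)
        dense, _ = lasso_fit(X, y, lm / 1e6)
        sparse, _ = lasso_fit(X, y, lm)
        assert (dense != 0).sum() >= (sparse != 0).sum()


class TestTuneLambda:
    def test_degenerate_singleton_grid(self):
        X, y = _toy()
        lam, (grid, curve) = tune_lambda(X, y, grid=np.array([0.5]), repeats=1)
        assert lam == 0.5 and len(curve) == 1

    def test_informative_feature_retained(self):
        rng = np.random.default_rng(11)
        n = 60
        X = rng.standard_normal((n, 5))
        y = np.array([0] * 30 + [1] * 30)
        X[y == 1, 0] += 3.0  # one strongly informative feature
        lam, (grid, curve) = tune_lambda(X, y, repeats=2, seed=4)
        assert curve.max() > 0.95
        sc = Standardizer.fit(X)
        beta, _ = lasso_fit(sc.transform(X), y, lam)
        assert beta[0] != 0.0

    def test_pure_noise_curve_near_chance(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 5))
            y = np.array([0] * 30 + [1] * 30)
            _, (_, curve) = tune_lambda(
                X, y, grid=default_lambda_grid(9), repeats=1, seed=seed
            )
            vals.append(curve)
        mean_curve = np.mean(vals, axis=0)
        assert np.all(mean_curve > 0.35) and np.all(mean_curve < 0.65)


class TestSelectFeatures:
    def test_selected_subset_of_screened_and_recovery(self):
        table = make_table(30, 30, 50, seed=8, informative=3, shift=2.0)
        res = select_features(table, seed=1, repeats=2)
        assert set(map(str, res.selected)) <= set(map(str, res.screened))
        recovered = sum(1 for d in res.selected if d.name in ("f0", "f1", "f2"))
        assert recovered >= 2

    def test_screening_empty_raises(self):
        table = make_table(5, 5, 10, seed=0)  # n too small for p < 0.001
        with pytest.raises(SelectionEmpty):
            select_features(table, seed=0)

    def test_no_leakage_from_held_out_row(self):
        """Flipping an excluded subject's label never changes the training
        fold's selection."""
        table = make_table(20, 20, 40, seed=9, informative=2, shift=2.0)
        train = table.subset_rows(np.arange(39))  # exclude the last subject
        res1 = select_features(train, seed=3, repeats=1)
        flipped = make_table(20, 20, 40, seed=9, informative=2, shift=2.0)
        flipped.grades[39] = "III"  # flip the held-out label
        train2 = flipped.subset_rows(np.arange(39))
        res2 = select_features(train2, seed=3, repeats=1)
        assert [str(d) for d in res1.selected] == [str(d) for d in res2.selected]
        np.testing.assert_array_equal(res1.beta, res2.beta)
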