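import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resourcescape.spatial_models import (
    backward_eliminate,
    build_weights,
    fit_sar_error,
    lr_test,
    morans_i,
    select_neighborhood,
)
from resourcescape.synthetic_data import gen_sar_response


def grid_coords(nx, ny, spacing=10.0):
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return np.column_stack([(xs.ravel() + 0.5) * spacing, (ys.ravel() + 0.5) * spacing])


def brute_neighbor_count(coords, i, threshold):
    d = np.sqrt(((coords - coords[i]) ** 2).sum(1))
    return int(((d > 0) & (d <= threshold)).sum())


class TestWeights:
    def test_interior_cell_has_36_neighbors_at_35km(self):
        coords = grid_coords(10, 10)
        w = build_weights(coords, 35.0)
        counts = w.neighbor_counts()
        center = 4 * 10 + 4
        assert counts[center] == 36
        assert counts[center] == brute_neighbor_count(coords, center, 35.0)

    def test_corner_cell_matches_offset_enumeration(self):
        # offsets (dx, dy) in [0..3]^2 with 0 < dx^2 + dy^2 <= 3.5^2
        expected = sum(
            1 for dx in range(4) for dy in range(4) if 0 < dx * dx + dy * dy <= 3.5**2
        )
        coords = grid_coords(10, 10)
        w = build_weights(coords, 35.0)
        assert w.neighbor_counts()[0] == expected == 12

    def test_two_distant_points_isolated_with_warning(self):
        coords = np.array([[0.0, 0.0], [36.0, 0.0]])
        with pytest.warns(UserWarning, match="no neighbors"):
            w = build_weights(coords, 35.0)
        assert w.isolated.all()
        assert np.all(w.matrix == 0)

    def test_row_standardized_rows_sum_to_one(self):
        w = build_weights(grid_coords(6, 6), 15.0)
        np.testing.assert_allclose(w.matrix.sum(axis=1), 1.0)

    def test_neighbor_relation_symmetric_before_standardization(self):
        w = build_weights(grid_coords(6, 6), 25.0)
        assert (w.adjacency == w.adjacency.T).all()
        assert not w.adjacency.diagonal().any()

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            build_weights(np.array([[0.0, 0.0], [0.0, 0.0]]), 35.0)


class TestMoran:
    def test_alternating_ring_is_minus_one(self):
        # ring of 4: each unit's neighbors are the two adjacent units
        adj = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=bool
        )
        from resourcescape.spatial_models import SpatialWeights

        w = SpatialWeights(n=4, threshold_km=1.0, style="row_standardized",
                           adjacency=adj, isolated=np.zeros(4, bool))
        res = morans_i([1.0, -1.0, 1.0, -1.0], w)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected_I == pytest.approx(-1 / 3)

    def test_constant_values_rejected(self):
        w = build_weights(grid_coords(3, 3), 15.0)
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(9), w)

    def test_iid_noise_near_null_expectation(self):
        w = build_weights(grid_coords(20, 20), 15.0)
        rng = np.random.default_rng(0)
        res = morans_i(rng.normal(size=400), w)
        assert abs(res.z) < 4

    def test_permutation_p_agrees_with_normal_approx_on_structure(self):
        w = build_weights(grid_coords(8, 8), 15.0)
        rng = np.random.default_rng(1)
        # smooth values: strong positive autocorrelation
        coords = grid_coords(8, 8)
        vals = np.sin(coords[:, 0] / 30) + np.cos(coords[:, 1] / 30)
        a = morans_i(vals, w)
        b = morans_i(vals, w, permutations=999, seed=0)
        assert a.p < 0.01 and b.p < 0.01
        assert a.I == pytest.approx(b.I)


@pytest.fixture(scope="module")
def sar_testbed():
    coords = grid_coords(15, 15)
    w = build_weights(coords, 10.0)  # first-order contiguity
    n = coords.shape[0]
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        {"intercept": 1.0, "x1": rng.normal(size=n), "x2": rng.normal(size=n)}
    )
    return coords, w, X


class TestSARFit:
    def test_lambda_zero_limit_equals_ols(self, sar_testbed):
        coords, w, X = sar_testbed
        n = len(X)
        rng = np.random.default_rng(7)
        y = X.to_numpy() @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_sar_error(y, X, w)
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        assert abs(fit.lam) < 0.12
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=2e-2)

    def test_profile_optimum_matches_slogdet_grid_oracle(self, sar_testbed):
        """Independent check of the concentrated likelihood: evaluate the
        full log-likelihood on a dense lambda grid using np.linalg.slogdet
        and confirm our profiled optimum dominates the grid."""
        coords, w, X = sar_testbed
        n = len(X)
        y = gen_sar_response(X.to_numpy(), w, np.array([1.0, 2.0, -1.0]), 0.5, 1.0, seed=3)
        fit = fit_sar_error(y, X, w)
        Xm = X.to_numpy()
        W = w.matrix
        best = -np.inf
        for lam in np.linspace(-0.9, 0.99, 120):
            A = np.eye(n) - lam * W
            Ay, AX = A @ y, A @ Xm
            beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
            r = Ay - AX @ beta
            s2 = r @ r / n
            ll = -n / 2 * (np.log(2 * np.pi * s2) + 1) + np.linalg.slogdet(A)[1]
            best = max(best, ll)
        assert fit.log_lik >= best - 1e-6
        assert fit.aic == pytest.approx(-2 * fit.log_lik + 2 * (3 + 2))

    def test_parameter_recovery_over_seeds(self):
        coords = grid_coords(20, 20)
        w = build_weights(coords, 10.0)
        n = coords.shape[0]
        beta = np.array([1.0, 2.0, -1.0])
        ok_lam = ok_beta = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            Xs = pd.DataFrame(
                {"intercept": 1.0, "x1": rng.normal(size=n), "x2": rng.normal(size=n)}
            )
            y = gen_sar_response(Xs.to_numpy(), w, beta, 0.6, 1.0, seed=200 + seed)
            fit = fit_sar_error(y, Xs, w)
            ok_lam += abs(fit.lam - 0.6) <= 0.1
            ok_beta += all(
                abs(fit.beta[i] - beta[i]) <= 2 * fit.se_beta[i] for i in range(3)
            )
        assert ok_lam >= 0.8 * n_seeds
        assert ok_beta >= 0.8 * n_seeds

    def test_whitened_residuals_lose_autocorrelation(self, sar_testbed):
        coords, w, X = sar_testbed
        y = gen_sar_response(X.to_numpy(), w, np.array([1.0, 2.0, -1.0]), 0.6, 1.0, seed=9)
        fit = fit_sar_error(y, X, w)
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        raw = y - X.to_numpy() @ beta_ols
        assert abs(morans_i(raw, w).z) > 2
        assert abs(morans_i(fit.whitened_residuals, w).z) < 2

    def test_loglik_dominates_nested_ols_point(self, sar_testbed):
        coords, w, X = sar_testbed
        n = len(X)
        for seed in range(5):
            y = gen_sar_response(
                X.to_numpy(), w, np.array([1.0, 2.0, -1.0]), 0.4, 1.0, seed=seed
            )
            fit = fit_sar_error(y, X, w)
            beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
            r = y - X.to_numpy() @ beta_ols
            s2 = r @ r / n
            ll_ols = -n / 2 * (np.log(2 * np.pi * s2) + 1)
            assert fit.log_lik >= ll_ols - 1e-9

    def test_square_transform_recorded_and_applied(self, sar_testbed):
        coords, w, X = sar_testbed
        rng = np.random.default_rng(4)
        y = np.sqrt(np.abs(X["x1"] * 2 + rng.normal(size=len(X)) + 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_sq = fit_sar_error(y, X, w, transform="square")
            fit_manual = fit_sar_error(y**2, X, w, transform="identity")
        assert fit_sq.dependent_transform == "square"
        assert fit_sq.log_lik == pytest.approx(fit_manual.log_lik)

    def test_singular_design_rejected(self, sar_testbed):
        coords, w, X = sar_testbed
        X2 = X.copy()
        X2["x3"] = X2["x1"]
        with pytest.raises(ValueError, match="singular"):
            fit_sar_error(np.arange(len(X2), dtype=float), X2, w)


class TestLRAndElimination:
    def test_identical_models_lr_zero(self, sar_testbed):
        coords, w, X = sar_testbed
        y = gen_sar_response(X.to_numpy(), w, np.array([1.0, 2.0, -1.0]), 0.5, 1.0, seed=1)
        fit = fit_sar_error(y, X, w)
        lr, df, p = lr_test(fit, fit)
        assert lr == 0 and df == 0 and p == 1.0

    def test_chi_square_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.0500, abs=5e-4)

    def test_lr_equals_aic_difference_identity(self, sar_testbed):
        coords, w, X = sar_testbed
        y = gen_sar_response(X.to_numpy(), w, np.array([1.0, 2.0, 0.0]), 0.5, 1.0, seed=2)
        full = fit_sar_error(y, X, w)
        reduced = fit_sar_error(y, X[["intercept", "x1"]], w)
        lr, df, _ = lr_test(full, reduced)
        assert lr == pytest.approx(-(full.aic - reduced.aic) + 2 * df)

    def test_non_nested_rejected(self, sar_testbed):
        coords, w, X = sar_testbed
        y = gen_sar_response(X.to_numpy(), w, np.array([1.0, 2.0, -1.0]), 0.5, 1.0, seed=3)
        a = fit_sar_error(y, X[["intercept", "x1"]], w)
        b = fit_sar_error(y, X[["intercept", "x2"]], w)
        with pytest.raises(ValueError, match="not nested"):
            lr_test(a, b)

    def test_noise_column_dropped(self, sar_testbed):
        coords, w, X = sar_testbed
        n = len(X)
        dropped = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            Xs = pd.DataFrame(
                {
                    "intercept": 1.0,
                    "x1": rng.normal(size=n),
                    "x2": rng.normal(size=n),
                    "noise": rng.normal(size=n),
                }
            )
            y = gen_sar_response(
                Xs[["intercept", "x1", "x2"]].to_numpy(), w,
                np.array([1.0, 2.0, -1.0]), 0.6, 1.0, seed=400 + seed,
            )
            trace = backward_eliminate(y, Xs, w)
            if "noise" in [s[0] for s in trace.steps]:
                dropped += 1
            assert "x1" in trace.final.terms and "x2" in trace.final.terms
        assert dropped >= 0.9 * n_seeds

    def test_all_protected_terms_kept(self, sar_testbed):
        coords, w, X = sar_testbed
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(X))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = backward_eliminate(y, X, w, protected=["x1", "x2"])
        assert trace.steps == []
        assert set(trace.final.terms) == {"intercept", "x1", "x2"}


class TestNeighborhoodSelection:
    def test_single_candidate_single_row(self, sar_testbed):
        coords, w, X = sar_testbed
        y = gen_sar_response(X.to_numpy(), w, np.array([1.0, 2.0, -1.0]), 0.5, 1.0, seed=6)
        tab = select_neighborhood(y, X, coords, [35.0])
        assert len(tab) == 1 and tab["best_aic"].all()

    def test_generating_threshold_among_best(self, sar_testbed):
        coords, _, X = sar_testbed
        w35 = build_weights(coords, 35.0)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            y = gen_sar_response(
                X.to_numpy(), w35, np.array([1.0, 2.0, -1.0]), 0.6, 1.0, seed=500 + seed
            )
            tab = select_neighborhood(y, X, coords, [15.0, 25.0, 35.0, 45.0])
            best = tab.loc[tab["best_aic"], "threshold_km"].iloc[0]
            hits += best in (25.0, 35.0, 45.0)
        assert hits >= 0.8 * n_seeds
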