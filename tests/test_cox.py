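import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import fedsurv as fs
from fedsurv import cox
from fedsurv.exceptions import (
    DegenerateNodeError,
    MonotoneLikelihoodError,
    ParameterError,
)
from fedsurv.fedstats import StandardizationParams
from oracles import ista_lasso_cox, stratified_nll_grad
from conftest import make_network


def _identity_std(names):
    p = len(names)
    return StandardizationParams(np.zeros(p), np.ones(p), list(names))


def _std_groups(fed, std, features=None):
    """Pooled, standardized (X, t, e) per node for the centralized oracles."""
    groups = []
    for h in fed.nodes:
        d = h._train_data()
        idx = [d.feature_names.index(f) for f in (features or d.feature_names)]
        groups.append((std.apply(d.features[:, idx]), d.times, d.events))
    return groups


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,gamma,expected",
        [(3, 1, 2), (-0.5, 1, 0), (-3, 1, -2), (0, 0, 0), (2.5, 0, 2.5)],
    )
    def test_operator(self, z, gamma, expected):
        assert cox.soft_threshold(z, gamma) == expected

    def test_negative_gamma_rejected(self):
        with pytest.raises(ParameterError):
            cox.soft_threshold(1.0, -0.1)


class TestLocalDerivatives:
    def test_score_at_zero_closed_form(self):
        """At beta=0 the score is sum over events of (x_i - risk-set mean)."""
        x = np.array([0.3, -1.2, 2.0])
        data = fs.NodeDataset(
            "n", np.array(list("abc"), object),
            times=np.array([1.0, 2.0, 3.0]), events=np.ones(3, int),
            features=x[:, None], feature_names=["x"],
        )
        agg = cox.local_cox_derivatives(
            data, np.zeros(1), ["x"], _identity_std(["x"]), mode="newton"
        )
        expected = (x[0] - x.mean()) + (x[1] - x[1:].mean()) + 0.0
        assert agg.gradient[0] == pytest.approx(expected, abs=1e-12)

    def test_all_censored_raises(self):
        data = fs.NodeDataset(
            "n", np.array(list("ab"), object),
            times=np.array([1.0, 2.0]), events=np.zeros(2, int),
            features=np.zeros((2, 1)), feature_names=["x"],
        )
        with pytest.raises(DegenerateNodeError):
            cox.local_cox_derivatives(data, np.zeros(1), ["x"], _identity_std(["x"]))

    def test_two_nodes_sum_to_pooled_stratified_derivatives(self, toy_fed, toy_std):
        """Summed node aggregates equal the centralized stratified gradient."""
        feats = toy_std.feature_names
        rng = np.random.default_rng(5)
        beta = rng.normal(scale=0.3, size=len(feats))
        parts = [
            cox.local_cox_derivatives(
                h._train_data(), beta, feats, toy_std, mode="newton"
            )
            for h in toy_fed.nodes
        ]
        U = sum(p.gradient for p in parts)
        groups = _std_groups(toy_fed, toy_std)
        N = sum(len(t) for _x, t, _e in groups)
        _nll, g_oracle = stratified_nll_grad(groups, beta)
        np.testing.assert_allclose(U, -g_oracle * N, atol=1e-12 * N)

    def test_coordinate_aggregate_reduces_to_score_at_zero(self, toy_fed, toy_std):
        feats = toy_std.feature_names
        newton = [
            cox.local_cox_derivatives(
                h._train_data(), np.zeros(len(feats)), feats, toy_std, "newton"
            )
            for h in toy_fed.nodes
        ]
        coord = [
            cox.local_cox_derivatives(
                h._train_data(), np.zeros(len(feats)), feats, toy_std, "coordinate"
            )
            for h in toy_fed.nodes
        ]
        np.testing.assert_allclose(
            sum(c.xz for c in coord), sum(n.gradient for n in newton), atol=1e-10
        )


class TestLambdaGrid:
    def test_log_spacing(self, toy_fed, toy_std):
        grid = cox.lambda_grid(toy_fed, toy_std.feature_names, toy_std, K=3, eps=0.01)
        assert grid[0] / grid[1] == pytest.approx(grid[1] / grid[2])
        assert grid[2] == pytest.approx(0.01 * grid[0])

    def test_lambda_max_is_max_score_over_n(self, toy_fed, toy_std):
        feats = toy_std.feature_names
        grid = cox.lambda_grid(toy_fed, feats, toy_std, K=2, eps=0.5)
        groups = _std_groups(toy_fed, toy_std)
        _nll, g = stratified_nll_grad(groups, np.zeros(len(feats)))
        assert grid[0] == pytest.approx(np.max(np.abs(g)), rel=1e-12)

    def test_fit_at_lambda_max_is_zero(self, toy_fed, toy_std):
        feats = toy_std.feature_names
        grid = cox.lambda_grid(toy_fed, feats, toy_std, K=5, eps=0.01)
        fit = cox.fit_penalized(toy_fed, feats, grid[0], toy_std)
        assert np.all(fit.beta == 0.0)


class TestFitPenalized:
    def test_lambda_zero_matches_centralized_stratified_cox(self, toy_fed, toy_std):
        feats = toy_std.feature_names
        fit = cox.fit_penalized(toy_fed, feats, 0.0, toy_std,
                                tol_inner=1e-9, tol_outer=1e-9)
        ref = _lifelines_stratified(toy_fed, toy_std)
        np.testing.assert_allclose(fit.beta, ref.params_.values, atol=1e-5)

    @pytest.mark.parametrize("frac", [0.5, 0.15, 0.03])
    def test_midpath_matches_ista_oracle(self, toy_fed, toy_std, frac):
        feats = toy_std.feature_names
        grid = cox.lambda_grid(toy_fed, feats, toy_std, K=2, eps=0.5)
        lam = frac * grid[0]
        fit = cox.fit_penalized(toy_fed, feats, lam, toy_std,
                                tol_inner=1e-9, tol_outer=1e-9)
        oracle = ista_lasso_cox(_std_groups(toy_fed, toy_std), lam, len(feats))
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-5)

    def test_kkt_conditions_hold(self, toy_fed, toy_std):
        """Active coordinates: score = lambda*sign(beta); inactive: |score| <= lambda
        — checked against the centralized pooled likelihood."""
        feats = toy_std.feature_names
        grid = cox.lambda_grid(toy_fed, feats, toy_std, K=3, eps=0.05)
        lam = grid[1]
        fit = cox.fit_penalized(toy_fed, feats, lam, toy_std,
                                tol_inner=1e-9, tol_outer=1e-9)
        _nll, g = stratified_nll_grad(_std_groups(toy_fed, toy_std), fit.beta)
        for k, b in enumerate(fit.beta):
            if abs(b) > 1e-8:
                assert -g[k] == pytest.approx(lam * np.sign(b), abs=1e-6)
            else:
                assert abs(g[k]) <= lam + 1e-6


@pytest.fixture(scope="module")
def fitted_path():
    datasets, _ = make_network(seed=9, nodes=(("a", 100), ("b", 120), ("c", 90)),
                               p=5, blocks=((5, 0.2),),
                               true_beta={"radiomic_1": 0.8, "radiomic_4": -0.6})
    fed = fs.build_federation(datasets, fs.PipelineConfig(seed=2))
    agg = fs.federated_moments(fed)
    std = fs.standardization_params(agg, datasets[0].feature_names)
    feats = datasets[0].feature_names
    grid = cox.lambda_grid(fed, feats, std, K=25, eps=0.01)
    path = cox.regularization_path(fed, feats, std, grid)
    return fed, std, path


class TestRegularizationPath:
    def test_first_column_all_zero(self, fitted_path):
        _fed, _std, path = fitted_path
        assert np.all(path.coef_matrix[:, 0] == 0.0)

    def test_matches_centralized_path(self, fitted_path):
        fed, std, path = fitted_path
        groups = _std_groups(fed, std)
        beta = np.zeros(len(path.feature_names))
        for j, lam in enumerate(path.lambda_grid):
            beta = ista_lasso_cox(groups, lam, beta.size, beta0=beta)
            np.testing.assert_allclose(path.coef_matrix[:, j], beta, atol=1e-4)

    def test_entry_lambda_consistent_with_matrix(self, fitted_path):
        _fed, _std, path = fitted_path
        for k, lam in enumerate(path.entry_lambda):
            nz = np.abs(path.coef_matrix[k]) > 1e-8
            if np.isnan(lam):
                assert not nz.any()
            else:
                assert lam == path.lambda_grid[np.flatnonzero(nz)[0]]

    def test_deviance_non_increasing_along_path(self, fitted_path):
        fed, std, path = fitted_path
        groups = _std_groups(fed, std)
        devs = [
            stratified_nll_grad(groups, path.coef_matrix[:, j])[0]
            for j in range(path.lambda_grid.size)
        ]
        assert all(d2 <= d1 + 1e-10 for d1, d2 in zip(devs, devs[1:]))

    def test_entry_order_ranks_signal_first(self, fitted_path):
        _fed, _std, path = fitted_path
        order = cox.entry_order(path)
        assert set(order[:2]) == {"radiomic_1", "radiomic_4"}

    def test_entry_order_tie_and_flag_rules(self):
        path = cox.RegularizationPath(
            lambda_grid=np.array([1.0, 0.5, 0.25]),
            coef_matrix=np.array([
                [0.0, 0.2, 0.3],   # enters at 0.5
                [0.1, 0.2, 0.25],  # enters at 1.0
                [0.0, 0.0, 0.0],   # never enters
            ]),
            entry_lambda=np.array([0.5, 1.0, np.nan]),
            feature_names=["f1", "f2", "f3"],
        )
        assert cox.entry_order(path) == ["f2", "f1", "f3"]
        assert path.never_entered() == ["f3"]


class TestFitUnpenalized:
    def test_matches_centralized_stratified_cox(self, toy_fed, toy_std):
        model = cox.fit_unpenalized(toy_fed, toy_std.feature_names, toy_std)
        ref = _lifelines_stratified(toy_fed, toy_std)
        np.testing.assert_allclose(model.beta, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(model.se, ref.standard_errors_.values, atol=1e-5)

    def test_gradient_vanishes_at_optimum(self, toy_fed, toy_std):
        feats = toy_std.feature_names
        model = cox.fit_unpenalized(toy_fed, feats, toy_std)
        groups = _std_groups(toy_fed, toy_std)
        N = sum(len(t) for _x, t, _e in groups)
        _nll, g = stratified_nll_grad(groups, model.beta)
        assert np.max(np.abs(g)) * N < 1e-7

    def test_ci_definitionally_correct(self, toy_fed, toy_std):
        m = cox.fit_unpenalized(toy_fed, toy_std.feature_names, toy_std)
        np.testing.assert_allclose(m.hr_ci_low, np.exp(m.beta - 1.96 * m.se))
        np.testing.assert_allclose(m.hr_ci_high, np.exp(m.beta + 1.96 * m.se))
        assert np.all((m.wald_p >= 0) & (m.wald_p <= 1))
        assert np.all((m.hr_ci_low < m.hr) & (m.hr < m.hr_ci_high))

    def test_perfectly_separating_feature_flagged_as_monotone(self):
        """A feature that orders survival perfectly drives beta to infinity."""
        n = 30
        t = np.arange(1.0, n + 1)
        data = fs.NodeDataset(
            "n", np.array([f"p{i}" for i in range(n)], object),
            times=t, events=np.ones(n, int),
            features=(-t)[:, None], feature_names=["x"],
        )
        fed = fs.Federation(
            [fs.NodeHandle(data)], fs.PrivacyPolicy(n_features=1)
        )
        std = StandardizationParams(
            np.array([(-t).mean()]), np.array([(-t).std()]), ["x"]
        )
        with pytest.raises((MonotoneLikelihoodError, fs.exceptions.ConvergenceError)):
            cox.fit_unpenalized(fed, ["x"], std)


def _lifelines_stratified(fed, std):
    feats = std.feature_names
    rows = []
    for h in fed.nodes:
        d = h._train_data()
        idx = [d.feature_names.index(f) for f in feats]
        df = pd.DataFrame(std.apply(d.features[:, idx]), columns=feats)
        df["T"], df["E"], df["node"] = d.times, d.events, h.node_id
        rows.append(df)
    cph = CoxPHFitter()
    return cph.fit(pd.concat(rows, ignore_index=True), "T", "E", strata=["node"])
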