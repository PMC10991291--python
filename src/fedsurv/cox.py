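"""Node-stratified Cox partial likelihood with LASSO, fitted federatedly.

Model
-----
Each institution (node) is a stratum with its own baseline hazard; the
coefficient vector beta is shared. The local Breslow partial log-likelihood
of node s is

    ll_s(beta) = sum_j [ sum_{i in D_js} eta_i - d_js * log sum_{l in R_js} exp(eta_l) ]

with eta = X_std beta, D_js the deaths at the j-th distinct event time of the
node, R_js its local risk set and d_js the tie count. Risk sets never cross
institution boundaries, so each node can evaluate its own derivatives and
ship only p-sized aggregates.

Penalized fitting follows the cyclical-coordinate-descent scheme for the Cox
LASSO: an outer IRLS loop builds a weighted least-squares approximation at
the current linear predictors (diagonal-Hessian weights w_i and working
responses z_i), and an inner cyclic soft-thresholding loop minimises

    (1/2N) sum_i w_i (z_i - x_i' beta)^2 + lambda ||beta||_1 .

Each IRLS round exchanges the weighted cross-product vector sum_i w_i z_i x_i
and the p x p weighted Gram matrix sum_i w_i x_i x_i'; the aggregator-side
coordinate loop then performs exact residual bookkeeping (identical numerics
to re-contacting the nodes after every coordinate update, because residual
corrections are linear in the Gram rows). At any IRLS fixed point the exact
L1 KKT conditions of the true partial likelihood hold, because
sum_i w_i (z_i - eta_i) x_ik telescopes to the true score U_k(beta).

Features are standardized with *federated* (pooled) means and population SDs
before fitting, so penalties treat features symmetrically and hazard ratios
are per 1 SD.

The unpenalized final fit is Newton-Raphson on the pooled gradient and full
p x p Hessian, with Wald standard errors from the inverse observed
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import NodeDataset
from .exceptions import (
    CollinearityError,
    ConvergenceError,
    DegenerateNodeError,
    MonotoneLikelihoodError,
    ParameterError,
)
from .federation import AggregatePayload, Federation, NodeHandle, register_task
from .fedstats import StandardizationParams

logger = logging.getLogger(__name__)

#: |beta| beyond this (standardized scale) is treated as monotone likelihood.
DIVERGENCE_BOUND = 50.0
ENTRY_TOL = 1e-8


# -- local (node-side) derivatives ---------------------------------------


@dataclass
class CoxRoundAggregate:
    """Per-node aggregate for one Cox iteration; every array is p-sized."""

    node_id: str
    n: int
    n_events: int
    loglik: float
    # coordinate mode: weighted working-response cross-products and Gram matrix
    xz: np.ndarray | None = None  # (p,)   sum_i w_i z_i x_ik
    gram: np.ndarray | None = None  # (p, p) sum_i w_i x_ik x_il
    # newton mode: exact derivatives of the local log partial likelihood
    gradient: np.ndarray | None = None  # (p,)
    hessian: np.ndarray | None = None  # (p, p)

    @property
    def weighted_squares(self) -> np.ndarray:
        """A_k = sum_i w_i x_ik^2 (diagonal of the weighted Gram matrix)."""
        return np.diag(self.gram)


def _design(data: NodeDataset, features, standardization: StandardizationParams):
    try:
        idx = [data.feature_names.index(f) for f in features]
    except ValueError as e:
        raise KeyError(f"feature missing from node '{data.node_id}': {e}") from None
    return standardization.apply(data.features[:, idx])


def local_cox_derivatives(
    data: NodeDataset,
    beta: np.ndarray,
    features,
    standardization: StandardizationParams,
    mode: str = "coordinate",
) -> CoxRoundAggregate:
    """Breslow partial-likelihood quantities over one node's rows.

    ``coordinate`` mode returns the IRLS weighted cross-products and Gram
    matrix; ``newton`` mode returns the exact local gradient and full Hessian.
    Risk sets are formed over this node's rows only (stratified likelihood).
    """
    if mode not in ("coordinate", "newton"):
        raise ParameterError(f"unknown mode '{mode}'")
    beta = np.asarray(beta, dtype=float)
    X = _design(data, features, standardization)
    n, p = X.shape
    if beta.shape != (p,):
        raise ParameterError("beta length does not match feature list")
    if data.events.sum() == 0:
        raise DegenerateNodeError(
            f"node '{data.node_id}' has no observed events"
        )

    eta = X @ beta
    order = np.argsort(data.times, kind="stable")
    ts, ev = data.times[order], data.events[order]
    Xs, eta_s = X[order], eta[order]
    # centring eta leaves the partial likelihood and all derivatives unchanged
    etac = eta_s - eta_s.max()
    th = np.exp(etac)

    rs0 = np.cumsum(th[::-1])[::-1]  # sum of th over the risk set {l: T_l >= T_i}
    event_times = ts[ev == 1]
    ue, first_idx = np.unique(event_times, return_index=True)
    # index of the first subject entering each risk set
    risk_start = np.searchsorted(ts, ue, side="left")
    d = np.diff(np.append(first_idx, event_times.size)).astype(float)  # tie counts
    S0 = rs0[risk_start]

    ev_mask = ev == 1
    loglik = float(etac[ev_mask].sum() - (d * np.log(S0)).sum())

    if mode == "newton":
        rs1 = np.cumsum((th[:, None] * Xs)[::-1], axis=0)[::-1]
        xo = th[:, None, None] * Xs[:, :, None] * Xs[:, None, :]
        rs2 = np.cumsum(xo[::-1], axis=0)[::-1]
        S1 = rs1[risk_start]  # (m, p)
        S2 = rs2[risk_start]  # (m, p, p)
        sum_dx = Xs[ev_mask].sum(axis=0)
        U = sum_dx - (d[:, None] * S1 / S0[:, None]).sum(axis=0)
        mean1 = S1 / S0[:, None]
        H = -(
            np.einsum("m,mkl->kl", d / S0, S2)
            - np.einsum("m,mk,ml->kl", d, mean1, mean1)
        )
        return CoxRoundAggregate(
            node_id=data.node_id,
            n=n,
            n_events=int(ev.sum()),
            loglik=loglik,
            gradient=U,
            hessian=0.5 * (H + H.T),
        )

    # coordinate mode: per-subject score g_i and diagonal-Hessian weight w_i
    cum1 = np.cumsum(d / S0)
    cum2 = np.cumsum(d / S0**2)
    pos = np.searchsorted(ue, ts, side="right")
    C1 = np.where(pos > 0, cum1[np.maximum(pos - 1, 0)], 0.0)
    C2 = np.where(pos > 0, cum2[np.maximum(pos - 1, 0)], 0.0)
    g = ev - th * C1
    w = th * C1 - th**2 * C2
    # w_i z_i = w_i eta_i + g_i, formed directly so w_i ~ 0 needs no division
    wz = w * eta_s + g
    xz = Xs.T @ wz
    gram = Xs.T @ (w[:, None] * Xs)
    return CoxRoundAggregate(
        node_id=data.node_id,
        n=n,
        n_events=int(ev.sum()),
        loglik=loglik,
        xz=xz,
        gram=gram,
    )


def soft_threshold(z: float, gamma: float) -> float:
    """S(z, gamma) = sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise ParameterError("soft-threshold parameter must be >= 0")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


# -- federated round plumbing --------------------------------------------


@register_task("cox_round")
def _cox_round_task(
    handle: NodeHandle,
    beta,
    features,
    std_means,
    std_sds,
    mode: str = "coordinate",
):
    std = StandardizationParams(
        means=np.asarray(std_means, float),
        sds=np.asarray(std_sds, float),
        feature_names=list(features),
    )
    data = handle._train_data()
    p = len(features)
    try:
        agg = local_cox_derivatives(data, np.asarray(beta, float), features, std, mode)
    except DegenerateNodeError:
        # an event-free node contributes zero likelihood and zero sums
        agg = CoxRoundAggregate(
            node_id=handle.node_id,
            n=data.n_patients,
            n_events=0,
            loglik=0.0,
            xz=np.zeros(p),
            gram=np.zeros((p, p)),
            gradient=np.zeros(p),
            hessian=np.zeros((p, p)),
        )
    content = {"n": agg.n, "n_events": agg.n_events, "loglik": agg.loglik}
    if mode == "newton":
        content["gradient"] = agg.gradient
        content["hessian"] = agg.hessian
    else:
        content["xz"] = agg.xz
        content["gram"] = agg.gram
    return AggregatePayload.build("cox_round", handle.node_id, content)


def _cox_round(fed: Federation, beta, features, std, mode, node_ids):
    payloads = fed.execute_round(
        "cox_round",
        node_ids=node_ids,
        beta=np.asarray(beta, float),
        features=list(features),
        std_means=std.means,
        std_sds=std.sds,
        mode=mode,
    )
    N = sum(int(p.content["n"]) for p in payloads)
    n_events = sum(int(p.content["n_events"]) for p in payloads)
    ll = float(sum(p.content["loglik"] for p in payloads))
    if mode == "newton":
        U = np.sum([np.asarray(p.content["gradient"], float) for p in payloads], axis=0)
        H = np.sum([np.asarray(p.content["hessian"], float) for p in payloads], axis=0)
        return N, n_events, ll, U, H
    xz = np.sum([np.asarray(p.content["xz"], float) for p in payloads], axis=0)
    gram = np.sum([np.asarray(p.content["gram"], float) for p in payloads], axis=0)
    return N, n_events, ll, xz, gram


# -- penalized path ------------------------------------------------------


@dataclass
class CoxCoefficients:
    """Solution of one penalized fit, on the standardized scale."""

    beta: np.ndarray
    features: list[str]
    lam: float
    converged: bool
    n_iterations: int
    final_deviance: float


@dataclass
class RegularizationPath:
    """Coefficients over a decreasing lambda grid."""

    lambda_grid: np.ndarray  # (K,) strictly decreasing
    coef_matrix: np.ndarray  # (p, K)
    entry_lambda: np.ndarray  # (p,) first lambda with nonzero coef; nan = never
    feature_names: list[str]

    def never_entered(self) -> list[str]:
        return [
            f for f, lam in zip(self.feature_names, self.entry_lambda) if np.isnan(lam)
        ]


def _cd_inner(
    xz: np.ndarray,
    gram: np.ndarray,
    beta0: np.ndarray,
    N: int,
    lam: float,
    tol_inner: float,
    max_inner: int,
) -> np.ndarray:
    """Cyclic coordinate descent on the weighted LS approximation.

    Exact residual bookkeeping: the partial residual cross-product for
    coordinate k is xz_k - sum_{l != k} gram_kl beta_l, refreshed after every
    single-coordinate update.
    """
    beta = beta0.copy()
    p = beta.size
    for _ in range(max_inner):
        delta = 0.0
        for k in range(p):
            akk = gram[k, k]
            if akk <= 1e-300:
                new = 0.0
            else:
                partial = xz[k] - gram[k] @ beta + akk * beta[k]
                new = soft_threshold(partial / N, lam) / (akk / N)
            delta = max(delta, abs(new - beta[k]))
            beta[k] = new
        if delta < tol_inner:
            break
    return beta


def fit_penalized(
    fed: Federation,
    features,
    lam: float,
    standardization: StandardizationParams,
    init: np.ndarray | None = None,
    node_ids=None,
    tol_inner: float = 1e-7,
    tol_outer: float = 1e-6,
    max_outer: int = 100,
    max_inner: int = 1000,
) -> CoxCoefficients:
    """LASSO-penalized node-stratified Cox fit at one penalty value.

    Outer IRLS rounds recompute weights and working responses from the
    current linear predictors; the inner cyclic soft-thresholding loop solves
    the resulting weighted LASSO. Converged when the largest coefficient
    change of an outer round falls below ``tol_inner`` and the relative
    deviance change below ``tol_outer``.
    """
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    p = len(features)
    beta = np.zeros(p) if init is None else np.asarray(init, float).copy()
    std = standardization.restrict(features)
    dev_prev = None
    trace = []
    for outer in range(max_outer):
        N, n_events, ll, xz, gram = _cox_round(
            fed, beta, features, std, "coordinate", node_ids
        )
        if n_events == 0:
            raise DegenerateNodeError("no events in any participating node")
        dev = -2.0 * ll
        beta_new = _cd_inner(xz, gram, beta, N, lam, tol_inner, max_inner)
        if np.max(np.abs(beta_new)) > DIVERGENCE_BOUND:
            raise MonotoneLikelihoodError(
                f"penalized fit diverged at lambda={lam:g}"
            )
        delta = float(np.max(np.abs(beta_new - beta))) if p else 0.0
        rel_dev = (
            abs(dev - dev_prev) / (abs(dev_prev) + 1e-300)
            if dev_prev is not None
            else np.inf
        )
        trace.append({"outer": outer, "delta": delta, "deviance": dev})
        beta = beta_new
        if delta < tol_inner and rel_dev < tol_outer:
            return CoxCoefficients(
                beta=beta,
                features=list(features),
                lam=float(lam),
                converged=True,
                n_iterations=outer + 1,
                final_deviance=dev,
            )
        dev_prev = dev
    raise ConvergenceError(
        f"penalized Cox did not converge at lambda={lam:g} "
        f"within {max_outer} IRLS rounds",
        trace=trace,
    )


def lambda_grid(
    fed: Federation,
    features,
    standardization: StandardizationParams,
    K: int = 100,
    eps: float = 0.01,
    node_ids=None,
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to eps*lambda_max.

    lambda_max = max_k |U_k(0)| / N with U the pooled score at beta = 0 on
    standardized features and N the total number of training patients; by
    construction the fit at lambda_max is identically zero.
    """
    if K < 1:
        raise ParameterError("grid size K must be >= 1")
    if not 0 < eps < 1:
        raise ParameterError("eps must be in (0, 1)")
    p = len(features)
    std = standardization.restrict(features)
    N, n_events, _ll, xz, _gram = _cox_round(
        fed, np.zeros(p), features, std, "coordinate", node_ids
    )
    if n_events == 0:
        raise DegenerateNodeError("no events in any participating node")
    # at beta = 0, w_i z_i = g_i, so xz is exactly the pooled score U(0)
    lam_max = float(np.max(np.abs(xz)) / N)
    if lam_max <= 0:
        raise DegenerateNodeError("score at beta=0 is identically zero")
    if K == 1:
        return np.array([lam_max])
    return lam_max * eps ** (np.arange(K) / (K - 1))


def regularization_path(
    fed: Federation,
    features,
    standardization: StandardizationParams,
    grid: np.ndarray,
    node_ids=None,
    **fit_kwargs,
) -> RegularizationPath:
    """Warm-started penalized fits over a decreasing penalty grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ParameterError("empty lambda grid")
    if np.any(grid <= 0) or (grid.size > 1 and np.any(np.diff(grid) >= 0)):
        raise ParameterError("grid must be strictly decreasing and positive")
    p = len(features)
    coefs = np.empty((p, grid.size))
    beta = np.zeros(p)
    for j, lam in enumerate(grid):
        try:
            fit = fit_penalized(
                fed, features, lam, standardization, init=beta,
                node_ids=node_ids, **fit_kwargs,
            )
        except ConvergenceError as e:
            raise ConvergenceError(
                f"path fit failed at lambda={lam:g} (grid index {j}): {e}",
                trace=e.trace,
            ) from e
        beta = fit.beta
        coefs[:, j] = beta
    entry = np.full(p, np.nan)
    for k in range(p):
        nz = np.flatnonzero(np.abs(coefs[k]) > ENTRY_TOL)
        if nz.size:
            entry[k] = grid[nz[0]]  # grid decreasing: first nonzero = largest lambda
    return RegularizationPath(
        lambda_grid=grid,
        coef_matrix=coefs,
        entry_lambda=entry,
        feature_names=list(features),
    )


def entry_order(path: RegularizationPath) -> list[str]:
    """Features ranked by the penalty at which they first enter the model.

    Earlier entry (larger entry lambda) = more important. Features that never
    enter are appended last. Ties broken by larger |coefficient| at the
    smallest penalty, then lexicographically.
    """
    last = np.abs(path.coef_matrix[:, -1])
    keys = []
    for k, name in enumerate(path.feature_names):
        lam = path.entry_lambda[k]
        keys.append((-(lam if not np.isnan(lam) else -np.inf), -last[k], name))
    ranked = [path.feature_names[i] for i in sorted(range(len(keys)), key=keys.__getitem__)]
    never = path.never_entered()
    if never:
        logger.info("features never entering the path: %s", never)
    return ranked


# -- unpenalized final fit -----------------------------------------------


@dataclass
class FinalModel:
    """Unpenalized node-stratified Cox fit with Wald inference.

    Coefficients are on the standardized scale, so each hazard ratio is per
    1 pooled SD of the feature; ``beta_raw`` maps back to the native scale.
    """

    features: list[str]
    beta: np.ndarray
    se: np.ndarray
    standardization: StandardizationParams
    strata: list[str]
    loglik: float = np.nan
    n_iterations: int = 0
    hr: np.ndarray = field(init=False)
    hr_ci_low: np.ndarray = field(init=False)
    hr_ci_high: np.ndarray = field(init=False)
    wald_p: np.ndarray = field(init=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        self.se = np.asarray(self.se, float)
        self.hr = np.exp(self.beta)
        self.hr_ci_low = np.exp(self.beta - 1.96 * self.se)
        self.hr_ci_high = np.exp(self.beta + 1.96 * self.se)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / np.where(self.se > 0, self.se, 1.0), np.inf)
        self.wald_p = 2.0 * stats.norm.sf(np.abs(z))

    @property
    def beta_raw(self) -> np.ndarray:
        """Coefficients per native feature unit (beta_k / sd_k)."""
        sds = np.where(
            self.standardization.sds > 0, self.standardization.sds, np.nan
        )
        return self.beta / sds


def fit_unpenalized(
    fed: Federation,
    features,
    standardization: StandardizationParams,
    node_ids=None,
    grad_tol: float = 1e-8,
    max_iter: int = 100,
) -> FinalModel:
    """Newton-Raphson on the pooled node-stratified partial likelihood.

    Each iteration exchanges the local gradient (p) and full Hessian (p x p);
    step halving guards against overshooting. Standard errors come from the
    inverse of the pooled negative Hessian at the optimum.
    """
    p = len(features)
    std = standardization.restrict(features)
    beta = np.zeros(p)
    _N, n_events, ll, U, H = _cox_round(fed, beta, features, std, "newton", node_ids)
    if n_events == 0:
        raise DegenerateNodeError("no events in any participating node")
    for it in range(max_iter):
        if np.max(np.abs(U)) < grad_tol:
            break
        try:
            step = np.linalg.solve(-H, U)
        except np.linalg.LinAlgError:
            raise CollinearityError(
                "singular information matrix (collinear features?)"
            ) from None
        if not np.isfinite(step).all():
            raise CollinearityError("non-finite Newton step")
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            _N, _ne, ll_c, U_c, H_c = _cox_round(
                fed, cand, features, std, "newton", node_ids
            )
            if ll_c >= ll - 1e-9 * (1.0 + abs(ll)):
                break
            t *= 0.5
        else:
            raise ConvergenceError("step halving failed in Newton iteration")
        beta, ll, U, H = cand, ll_c, U_c, H_c
        if np.max(np.abs(beta)) > DIVERGENCE_BOUND:
            raise MonotoneLikelihoodError(
                "coefficients diverged (monotone likelihood)"
            )
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations"
        )
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        raise CollinearityError("singular information matrix at the optimum") from None
    dvar = np.diag(cov)
    if np.any(dvar <= 0):
        raise CollinearityError("non-positive variance estimate")
    return FinalModel(
        features=list(features),
        beta=beta,
        se=np.sqrt(dvar),
        standardization=std,
        strata=list(fed.node_ids if node_ids is None else node_ids),
        loglik=ll,
        n_iterations=it + 1,
    )
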