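"""Independent reference computations used as test oracles.

Everything here is deliberately written from the mathematical definitions,
sharing no code path with the package: a centralized stratified Breslow
partial likelihood with analytic gradient, a proximal-gradient (ISTA) LASSO
solver over it, and a brute-force pair-enumeration concordance index.
"""

from __future__ import annotations

import numpy as np


def pooled_groups(fed):
    """Materialize (X_std, times, events) per node from a federation's
    training partitions, standardizing with the supplied params applied
    to raw features — used only to hand data to centralized oracles."""
    groups = []
    for h in fed.nodes:
        d = h._train_data()
        groups.append((d.features.copy(), d.times.copy(), d.events.copy()))
    return groups


def stratified_nll_grad(groups, beta):
    """(negative log partial likelihood / N, gradient / N) for stratified
    Breslow Cox over pre-standardized groups [(X, t, e), ...]."""
    beta = np.asarray(beta, float)
    N = sum(len(t) for _X, t, _e in groups)
    ll = 0.0
    g = np.zeros_like(beta)
    for X, t, e in groups:
        if e.sum() == 0:
            continue
        eta = X @ beta
        shift = eta.max()
        o = np.argsort(t, kind="stable")
        ts, ev = t[o], e[o]
        Xs = X[o]
        etas = (eta - shift)[o]
        th = np.exp(etas)
        rs0 = np.cumsum(th[::-1])[::-1]
        rs1 = np.cumsum((th[:, None] * Xs)[::-1], axis=0)[::-1]
        ue, fi = np.unique(ts[ev == 1], return_index=True)
        start = np.searchsorted(ts, ue, "left")
        d = np.diff(np.append(fi, int((ev == 1).sum()))).astype(float)
        S0, S1 = rs0[start], rs1[start]
        ll += etas[ev == 1].sum() - (d * np.log(S0)).sum()
        g += Xs[ev == 1].sum(axis=0) - (d[:, None] * S1 / S0[:, None]).sum(axis=0)
    return -ll / N, -g / N


def ista_lasso_cox(groups, lam, p, beta0=None, max_iter=200000, tol=1e-11):
    """Proximal-gradient solution of min nll(beta)/N + lam * ||beta||_1."""
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    step = 1.0
    f, g = stratified_nll_grad(groups, beta)
    for _ in range(max_iter):
        while True:
            z = beta - step * g
            nb = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0.0)
            fn, gn = stratified_nll_grad(groups, nb)
            diff = nb - beta
            if fn <= f + g @ diff + (diff @ diff) / (2 * step) + 1e-16:
                break
            step *= 0.5
        moved = np.max(np.abs(nb - beta)) if p else 0.0
        beta, f, g = nb, fn, gn
        if moved < tol:
            break
        step *= 1.1
    return beta


def brute_force_c_index(scores, times, events):
    """O(n^2) pair enumeration: comparable iff T_i < T_j and subject i died;
    concordant iff the earlier death has the higher score; score ties 0.5."""
    n = len(times)
    num = 0.0
    comp = 0
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if times[i] < times[j]:
                comp += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    if comp == 0:
        return None
    return num / comp


def direct_logrank(ta, ea, tb, eb):
    """Term-by-term O-E / hypergeometric-variance accumulation."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    events = sorted(set(ta[ea == 1]) | set(tb[eb == 1]))
    ome = 0.0
    var = 0.0
    for u in events:
        na = float((ta >= u).sum())
        nb = float((tb >= u).sum())
        n = na + nb
        da = float(((ta == u) & (ea == 1)).sum())
        d = da + float(((tb == u) & (eb == 1)).sum())
        ome += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return ome, var
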