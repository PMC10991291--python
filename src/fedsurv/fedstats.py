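"""Federated first/second moments, Pearson correlations and standardization.

Each node contributes only additive sufficient statistics (sums, cross-product
sums and an outcome column encoded as either survival time or event status).
Because the statistics are additive, the pooled correlation matrix and the
pooled means/SDs computed here are *exactly* those a centralized analysis
would produce — this is the module's core guarantee and is enforced by tests.

The variance convention is population (divisor ``n``): it makes the formulas
exactly additive across nodes, and Pearson correlation is invariant to the
choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import NodeDataset
from .exceptions import MergeError, ParameterError, SizeError
from .federation import AggregatePayload, NodeHandle, register_task

logger = logging.getLogger(__name__)

OUTCOME_ENCODINGS = ("time", "event")

_DEGENERATE_TOL = 1e-12


@dataclass
class MomentAggregate:
    """Additive sufficient statistics of one node (or a merge of nodes)."""

    n: int
    sum_x: np.ndarray  # (p,)
    sum_xx: np.ndarray  # (p, p) cross-products, symmetric
    sum_y: float
    sum_yy: float
    sum_xy: np.ndarray  # (p,)
    outcome_encoding: str

    def __post_init__(self):
        self.sum_x = np.asarray(self.sum_x, dtype=float)
        self.sum_xx = np.asarray(self.sum_xx, dtype=float)
        self.sum_xy = np.asarray(self.sum_xy, dtype=float)
        if self.outcome_encoding not in OUTCOME_ENCODINGS:
            raise ParameterError(f"unknown outcome encoding '{self.outcome_encoding}'")
        p = self.sum_x.shape[0]
        if self.sum_xx.shape != (p, p) or self.sum_xy.shape != (p,):
            raise MergeError("inconsistent moment shapes")
        if p and not np.allclose(self.sum_xx, self.sum_xx.T, atol=1e-8):
            raise MergeError("sum_xx is not symmetric")

    @property
    def p(self) -> int:
        return self.sum_x.shape[0]


@dataclass
class CorrelationBundle:
    """Pooled Pearson correlations: feature-feature and feature-outcome."""

    feature_corr: np.ndarray  # (p, p)
    outcome_corr: np.ndarray  # (p,)
    feature_names: list[str]
    n_total: int
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.feature_corr = np.asarray(self.feature_corr, dtype=float)
        self.outcome_corr = np.asarray(self.outcome_corr, dtype=float)
        p = len(self.feature_names)
        if self.feature_corr.shape != (p, p) or self.outcome_corr.shape != (p,):
            raise MergeError("correlation bundle shape mismatch")
        self._index = {name: j for j, name in enumerate(self.feature_names)}

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def indices(self, names) -> np.ndarray:
        try:
            return np.array([self._index[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown feature {e}") from None


@dataclass
class StandardizationParams:
    """Pooled means and population SDs; near-constant features are flagged."""

    means: np.ndarray
    sds: np.ndarray
    feature_names: list[str]
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self._index = {name: j for j, name in enumerate(self.feature_names)}

    def restrict(self, names) -> "StandardizationParams":
        idx = np.array([self._index[n] for n in names], dtype=int)
        return StandardizationParams(
            means=self.means[idx],
            sds=self.sds[idx],
            feature_names=list(names),
            degenerate=[n for n in self.degenerate if n in set(names)],
        )

    def apply(self, X: np.ndarray) -> np.ndarray:
        sds = np.where(self.sds < _DEGENERATE_TOL, 1.0, self.sds)
        return (X - self.means) / sds


def encode_outcome(data: NodeDataset, outcome_encoding: str) -> np.ndarray:
    """Outcome column used for feature-outcome correlation.

    ``time``: observed survival time in days (default; censoring-agnostic
    screening signal). ``event``: the 0/1 death indicator.
    """
    if outcome_encoding == "time":
        return data.times.astype(float)
    if outcome_encoding == "event":
        return data.events.astype(float)
    raise ParameterError(f"unknown outcome encoding '{outcome_encoding}'")


def local_moments(data: NodeDataset, outcome_encoding: str = "time") -> MomentAggregate:
    """Exact sums over one node's rows (runs node-side)."""
    if data.n_patients < 1:
        raise SizeError("empty training subset")
    X = data.features
    y = encode_outcome(data, outcome_encoding)
    return MomentAggregate(
        n=data.n_patients,
        sum_x=X.sum(axis=0),
        sum_xx=X.T @ X,
        sum_y=float(y.sum()),
        sum_yy=float(y @ y),
        sum_xy=X.T @ y,
        outcome_encoding=outcome_encoding,
    )


def merge_moments(parts: list[MomentAggregate]) -> MomentAggregate:
    """Component-wise sum; order-invariant by construction."""
    if not parts:
        raise MergeError("nothing to merge")
    first = parts[0]
    for part in parts[1:]:
        if part.p != first.p:
            raise MergeError(f"feature count mismatch: {part.p} vs {first.p}")
        if part.outcome_encoding != first.outcome_encoding:
            raise MergeError("outcome encoding mismatch")
    return MomentAggregate(
        n=sum(part.n for part in parts),
        sum_x=np.sum([part.sum_x for part in parts], axis=0),
        sum_xx=np.sum([part.sum_xx for part in parts], axis=0),
        sum_y=float(sum(part.sum_y for part in parts)),
        sum_yy=float(sum(part.sum_yy for part in parts)),
        sum_xy=np.sum([part.sum_xy for part in parts], axis=0),
        outcome_encoding=first.outcome_encoding,
    )


def correlations_from_moments(
    agg: MomentAggregate, feature_names: list[str]
) -> CorrelationBundle:
    """Pooled Pearson correlations from sufficient statistics.

    r_kl = (n*Sxx_kl - Sx_k*Sx_l) / sqrt((n*Sxx_kk - Sx_k^2)(n*Sxx_ll - Sx_l^2)),
    identically for the outcome using the y-sums. Equals the centralized
    correlation of the pooled table exactly. Zero-variance features get all
    correlations set to 0 and are flagged rather than raising.
    """
    if agg.n < 2:
        raise SizeError("need n >= 2 for correlations")
    if len(feature_names) != agg.p:
        raise MergeError("feature name count does not match aggregate")
    n = agg.n
    cov = n * agg.sum_xx - np.outer(agg.sum_x, agg.sum_x)
    var = np.clip(np.diag(cov).copy(), 0.0, None)
    var_y = max(n * agg.sum_yy - agg.sum_y**2, 0.0)
    ok = var > _DEGENERATE_TOL * n * n
    degenerate = [name for name, good in zip(feature_names, ok) if not good]
    if degenerate:
        logger.warning("degenerate (constant) features: %s", degenerate)

    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    np.fill_diagonal(r, np.where(ok, 1.0, 0.0))
    r = np.clip(r, -1.0, 1.0)

    cov_y = n * agg.sum_xy - agg.sum_x * agg.sum_y
    denom_y = np.sqrt(var * var_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_cf = np.where(denom_y > 0, cov_y / np.where(denom_y > 0, denom_y, 1.0), 0.0)
    r_cf[~ok] = 0.0
    r_cf = np.clip(r_cf, -1.0, 1.0)
    return CorrelationBundle(
        feature_corr=r,
        outcome_corr=r_cf,
        feature_names=list(feature_names),
        n_total=n,
        degenerate=degenerate,
    )


def standardization_params(
    agg: MomentAggregate, feature_names: list[str]
) -> StandardizationParams:
    """Pooled means and population SDs (divisor n) from the moment sums."""
    if agg.n < 2:
        raise SizeError("need n >= 2 for standardization")
    means = agg.sum_x / agg.n
    var = np.clip(np.diag(agg.sum_xx) / agg.n - means**2, 0.0, None)
    sds = np.sqrt(var)
    degenerate = [
        name for name, sd in zip(feature_names, sds) if sd < _DEGENERATE_TOL
    ]
    if degenerate:
        logger.warning("features with ~zero SD: %s", degenerate)
    return StandardizationParams(
        means=means, sds=sds, feature_names=list(feature_names), degenerate=degenerate
    )


# -- federated task ------------------------------------------------------


@register_task("local_moments")
def _local_moments_task(handle: NodeHandle, outcome_encoding: str = "time"):
    agg = local_moments(handle._train_data(), outcome_encoding)
    return AggregatePayload.build(
        "moments",
        handle.node_id,
        {
            "n": agg.n,
            "sum_x": agg.sum_x,
            "sum_xx": agg.sum_xx,
            "sum_y": agg.sum_y,
            "sum_yy": agg.sum_yy,
            "sum_xy": agg.sum_xy,
            "outcome_encoding": agg.outcome_encoding,
        },
    )


def moments_from_payload(payload: AggregatePayload) -> MomentAggregate:
    c = payload.content
    return MomentAggregate(
        n=int(c["n"]),
        sum_x=np.asarray(c["sum_x"], dtype=float),
        sum_xx=np.asarray(c["sum_xx"], dtype=float),
        sum_y=float(c["sum_y"]),
        sum_yy=float(c["sum_yy"]),
        sum_xy=np.asarray(c["sum_xy"], dtype=float),
        outcome_encoding=c["outcome_encoding"],
    )


def federated_moments(fed, node_ids=None, outcome_encoding: str = "time"):
    """One federated round of moment collection, merged at the aggregator."""
    payloads = fed.execute_round(
        "local_moments", node_ids=node_ids, outcome_encoding=outcome_encoding
    )
    return merge_moments([moments_from_payload(p) for p in payloads])
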