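"""Final-model validation: test C-indices, risk stratification, KM, log-rank.

Each patient's risk score is exp(linear predictor) relative to the stratum
baseline, computed on the model's standardized scale. The global high/low
cutoff is the median of the per-institution median risk scores — an
aggregate-only analogue of a pooled median. Kaplan-Meier curves and two-group
log-rank tests are computed per institution; KM tables travel to the
aggregator for central plotting (the one whitelisted payload kind).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import NodeDataset
from .exceptions import SizeError, UndefinedMetricError
from .federation import AggregatePayload, Federation, NodeHandle, register_task
from .cox import FinalModel
from .model_selection import harrell_c_index

logger = logging.getLogger(__name__)


@dataclass
class KMTable:
    """Product-limit estimate tabulated at the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, float)
        self.n_at_risk = np.asarray(self.n_at_risk, float)
        self.n_events = np.asarray(self.n_events, float)
        self.survival = np.asarray(self.survival, float)


@dataclass
class NodeStratification:
    """One institution's test-set stratification summary (aggregates only)."""

    node_id: str
    n_low: int
    n_high: int
    km_low: KMTable | None
    km_high: KMTable | None
    logrank_chi2: float
    logrank_p: float


@dataclass
class RiskStratification:
    threshold: float
    node_medians: dict[str, float]
    per_node: dict[str, NodeStratification] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    test_c_index: dict[str, float | None]  # None when undefined on that node
    stratification: RiskStratification


def risk_scores(model: FinalModel, data: NodeDataset) -> np.ndarray:
    """exp(linear predictor) using the model's stored standardization."""
    try:
        idx = [data.feature_names.index(f) for f in model.features]
    except ValueError as e:
        raise KeyError(f"model feature missing from node '{data.node_id}': {e}") from None
    X = model.standardization.apply(data.features[:, idx])
    return np.exp(X @ model.beta)


def global_threshold(node_medians) -> float:
    """Median of the per-institution medians (even count: mean of middles)."""
    med = np.asarray(list(node_medians), float)
    if med.size == 0:
        raise SizeError("no node medians provided")
    return float(np.median(med))


def stratify(scores, threshold: float) -> np.ndarray:
    """'low' where score < threshold, 'high' where score >= threshold."""
    s = np.asarray(scores, float)
    return np.where(s < threshold, "low", "high").astype(object)


def km_curve(times, events) -> KMTable:
    """Kaplan-Meier product-limit estimator.

    Steps occur only at event times: S <- S * (1 - d_j / n_j). Censored-only
    times shrink the at-risk count without a step.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise SizeError("empty sample")
    ue = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= u).sum() for u in ue], float)
    d = np.array([((t == u) & (e == 1)).sum() for u in ue], float)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    return KMTable(event_times=ue, n_at_risk=n_at_risk, n_events=d, survival=surv)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    Over the pooled distinct event times, accumulates observed-minus-expected
    deaths in group a with the hypergeometric variance;
    chi2 = (sum(O - E))^2 / sum(V), p from chi-square with 1 df.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise SizeError("both groups must be non-empty")
    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    if pooled_e.sum() == 0:
        raise UndefinedMetricError("no events in either group")
    ue = np.unique(pooled_t[pooled_e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in ue:
        n_a = float((ta >= u).sum())
        n_b = float((tb >= u).sum())
        n = n_a + n_b
        d_a = float(((ta == u) & (ea == 1)).sum())
        d = d_a + float(((tb == u) & (eb == 1)).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1.0)
    if var <= 0:
        raise UndefinedMetricError("log-rank variance is zero")
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# -- federated tasks -----------------------------------------------------


def _model_from_params(features, beta, std_means, std_sds, node_id):
    from .fedstats import StandardizationParams

    return FinalModel(
        features=list(features),
        beta=np.asarray(beta, float),
        se=np.ones(len(features)),
        standardization=StandardizationParams(
            means=np.asarray(std_means, float),
            sds=np.asarray(std_sds, float),
            feature_names=list(features),
        ),
        strata=[node_id],
    )


@register_task("test_cindex")
def _test_cindex_task(handle: NodeHandle, beta, features, std_means, std_sds):
    data = handle._test_data()
    model = _model_from_params(features, beta, std_means, std_sds, handle.node_id)
    try:
        c = harrell_c_index(risk_scores(model, data), data.times, data.events)
        defined = True
    except UndefinedMetricError:
        c, defined = float("nan"), False
    return AggregatePayload.build(
        "scalar_metric",
        handle.node_id,
        {"c_index": c, "defined": defined, "n_test": data.n_patients},
    )


@register_task("risk_median")
def _risk_median_task(
    handle: NodeHandle, beta, features, std_means, std_sds, partition: str = "test"
):
    data = handle._test_data() if partition == "test" else handle._train_data()
    model = _model_from_params(features, beta, std_means, std_sds, handle.node_id)
    scores = risk_scores(model, data)
    return AggregatePayload.build(
        "median_scalar", handle.node_id, {"median": float(np.median(scores))}
    )


@register_task("stratify_km")
def _stratify_km_task(
    handle: NodeHandle, beta, features, std_means, std_sds, threshold: float
):
    data = handle._test_data()
    model = _model_from_params(features, beta, std_means, std_sds, handle.node_id)
    scores = risk_scores(model, data)
    labels = stratify(scores, threshold)
    content: dict = {"threshold": float(threshold)}
    masks = {"low": labels == "low", "high": labels == "high"}
    for name, mask in masks.items():
        content[f"n_{name}"] = int(mask.sum())
        if mask.any() and data.events[mask].sum() > 0:
            km = km_curve(data.times[mask], data.events[mask])
            content[f"km_{name}_times"] = km.event_times
            content[f"km_{name}_at_risk"] = km.n_at_risk
            content[f"km_{name}_events"] = km.n_events
            content[f"km_{name}_survival"] = km.survival
    try:
        chi2, p = logrank_test(
            data.times[masks["low"]], data.events[masks["low"]],
            data.times[masks["high"]], data.events[masks["high"]],
        )
    except (SizeError, UndefinedMetricError):
        chi2, p = float("nan"), float("nan")
    content["logrank_chi2"] = chi2
    content["logrank_p"] = p
    return AggregatePayload.build("km_table", handle.node_id, content)


def evaluate_final(
    fed: Federation, model: FinalModel, threshold_partition: str = "test"
) -> EvaluationReport:
    """Per-node test C-index plus risk stratification with KM and log-rank.

    Node medians feeding the global threshold are taken from the partition
    named by ``threshold_partition`` (default: the held-out test sets). A
    node whose C-index is undefined is reported as None without affecting
    the others.
    """
    params = dict(
        beta=model.beta,
        features=model.features,
        std_means=model.standardization.means,
        std_sds=model.standardization.sds,
    )
    c_payloads = fed.execute_round("test_cindex", **params)
    test_c = {
        p.node_id: (float(p.content["c_index"]) if p.content["defined"] else None)
        for p in c_payloads
    }
    for node_id, c in test_c.items():
        if c is None:
            logger.warning("C-index undefined on node '%s' test set", node_id)

    med_payloads = fed.execute_round(
        "risk_median", partition=threshold_partition, **params
    )
    medians = {p.node_id: float(p.content["median"]) for p in med_payloads}
    threshold = global_threshold(medians.values())

    km_payloads = fed.execute_round("stratify_km", threshold=threshold, **params)
    strat = RiskStratification(threshold=threshold, node_medians=medians)
    for p in km_payloads:
        c = p.content

        def _km(prefix):
            if f"km_{prefix}_times" not in c:
                return None
            return KMTable(
                event_times=np.asarray(c[f"km_{prefix}_times"], float),
                n_at_risk=np.asarray(c[f"km_{prefix}_at_risk"], float),
                n_events=np.asarray(c[f"km_{prefix}_events"], float),
                survival=np.asarray(c[f"km_{prefix}_survival"], float),
            )

        strat.per_node[p.node_id] = NodeStratification(
            node_id=p.node_id,
            n_low=int(c["n_low"]),
            n_high=int(c["n_high"]),
            km_low=_km("low"),
            km_high=_km("high"),
            logrank_chi2=float(c["logrank_chi2"]),
            logrank_p=float(c["logrank_p"]),
        )
    return EvaluationReport(test_c_index=test_c, stratification=strat)
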