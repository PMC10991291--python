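"""Candidate feature sets, leave-one-node-out CV and Harrell's C-index.

The regularization path's entry order induces nested candidate sets (the
prefixes from the two most important features up to all of them). Each
candidate is scored by leave-one-node-out (LONO) cross-validation: an
unpenalized node-stratified Cox model is fitted on two institutions'
training partitions and scored on the held-out institution via Harrell's
concordance index. Per-fold hazard ratios with Wald CIs are recorded, and
fold C-indices are summarised by their mean with a Student-t 95% interval
(n_folds - 1 degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    FedsurvError,
    ParameterError,
    SelectionError,
    SizeError,
    UndefinedMetricError,
)
from .federation import AggregatePayload, Federation, NodeHandle, register_task
from .fedstats import federated_moments, standardization_params
from . import cox

logger = logging.getLogger(__name__)


def candidate_sets(order: list[str]) -> list[list[str]]:
    """Nested prefixes of the entry order, sizes 2..p (most important first)."""
    if len(order) < 2:
        raise SizeError("need at least 2 ranked features to build candidate sets")
    return [list(order[:k]) for k in range(2, len(order) + 1)]


def lono_folds(node_ids: list[str]) -> list[tuple[tuple[str, ...], str]]:
    """One fold per node; the held-out institution rotates from last to first.

    For nodes (A, B, C): folds are train (A,B)/validate C, train (C,A)/
    validate B, train (B,C)/validate A.
    """
    m = len(node_ids)
    if m < 2:
        raise SizeError("LONO needs at least 2 nodes")
    folds = []
    for v in range(m - 1, -1, -1):
        train = tuple(node_ids[(v + 1 + j) % m] for j in range(m - 1))
        folds.append((train, node_ids[v]))
    return folds


def harrell_c_index(scores, times, events) -> float:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) is comparable when T_i < T_j and subject i died; it is
    concordant when the earlier death carries the higher risk score. Ties in
    score count one half. Raises when no pair is comparable.
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if not (len(s) == len(t) == len(e)):
        raise ParameterError("scores, times and events must have equal length")
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs")
    concordant = int((comparable & (s[:, None] > s[None, :])).sum())
    tied = int((comparable & (s[:, None] == s[None, :])).sum())
    return (concordant + 0.5 * tied) / n_comp


def summarize_folds(values) -> tuple[float, float, float]:
    """Cross-fold mean with Student-t 95% CI (df = n_folds - 1)."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise SizeError("need at least 2 folds to summarise")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = stats.t.ppf(0.975, v.size - 1) * sd / np.sqrt(v.size)
    return mean, mean - half, mean + half


@dataclass
class FoldResult:
    train_node_ids: tuple[str, ...]
    valid_node_id: str
    features: list[str]
    hr: np.ndarray | None = None
    hr_ci_low: np.ndarray | None = None
    hr_ci_high: np.ndarray | None = None
    c_index: float | None = None
    failed: bool = False
    error: str = ""


@dataclass
class CandidateEvaluation:
    features: list[str]
    folds: list[FoldResult]
    mean_c: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    failed: bool = False


@dataclass
class CVReport:
    candidates: list[CandidateEvaluation]
    folds: list[tuple[tuple[str, ...], str]]
    selected_set: list[str] | None = None


@register_task("cv_validate")
def _cv_validate_task(
    handle: NodeHandle, beta, features, std_means, std_sds, partition: str = "train"
):
    """Held-out scoring: risk scores stay local, only the C-index travels."""
    from .evaluation import risk_scores  # local import avoids a cycle

    from .fedstats import StandardizationParams

    data = handle._train_data() if partition == "train" else handle._test_data()
    model = cox.FinalModel(
        features=list(features),
        beta=np.asarray(beta, float),
        se=np.ones(len(features)),
        standardization=StandardizationParams(
            means=np.asarray(std_means, float),
            sds=np.asarray(std_sds, float),
            feature_names=list(features),
        ),
        strata=[handle.node_id],
    )
    try:
        c = harrell_c_index(risk_scores(model, data), data.times, data.events)
        defined = True
    except UndefinedMetricError:
        c, defined = float("nan"), False
    return AggregatePayload.build(
        "scalar_metric",
        handle.node_id,
        {"c_index": c, "defined": defined, "metric": "harrell_c"},
    )


def cross_validate(
    fed: Federation,
    candidates: list[list[str]],
    outcome_encoding: str = "time",
) -> CVReport:
    """LONO cross-validation of every candidate set.

    Standardization is re-derived from each fold's training nodes only (the
    validation institution contributes nothing to the fit). Validation uses
    the held-out node's training partition; its 20% test partition stays
    untouched until final evaluation. Sets with any failed fold are excluded
    from selection and logged.
    """
    if not candidates:
        raise SizeError("no candidate sets to evaluate")
    folds = lono_folds(fed.node_ids)
    fold_stds = []
    for train_ids, _valid in folds:
        agg = federated_moments(fed, node_ids=train_ids, outcome_encoding=outcome_encoding)
        fold_stds.append(standardization_params(agg, _first_feature_names(fed)))

    evaluations = []
    for cand in candidates:
        fold_results = []
        for (train_ids, valid_id), full_std in zip(folds, fold_stds):
            fr = FoldResult(train_node_ids=train_ids, valid_node_id=valid_id,
                            features=list(cand))
            try:
                std = full_std.restrict(cand)
                model = cox.fit_unpenalized(fed, cand, std, node_ids=train_ids)
                payload = fed.execute_round(
                    "cv_validate",
                    node_ids=[valid_id],
                    beta=model.beta,
                    features=cand,
                    std_means=std.means,
                    std_sds=std.sds,
                    partition="train",
                )[0]
                if not payload.content["defined"]:
                    raise UndefinedMetricError(
                        f"C-index undefined on node '{valid_id}'"
                    )
                fr.hr = model.hr
                fr.hr_ci_low = model.hr_ci_low
                fr.hr_ci_high = model.hr_ci_high
                fr.c_index = float(payload.content["c_index"])
            except FedsurvError as e:
                fr.failed = True
                fr.error = str(e)
                logger.warning(
                    "fold (train=%s, valid=%s) failed for set %s: %s",
                    train_ids, valid_id, cand, e,
                )
            fold_results.append(fr)
        ev = CandidateEvaluation(features=list(cand), folds=fold_results)
        if any(fr.failed for fr in fold_results):
            ev.failed = True
        else:
            ev.mean_c, ev.ci_low, ev.ci_high = summarize_folds(
                [fr.c_index for fr in fold_results]
            )
        evaluations.append(ev)
    report = CVReport(candidates=evaluations, folds=folds)
    try:
        report.selected_set = select_best(report)
    except SelectionError:
        report.selected_set = None
    return report


def select_best(report: CVReport) -> list[str]:
    """Best candidate by mean C-index; ties favour the smaller, earlier set."""
    best = None
    best_key = None
    for pos, ev in enumerate(report.candidates):
        if ev.failed or ev.mean_c is None:
            continue
        key = (-ev.mean_c, len(ev.features), pos)
        if best_key is None or key < best_key:
            best_key, best = key, ev
    if best is None:
        raise SelectionError("no candidate set was successfully evaluated")
    return list(best.features)


def _first_feature_names(fed: Federation) -> list[str]:
    # feature names are shared metadata, identical across nodes
    return list(fed.nodes[0]._dataset.feature_names)
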