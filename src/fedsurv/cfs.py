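"""Correlation-based Feature Selection over a federated correlation bundle.

CFS scores a candidate subset S of k features with Hall's merit

    M_S = k * rbar_cf / sqrt(k + k (k - 1) * rbar_ff)

where ``rbar_cf`` is the mean absolute feature-outcome correlation over S and
``rbar_ff`` the mean absolute pairwise feature-feature correlation within S.
High merit rewards subsets that track the outcome while being mutually
uncorrelated. Since merit depends on the data only through the pooled
correlation bundle, the federated search is exactly the centralized one.

Search is forward best-first with a stale-expansion stopping rule; an
exhaustive enumerator (p <= 15) serves as the optimality oracle in tests.
Tie-breaking everywhere is: higher merit, then smaller subset, then
lexicographic order — deterministic across platforms.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SizeError
from .fedstats import CorrelationBundle

logger = logging.getLogger(__name__)


@dataclass
class CFSResult:
    selected: list[str]  # ordered by decreasing |r_cf|
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def merit(subset, bundle: CorrelationBundle) -> float:
    """Hall's merit of a non-empty feature subset (absolute correlations)."""
    names = list(subset)
    if not names:
        raise SizeError("merit of the empty subset is undefined")
    idx = bundle.indices(names)
    k = len(idx)
    rbar_cf = float(np.mean(np.abs(bundle.outcome_corr[idx])))
    if k == 1:
        return rbar_cf
    sub = np.abs(bundle.feature_corr[np.ix_(idx, idx)])
    rbar_ff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * rbar_cf / np.sqrt(k + k * (k - 1) * rbar_ff)


def _key(m: float, names: tuple[str, ...]):
    # Total order: higher merit first, then smaller subset, then lexicographic.
    return (-m, len(names), names)


def _order_selected(names, bundle: CorrelationBundle) -> list[str]:
    idx = bundle.indices(names)
    strength = np.abs(bundle.outcome_corr[idx])
    return [n for _, n in sorted(zip(-strength, names))]


def best_first_search(
    bundle: CorrelationBundle, max_stale: int = 5
) -> CFSResult:
    """Forward best-first search from the empty set.

    Expands subsets by single-feature additions, keeping an open list ordered
    by merit; terminates after ``max_stale`` consecutive expansions without
    improving the best merit seen.
    """
    if bundle.p < 1:
        raise SizeError("no features to select from")
    features = sorted(bundle.feature_names)

    trace: list[tuple[tuple[str, ...], float]] = []
    seen: set[tuple[str, ...]] = set()
    open_list: list = []

    def evaluate(names: tuple[str, ...]) -> float:
        m = merit(names, bundle)
        trace.append((names, m))
        return m

    best_names: tuple[str, ...] | None = None
    best_key = None
    for f in features:
        names = (f,)
        m = evaluate(names)
        seen.add(names)
        heapq.heappush(open_list, _key(m, names))
        if best_key is None or _key(m, names) < best_key:
            best_key = _key(m, names)
            best_names = names

    stale = 0
    while open_list and stale < max_stale:
        _negm, _sz, current = heapq.heappop(open_list)
        improved = False
        current_set = set(current)
        for f in features:
            if f in current_set:
                continue
            child = tuple(sorted(current_set | {f}))
            if child in seen:
                continue
            seen.add(child)
            m = evaluate(child)
            heapq.heappush(open_list, _key(m, child))
            if _key(m, child) < best_key:
                best_key = _key(m, child)
                best_names = child
                improved = True
        stale = 0 if improved else stale + 1

    selected = _order_selected(best_names, bundle)
    result = CFSResult(
        selected=selected,
        merit=-best_key[0],
        trace=trace,
        config={"max_stale": max_stale, "search": "best_first"},
    )
    logger.info(
        "CFS selected %d feature(s) with merit %.4f: %s",
        len(selected),
        result.merit,
        selected,
    )
    return result


def exhaustive_best_subset(bundle: CorrelationBundle) -> CFSResult:
    """Maximize merit over all non-empty subsets (oracle; p <= 15).

    Ties broken by smaller size then lexicographic order, matching the
    heuristic search's ordering.
    """
    if bundle.p > 15:
        raise SizeError(f"exhaustive search limited to p <= 15, got p={bundle.p}")
    if bundle.p < 1:
        raise SizeError("no features to select from")
    features = sorted(bundle.feature_names)
    best_key = None
    best_names = None
    trace = []
    for k in range(1, len(features) + 1):
        for combo in itertools.combinations(features, k):
            m = merit(combo, bundle)
            trace.append((combo, m))
            if best_key is None or _key(m, combo) < best_key:
                best_key = _key(m, combo)
                best_names = combo
    return CFSResult(
        selected=_order_selected(best_names, bundle),
        merit=-best_key[0],
        trace=trace,
        config={"search": "exhaustive"},
    )
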