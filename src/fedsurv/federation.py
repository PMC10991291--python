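"""In-process simulation of a star-topology federated learning network.

Mirrors the message contract of a Vantage6-style deployment: a central
orchestrator dispatches named tasks to institution nodes, each node executes
the task against its private :class:`~fedsurv.data_io.NodeDataset`, and only
:class:`AggregatePayload` objects travel back. Every payload is recorded in a
transcript and screened by the privacy validator, which rejects any array
whose size scales with the node's patient count rather than with the feature
count or the penalty-grid size. Kaplan-Meier tables are the one whitelisted
exception: event times are shared in the clear so the aggregator can plot
centre-level survival curves.

The network stack itself (servers, containers, authentication) is out of
scope; payloads are plain serializable dictionaries so a transport could be
added without touching the algorithms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .data_io import NodeDataset, SplitAssignment
from .exceptions import DataValidationError, DispatchError, RoundError

logger = logging.getLogger(__name__)

PAYLOAD_KINDS = (
    "moments",
    "cox_round",
    "cox_scalar",
    "km_table",
    "scalar_metric",
    "median_scalar",
)

#: Payload kinds exempt from the dimension check. KM tables are sized by the
#: number of distinct event times, which can approach n; sharing them matches
#: the practice of central KM plotting (encrypted alternatives are future work).
WHITELISTED_KINDS = ("km_table",)


def _array_items(content: dict) -> dict[str, np.ndarray]:
    return {
        k: np.asarray(v)
        for k, v in content.items()
        if isinstance(v, (list, tuple, np.ndarray))
    }


@dataclass
class AggregatePayload:
    """The only object allowed to cross a node boundary.

    ``declared_dims`` maps each array in ``content`` to its largest axis
    extent; the privacy validator reasons about these declared sizes, and
    construction fails if a declaration disagrees with the actual array.
    """

    payload_kind: str
    node_id: str
    content: dict[str, Any]
    declared_dims: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.payload_kind not in PAYLOAD_KINDS:
            raise DataValidationError(f"unknown payload kind '{self.payload_kind}'")
        arrays = _array_items(self.content)
        for name, arr in arrays.items():
            if name not in self.declared_dims:
                raise DataValidationError(
                    f"payload from '{self.node_id}': array '{name}' has no "
                    "declared dimension"
                )
            actual = max(arr.shape) if arr.ndim else 1
            if self.declared_dims[name] != actual:
                raise DataValidationError(
                    f"payload from '{self.node_id}': array '{name}' declares "
                    f"{self.declared_dims[name]} but has extent {actual}"
                )

    @classmethod
    def build(cls, kind: str, node_id: str, content: dict[str, Any]):
        """Construct with dimensions auto-declared from the arrays themselves."""
        dims = {
            k: (max(a.shape) if a.ndim else 1)
            for k, a in _array_items(content).items()
        }
        return cls(payload_kind=kind, node_id=node_id, content=content, declared_dims=dims)

    def to_dict(self) -> dict:
        content = {
            k: (np.asarray(v).tolist() if isinstance(v, (np.ndarray, list, tuple)) else v)
            for k, v in self.content.items()
        }
        return {
            "payload_kind": self.payload_kind,
            "node_id": self.node_id,
            "content": content,
            "declared_dims": dict(self.declared_dims),
        }


@dataclass(frozen=True)
class PrivacyPolicy:
    """Sizes a payload dimension may legitimately take.

    A dimension is justified when it is a function of the feature count ``p``
    (at most ``p``, covering feature subsets, or exactly ``p*p`` is never
    declared since declarations are per-axis) or equals the penalty grid
    size. Anything that reaches the node's patient count is a leak.
    """

    n_features: int
    grid_size: int = 0
    whitelist: tuple = WHITELISTED_KINDS

    def dimension_allowed(self, dim: int) -> bool:
        return dim <= self.n_features or (self.grid_size and dim == self.grid_size)


def check_privacy(
    payload: AggregatePayload, node_n: int, policy: PrivacyPolicy
) -> list[str]:
    """Return the list of privacy violations for one payload (empty = clean).

    A violation is an array whose declared dimension equals or exceeds the
    node's patient count without being justified by the feature count or the
    penalty-grid size. Whitelisted kinds (KM tables) pass unconditionally.
    """
    if payload.payload_kind in policy.whitelist:
        return []
    violations = []
    for name, dim in payload.declared_dims.items():
        if dim >= node_n and not policy.dimension_allowed(dim):
            violations.append(
                f"payload '{payload.payload_kind}' from node '{payload.node_id}': "
                f"array '{name}' has dimension {dim} >= patient count {node_n}"
            )
    return violations


class NodeHandle:
    """Orchestrator-side handle to one institution.

    The dataset reference is private: the orchestrator never touches it
    directly, only through registered task functions whose results must be
    :class:`AggregatePayload` instances.
    """

    def __init__(self, dataset: NodeDataset, split: SplitAssignment | None = None):
        if split is not None and split.node_id != dataset.node_id:
            raise DataValidationError("split/node id mismatch")
        self.node_id = dataset.node_id
        self._dataset = dataset
        self.split = split

    @property
    def n_patients(self) -> int:
        return self._dataset.n_patients

    # Accessors below are intended for task functions executing *at* the node.
    def _train_data(self) -> NodeDataset:
        if self.split is None:
            return self._dataset
        return self._dataset.subset(self.split.train_indices)

    def _test_data(self) -> NodeDataset:
        if self.split is None:
            raise DataValidationError(f"node '{self.node_id}' has no split assigned")
        return self._dataset.subset(self.split.test_indices)


TASK_REGISTRY: dict[str, Callable[..., AggregatePayload]] = {}


def register_task(name: str):
    """Register a function as a dispatchable federated task.

    Task signature: ``fn(handle: NodeHandle, **params) -> AggregatePayload``.
    """

    def deco(fn):
        TASK_REGISTRY[name] = fn
        return fn

    return deco


@dataclass
class TranscriptRecord:
    """One inter-node message as observed by the orchestrator."""

    task: str
    node_n: int
    payload: AggregatePayload


class Federation:
    """Plain orchestrator over a set of node handles.

    Holds no privileged view of any dataset; it can only dispatch registered
    tasks and merge the aggregate payloads that come back. All traffic is
    appended to ``transcript`` for later audit.
    """

    def __init__(self, nodes: list[NodeHandle], policy: PrivacyPolicy):
        if not nodes:
            raise DataValidationError("federation needs at least one node")
        ids = [h.node_id for h in nodes]
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate node ids")
        self.nodes = list(nodes)
        self.policy = policy
        self.transcript: list[TranscriptRecord] = []

    @property
    def node_ids(self) -> list[str]:
        return [h.node_id for h in self.nodes]

    def handles(self, node_ids=None) -> list[NodeHandle]:
        if node_ids is None:
            return list(self.nodes)
        by_id = {h.node_id: h for h in self.nodes}
        try:
            return [by_id[i] for i in node_ids]
        except KeyError as e:
            raise DispatchError(f"unknown node id {e}") from None

    def execute_round(
        self, task: str, node_ids=None, **params
    ) -> list[AggregatePayload]:
        """Dispatch one task to (a subset of) the nodes; collect one payload each.

        Any node-side exception aborts the round with the failing node named;
        partial progress is discarded, matching a fail-fast deployment.
        """
        if task not in TASK_REGISTRY:
            raise DispatchError(f"task '{task}' is not registered")
        fn = TASK_REGISTRY[task]
        payloads = []
        for handle in self.handles(node_ids):
            try:
                payload = fn(handle, **params)
            except RoundError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with node id
                raise RoundError(handle.node_id, f"task '{task}' failed: {e}") from e
            violations = check_privacy(payload, handle.n_patients, self.policy)
            self.transcript.append(
                TranscriptRecord(task=task, node_n=handle.n_patients, payload=payload)
            )
            if violations:
                raise RoundError(
                    handle.node_id, "privacy violation: " + "; ".join(violations)
                )
            payloads.append(payload)
        return payloads

    # -- transcript audit -------------------------------------------------

    def audit(self) -> list[str]:
        """Re-run the privacy validator over every recorded message."""
        return audit_transcript(self.transcript, self.policy)

    def save_transcript(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                json.dumps(
                    {
                        "policy": {
                            "n_features": self.policy.n_features,
                            "grid_size": self.policy.grid_size,
                        }
                    }
                )
                + "\n"
            )
            for rec in self.transcript:
                fh.write(
                    json.dumps(
                        {
                            "task": rec.task,
                            "node_n": rec.node_n,
                            "payload": rec.payload.to_dict(),
                        }
                    )
                    + "\n"
                )


def audit_transcript(
    transcript: list[TranscriptRecord], policy: PrivacyPolicy
) -> list[str]:
    violations = []
    for rec in transcript:
        violations.extend(check_privacy(rec.payload, rec.node_n, policy))
    return violations


def load_transcript(path) -> tuple[list[TranscriptRecord], PrivacyPolicy]:
    """Load a transcript saved by :meth:`Federation.save_transcript`."""
    records = []
    with open(path) as fh:
        header = json.loads(fh.readline())
        policy = PrivacyPolicy(
            n_features=header["policy"]["n_features"],
            grid_size=header["policy"]["grid_size"],
        )
        for line in fh:
            d = json.loads(line)
            p = d["payload"]
            records.append(
                TranscriptRecord(
                    task=d["task"],
                    node_n=d["node_n"],
                    payload=AggregatePayload(
                        payload_kind=p["payload_kind"],
                        node_id=p["node_id"],
                        content=p["content"],
                        declared_dims=p["declared_dims"],
                    ),
                )
            )
    return records, policy
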