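"""Survival data containers, CSV I/O and per-node train/test splitting.

A :class:`NodeDataset` is one institution's survival table: patient ids,
follow-up times in days, death indicators and a numeric feature matrix.
Datasets never leave their node; everything downstream exchanges aggregates
only (see :mod:`fedsurv.federation`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    EmptyDatasetError,
    ParameterError,
    SchemaError,
    SizeError,
)

logger = logging.getLogger(__name__)

#: Default CSV column names (override via the ``schema`` mapping).
DEFAULT_SCHEMA = {"id": "patient_id", "time": "time_days", "event": "event"}


@dataclass
class NodeDataset:
    """One institution's survival table.

    Parameters
    ----------
    node_id : str
        Institution identifier (e.g. ``"site_a"``).
    patient_ids : ndarray of str
    times : ndarray of float
        Survival/censoring times in days, strictly positive. Measured from
        the first radiotherapy fraction to death or last follow-up.
    events : ndarray of int
        1 = death (from any cause), 0 = censored.
    features : ndarray, shape (n_patients, p)
    feature_names : list of str
    """

    node_id: str
    patient_ids: np.ndarray
    times: np.ndarray
    events: np.ndarray
    features: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.feature_names = list(self.feature_names)
        n = len(self.patient_ids)
        if n < 1:
            raise EmptyDatasetError(f"node '{self.node_id}' has no patients")
        if not (len(self.times) == len(self.events) == self.features.shape[0] == n):
            raise DataValidationError(
                f"node '{self.node_id}': inconsistent row counts"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise DataValidationError(
                f"node '{self.node_id}': feature matrix has "
                f"{self.features.shape[1]} columns for {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataValidationError(f"node '{self.node_id}': duplicate feature names")
        if np.any(self.times <= 0):
            bad = int(np.argmax(self.times <= 0))
            raise DataValidationError(
                f"node '{self.node_id}': non-positive time {self.times[bad]} "
                f"for patient '{self.patient_ids[bad]}' (row {bad})"
            )
        if not np.isin(self.events, (0, 1)).all():
            raise DataValidationError(f"node '{self.node_id}': events must be 0/1")
        if not np.isfinite(self.features).all():
            raise DataValidationError(
                f"node '{self.node_id}': non-finite feature values"
            )

    @property
    def n_patients(self) -> int:
        return len(self.times)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "NodeDataset":
        """Row subset (used to carve out the train/test partitions)."""
        idx = np.asarray(indices, dtype=int)
        return NodeDataset(
            node_id=self.node_id,
            patient_ids=self.patient_ids[idx],
            times=self.times[idx],
            events=self.events[idx],
            features=self.features[idx],
            feature_names=self.feature_names,
        )

    def feature_column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"feature '{name}' not in node '{self.node_id}'") from None
        return self.features[:, j]


@dataclass(frozen=True)
class SplitAssignment:
    """Deterministic per-node train/test partition."""

    node_id: str
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    fraction_test: float

    def __post_init__(self):
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise DataValidationError("train and test indices overlap")


def read_node_table(
    path,
    node_id: str,
    schema: dict | None = None,
) -> NodeDataset:
    """Read one institution's CSV into a :class:`NodeDataset`.

    The CSV must carry the id/time/event columns named by ``schema`` (defaults
    in :data:`DEFAULT_SCHEMA`); every remaining column is treated as a numeric
    feature. Rows with missing or non-numeric feature, time or event values
    are dropped and the drop count logged. A non-positive survival time is an
    error (it indicates corrupted follow-up data, not missingness).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype={schema["id"]: str}, float_precision="round_trip")
    for role in ("id", "time", "event"):
        if schema[role] not in df.columns:
            raise SchemaError(
                f"node '{node_id}': required column '{schema[role]}' ({role}) "
                f"missing from {path}"
            )
    mandatory = [schema["id"], schema["time"], schema["event"]]
    feature_cols = [c for c in df.columns if c not in mandatory]

    times = pd.to_numeric(df[schema["time"]], errors="coerce")
    events = pd.to_numeric(df[schema["event"]], errors="coerce")
    feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    usable = times.notna() & events.notna()
    if feature_cols:
        usable &= feats.notna().all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "node '%s': dropped %d row(s) with missing/non-numeric values",
            node_id,
            n_dropped,
        )
    if not usable.any():
        raise EmptyDatasetError(f"node '{node_id}': no usable rows in {path}")

    kept = df.loc[usable]
    t = times[usable].to_numpy(float)
    if np.any(t <= 0):
        bad_pos = int(np.argmax(t <= 0))
        pid = kept[schema["id"]].iloc[bad_pos]
        raise DataValidationError(
            f"node '{node_id}': non-positive time {t[bad_pos]} for patient '{pid}'"
        )
    return NodeDataset(
        node_id=node_id,
        patient_ids=kept[schema["id"]].to_numpy(object),
        times=t,
        events=events[usable].to_numpy(int),
        features=feats.loc[usable].to_numpy(float)
        if feature_cols
        else np.empty((int(usable.sum()), 0)),
        feature_names=feature_cols,
    )


def write_node_table(data: NodeDataset, path, schema: dict | None = None) -> None:
    """Write a dataset back to CSV with 17 significant digits (round-trip safe)."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.DataFrame({schema["id"]: data.patient_ids})
    df[schema["time"]] = data.times
    df[schema["event"]] = data.events
    for j, name in enumerate(data.feature_names):
        df[name] = data.features[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def split_node(data: NodeDataset, fraction_test: float, seed: int) -> SplitAssignment:
    """Randomly partition a node into train/test sets.

    The test size is ``round(fraction_test * n)`` (half away from zero),
    clamped so both sides keep at least one patient. Deterministic for a
    given ``(seed, fraction_test, n)`` via numpy's seeded PCG64 generator.
    """
    if not 0.0 < fraction_test < 1.0:
        raise ParameterError(f"fraction_test must be in (0,1), got {fraction_test}")
    n = data.n_patients
    if n < 2:
        raise SizeError(f"node '{data.node_id}': need at least 2 patients to split")
    n_test = int(np.floor(fraction_test * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitAssignment(
        node_id=data.node_id,
        train_indices=np.sort(perm[n_test:]),
        test_indices=np.sort(perm[:n_test]),
        seed=seed,
        fraction_test=fraction_test,
    )
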