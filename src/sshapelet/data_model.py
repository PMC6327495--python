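"""Core containers and long-format I/O for sparse multi-variate series data.

A *dataset* is a universe of labeled objects (e.g. patients) observed over a
set of features (e.g. laboratory analytes).  Each (object, feature) record is
an ordered, variable-length series of real values; a zero-length record is the
empty record ``∅``, which in this setting is informative rather than noise
(values are missing not at random).  Times are used only to order the values
of a record; sampling irregularity is otherwise ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SparseDataset",
    "SymbolicDataset",
    "FeatureMatrix",
    "read_long_csv",
    "write_long_csv",
    "write_feature_matrix",
    "read_feature_matrix",
    "sparsity_fraction",
]

_EMPTY = np.empty(0, dtype=float)

MEASUREMENT_COLUMNS = ("object_id", "feature_id", "time", "value")
LABEL_COLUMNS = ("object_id", "label")


@dataclass
class SparseDataset:
    """Labeled objects over multi-variate series features.

    Parameters
    ----------
    feature_ids : list of str
        The m feature identifiers.
    object_ids : list of str
        The n object identifiers (order defines row order everywhere).
    records : dict
        Map ``(object_id, feature_id) -> 1-D float array``.  Absent keys and
        zero-length arrays both denote the empty record ``∅``; there is no
        third "NA" state.
    labels : dict
        Map ``object_id -> class label`` (opaque strings; every object must
        have exactly one label).
    """

    feature_ids: list[str]
    object_ids: list[str]
    records: dict[tuple[str, str], np.ndarray]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.feature_ids) < 1:
            raise ValueError("dataset needs at least one feature")
        if len(self.object_ids) < 1:
            raise ValueError("dataset needs at least one object")
        missing = [o for o in self.object_ids if o not in self.labels]
        if missing:
            raise ValueError(f"objects without a label: {missing[:5]}")
        self.records = {
            k: np.asarray(v, dtype=float) for k, v in self.records.items() if len(v) > 0
        }

    # -- basic geometry -------------------------------------------------
    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def classes(self) -> list[str]:
        return sorted({self.labels[o] for o in self.object_ids})

    def record(self, object_id: str, feature_id: str) -> np.ndarray:
        """Return the series for (object, feature); length 0 means ∅."""
        return self.records.get((object_id, feature_id), _EMPTY)

    def is_empty(self, object_id: str, feature_id: str) -> bool:
        return len(self.record(object_id, feature_id)) == 0

    def labels_array(self) -> np.ndarray:
        return np.asarray([self.labels[o] for o in self.object_ids], dtype=object)

    def subset(self, object_ids: Sequence[str]) -> "SparseDataset":
        """Row-subset (and reorder) by object id; features are unchanged."""
        keep = set(object_ids)
        unknown = keep - set(self.object_ids)
        if unknown:
            raise KeyError(f"unknown object ids: {sorted(unknown)[:5]}")
        records = {
            (o, f): v for (o, f), v in self.records.items() if o in keep
        }
        return SparseDataset(
            feature_ids=list(self.feature_ids),
            object_ids=list(object_ids),
            records=records,
            labels={o: self.labels[o] for o in object_ids},
        )


@dataclass
class SymbolicDataset:
    """SAX-discretized counterpart of a :class:`SparseDataset`.

    Records map to symbol strings over an alphabet of size ``alphabet_size``;
    the empty string denotes ``∅``.  The (object, feature) key set equals that
    of the source dataset by construction.
    """

    feature_ids: list[str]
    object_ids: list[str]
    records: dict[tuple[str, str], str]
    labels: dict[str, str]
    alphabet_size: int = 0

    def record(self, object_id: str, feature_id: str) -> str:
        return self.records.get((object_id, feature_id), "")

    def column(self, feature_id: str) -> list[tuple[str, str]]:
        """(symbolic record, label) pairs for one feature, in object order."""
        if feature_id not in self.feature_ids:
            raise KeyError(f"unknown feature id: {feature_id!r}")
        return [
            (self.record(o, feature_id), self.labels[o]) for o in self.object_ids
        ]


@dataclass
class FeatureMatrix:
    """n x m' single-valued output of the learned transform."""

    object_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.object_ids), len(self.feature_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.object_ids)} objects x {len(self.feature_ids)} features"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "object_id", self.object_ids)
        if self.labels:
            df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# long-format I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _numeric_or_fail(df: pd.DataFrame, column: str, path) -> pd.Series:
    parsed = pd.to_numeric(df[column], errors="coerce")
    bad = parsed.isna()
    if bad.any():
        # +2: one for the header row, one for 0- vs 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(
            f"{path}: malformed {column!r} value {df[column].iloc[line - 2]!r} "
            f"on line {line}"
        )
    return parsed


def read_long_csv(measurements_path, labels_path) -> SparseDataset:
    """Read a long-format measurements file plus a labels file.

    The measurements CSV has columns ``object_id, feature_id, time, value``
    (one row per measurement); the labels CSV has ``object_id, label``.  Per
    (object, feature), values sorted ascending by time form the record; ties
    in time keep file order.  Objects present in the labels file but absent
    from the measurements get all-empty records; measured but unlabeled
    objects are an error.
    """
    labels_df = pd.read_csv(labels_path, dtype=str)
    _require_columns(labels_df, LABEL_COLUMNS, labels_path)
    if labels_df["object_id"].duplicated().any():
        dupes = labels_df.loc[labels_df["object_id"].duplicated(), "object_id"]
        raise ValueError(f"{labels_path}: duplicated object ids {list(dupes)[:5]}")
    labels = dict(zip(labels_df["object_id"], labels_df["label"]))
    object_ids = list(labels_df["object_id"])

    try:
        meas = pd.read_csv(
            measurements_path, dtype={"object_id": str, "feature_id": str}
        )
    except pd.errors.EmptyDataError:
        meas = pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))
    _require_columns(meas, MEASUREMENT_COLUMNS, measurements_path)

    records: dict[tuple[str, str], np.ndarray] = {}
    feature_ids: list[str] = []
    if len(meas):
        meas = meas.copy()
        meas["time"] = _numeric_or_fail(meas, "time", measurements_path)
        meas["value"] = _numeric_or_fail(meas, "value", measurements_path)
        unlabeled = sorted(set(meas["object_id"]) - set(labels))
        if unlabeled:
            raise ValueError(
                f"{measurements_path}: objects without labels: {unlabeled[:5]}"
            )
        # stable sort: simultaneous measurements keep file order (documented)
        meas = meas.sort_values("time", kind="stable")
        grouped = meas.groupby(["object_id", "feature_id"], sort=False)["value"]
        records = {key: grp.to_numpy(dtype=float) for key, grp in grouped}
        feature_ids = sorted(meas["feature_id"].unique())
    if not feature_ids:
        feature_ids = ["feature"]  # degenerate all-empty input still needs m >= 1

    return SparseDataset(
        feature_ids=feature_ids,
        object_ids=object_ids,
        records=records,
        labels=labels,
    )


def write_long_csv(dataset: SparseDataset, measurements_path, labels_path) -> None:
    """Write a dataset back to long format (times are 0..d-1 per record)."""
    rows = []
    for o in dataset.object_ids:
        for f in dataset.feature_ids:
            series = dataset.record(o, f)
            for t, v in enumerate(series):
                rows.append((o, f, t, v))
    pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)).to_csv(
        measurements_path, index=False
    )
    pd.DataFrame(
        {"object_id": dataset.object_ids,
         "label": [dataset.labels[o] for o in dataset.object_ids]}
    ).to_csv(labels_path, index=False)


def write_feature_matrix(matrix: FeatureMatrix, path, float_format: str = "%.10g") -> None:
    """Write the transformed matrix as CSV (object_id, features..., label)."""
    if len(matrix.feature_ids) == 0:
        raise ValueError("refusing to write a feature matrix with zero columns")
    if np.isnan(matrix.values).any():
        raise ValueError("feature matrix contains NaN cells")
    try:
        matrix.to_frame().to_csv(path, index=False, float_format=float_format)
    except OSError as exc:  # pragma: no cover - io failure path
        raise OSError(f"failed writing feature matrix to {path}: {exc}") from exc


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, dtype={"object_id": str, "label": str})
    labels = list(df["label"]) if "label" in df.columns else []
    feature_cols = [c for c in df.columns if c not in ("object_id", "label")]
    return FeatureMatrix(
        object_ids=list(df["object_id"]),
        feature_ids=feature_cols,
        values=df[feature_cols].to_numpy(dtype=float),
        labels=labels,
    )


def sparsity_fraction(dataset: SparseDataset, feature_id: str) -> float:
    """Fraction of objects whose record for ``feature_id`` is empty."""
    if feature_id not in dataset.feature_ids:
        raise KeyError(f"unknown feature id: {feature_id!r}")
    empty = sum(dataset.is_empty(o, feature_id) for o in dataset.object_ids)
    return empty / dataset.n_objects
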