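"""The learned mapping from multi-variate objects to single-valued features.

:class:`SequenceShapeletTransform` is a scikit-learn style transformer: fit on
a training :class:`~sshapelet.data_model.SparseDataset`, it retains the
features passing the sparsity filter, discretizes them per alphabet size,
discovers one s-shapelet per retained feature, and learns the empty-record
encoding of the chosen strategy.  ``transform`` then maps any dataset with the
same features to an n x m' real matrix (each cell the distance of the record's
symbolic form to the feature's shapelet; empty records get the learned
encoding).  The ``sl`` baseline strategy learns no shapelets: each cell is the
raw record length, empty records map to 0.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import FeatureMatrix, SparseDataset, sparsity_fraction
from .discovery import (
    SShapelet,
    STRATEGIES,
    column_distances,
    sample_candidates,
    select_shapelet,
)
from .discretization import Alphabet, PAAConfig, discretize_dataset, discretize_series

__all__ = [
    "SequenceShapeletTransform",
    "filter_features",
    "fit_transform_model",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = 1

ALL_STRATEGIES = STRATEGIES + ("sl",)


def filter_features(dataset: SparseDataset, tau_sp: float) -> list[str]:
    """Features with sparsity fraction <= tau_sp and >= 1 non-empty record.

    ``tau_sp`` is the sparsity tolerance: the maximum fraction of empty
    records a feature may contain and still be used for training.  The bound
    is inclusive; a fully empty feature is always dropped.
    """
    if not 0 < tau_sp <= 1:
        raise ValueError("tau_sp must be in (0, 1]")
    kept = []
    for f in dataset.feature_ids:
        frac = sparsity_fraction(dataset, f)
        if frac <= tau_sp and frac < 1.0:
            kept.append(f)
    return kept


class SequenceShapeletTransform(TransformerMixin, BaseEstimator):
    """Shapelet-based single-valued feature transform for sparse series data.

    Parameters
    ----------
    strategy : {"plain", "mc", "lr", "sl"}, default="lr"
        Empty-record handling.  ``plain`` scores an empty record as the
        shapelet length, ``mc`` as the modal training distance, ``lr`` as the
        gain-optimized left/right placement value, and ``sl`` is the
        sequence-length baseline (no shapelets; value = record length, 0 for
        empty).
    alphabet_sizes : sequence of int, default=(2, 3, 5)
        Candidate SAX alphabet sizes; the best per feature is chosen by gain.
    tau_sp : float, default=1.0
        Sparsity tolerance for the training-time feature filter.
    paa_ratio : float, default=1.0
        PAA compression ratio (1.0 keeps raw, variable lengths).
    n_candidates : int, default=50
        Random candidate snippets drawn per (feature, alphabet).
    random_state : int, default=0
        Seed driving all candidate sampling; stored in the serialized model.

    Attributes
    ----------
    feature_ids_ : list of str
        Features retained by the sparsity filter, in dataset order.
    shapelets_ : list of SShapelet or None
        One per retained feature (None for the ``sl`` strategy).
    classes_ : list of str
        Class labels seen during fit.
    n_features_out_ : int
        Number of output columns (= len(feature_ids_)).
    """

    def __init__(self, strategy: str = "lr",
                 alphabet_sizes: Sequence[int] = (2, 3, 5),
                 tau_sp: float = 1.0, paa_ratio: float = 1.0,
                 n_candidates: int = 50, random_state: int = 0):
        self.strategy = strategy
        self.alphabet_sizes = alphabet_sizes
        self.tau_sp = tau_sp
        self.paa_ratio = paa_ratio
        self.n_candidates = n_candidates
        self.random_state = random_state

    # -- fitting --------------------------------------------------------
    def fit(self, X: SparseDataset, y=None) -> "SequenceShapeletTransform":
        if not isinstance(X, SparseDataset):
            raise TypeError("X must be a SparseDataset")
        if self.strategy not in ALL_STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {ALL_STRATEGIES}"
            )
        classes = X.classes
        if len(classes) < 2:
            raise ValueError("training set must contain at least two classes")
        self.classes_ = classes
        self.feature_ids_ = filter_features(X, self.tau_sp)
        if not self.feature_ids_:
            raise ValueError(
                f"no features pass the sparsity filter tau_sp={self.tau_sp}"
            )

        if self.strategy == "sl":
            self.shapelets_ = None
        else:
            paa = PAAConfig(self.paa_ratio)
            alphas = sorted(set(int(a) for a in self.alphabet_sizes))
            symbolic_by_alpha = {
                a: discretize_dataset(X, Alphabet(a), paa) for a in alphas
            }
            rng = np.random.default_rng(self.random_state)
            shapelets: list[SShapelet] = []
            for f in self.feature_ids_:
                candidates_by_alpha = {
                    a: sample_candidates(symbolic_by_alpha[a], f,
                                         self.n_candidates, rng)
                    for a in alphas
                }
                shapelets.append(
                    select_shapelet(symbolic_by_alpha, f,
                                    candidates_by_alpha, self.strategy)
                )
            self.shapelets_ = shapelets
        self.n_features_out_ = len(self.feature_ids_)
        return self

    # -- transforming ---------------------------------------------------
    def transform(self, X: SparseDataset) -> np.ndarray:
        self._check_fitted()
        if not isinstance(X, SparseDataset):
            raise TypeError("X must be a SparseDataset")
        unknown = [f for f in self.feature_ids_ if f not in X.feature_ids]
        if unknown:
            raise KeyError(f"dataset lacks model features: {unknown[:5]}")
        n = X.n_objects
        out = np.empty((n, self.n_features_out_), dtype=float)
        if self.strategy == "sl":
            for j, f in enumerate(self.feature_ids_):
                out[:, j] = [len(X.record(o, f)) for o in X.object_ids]
            return out
        paa = PAAConfig(self.paa_ratio)
        for j, (f, sh) in enumerate(zip(self.feature_ids_, self.shapelets_)):
            alphabet = Alphabet(sh.alphabet_size)
            symbolic = [
                discretize_series(X.record(o, f), alphabet, paa)
                if not X.is_empty(o, f) else ""
                for o in X.object_ids
            ]
            nonempty = [t for t in symbolic if t]
            dists = column_distances(sh.sequence, nonempty) if nonempty else None
            col = np.empty(n, dtype=float)
            it = iter(dists if dists is not None else ())
            for i, t in enumerate(symbolic):
                col[i] = float(next(it)) if t else sh.empty_distance
            out[:, j] = col
        return out

    def transform_matrix(self, X: SparseDataset) -> FeatureMatrix:
        """Transform and wrap the result with ids and labels."""
        values = self.transform(X)
        return FeatureMatrix(
            object_ids=list(X.object_ids),
            feature_ids=list(self.feature_ids_),
            values=values,
            labels=[X.labels[o] for o in X.object_ids],
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        self._check_fitted()
        return np.asarray(self.feature_ids_, dtype=object)

    def _check_fitted(self) -> None:
        if not hasattr(self, "feature_ids_"):
            raise RuntimeError("transformer is not fitted; call fit first")

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        """Serialize the fitted model losslessly (stable key order)."""
        self._check_fitted()
        doc = {
            "version": MODEL_SCHEMA_VERSION,
            "strategy": self.strategy,
            "seed": int(self.random_state),
            "paa_ratio": float(self.paa_ratio),
            "tau_sp": float(self.tau_sp),
            "alphabet_sizes": [int(a) for a in self.alphabet_sizes],
            "n_candidates": int(self.n_candidates),
            "classes": list(self.classes_),
            "features": [
                {
                    "id": f,
                    "shapelet": sh.sequence if sh else None,
                    "alpha": sh.alphabet_size if sh else None,
                    "delta_osp": sh.threshold if sh else None,
                    "gain": sh.gain if sh else None,
                    "empty_encoding": sh.empty_distance if sh else 0.0,
                    "empty_side": sh.empty_side if sh else "n/a",
                }
                for f, sh in zip(
                    self.feature_ids_,
                    self.shapelets_ if self.shapelets_ is not None
                    else [None] * len(self.feature_ids_),
                )
            ],
        }
        return json.dumps(doc, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, document: str) -> "SequenceShapeletTransform":
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed model document: {exc}") from exc
        version = doc.get("version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {version!r} not supported "
                f"(expected {MODEL_SCHEMA_VERSION})"
            )
        est = cls(
            strategy=doc["strategy"],
            alphabet_sizes=tuple(doc["alphabet_sizes"]),
            tau_sp=doc["tau_sp"],
            paa_ratio=doc["paa_ratio"],
            n_candidates=doc["n_candidates"],
            random_state=doc["seed"],
        )
        est.classes_ = list(doc["classes"])
        est.feature_ids_ = [f["id"] for f in doc["features"]]
        if doc["strategy"] == "sl":
            est.shapelets_ = None
        else:
            est.shapelets_ = [
                SShapelet(
                    feature_id=f["id"],
                    sequence=f["shapelet"],
                    alphabet_size=f["alpha"],
                    threshold=f["delta_osp"],
                    gain=f["gain"],
                    strategy=doc["strategy"],
                    empty_distance=f["empty_encoding"],
                    empty_side=f.get("empty_side", "n/a"),
                )
                for f in doc["features"]
            ]
        est.n_features_out_ = len(est.feature_ids_)
        return est


def fit_transform_model(dataset: SparseDataset, **params) -> SequenceShapeletTransform:
    """Thin functional wrapper: fit a transform model on a dataset."""
    return SequenceShapeletTransform(**params).fit(dataset)
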