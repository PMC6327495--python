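"""Cross-validated evaluation of the transform strategies.

Mirrors the study protocol at desk scale: stratified k-fold cross-validation
(default 10 folds), a random forest on the transformed features (100 trees,
information-gain splits, sqrt(m) features per split), AUC scoring,
sparsity-tolerance sweeps, and paired Wilcoxon signed-rank comparison of two
result vectors.  The classifier is pluggable: anything with ``fit`` and
``predict_proba`` works.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data_model import SparseDataset
from .transform import SequenceShapeletTransform

__all__ = ["EvalConfig", "CVResult", "make_classifier", "cross_validate",
           "sparsity_sweep", "paired_comparison", "PairedComparison",
           "DEFAULT_TAU_GRID"]

DEFAULT_TAU_GRID = (0.2, 0.3, 0.5, 0.7, 0.9, 0.95, 1.0)


@dataclass(frozen=True)
class EvalConfig:
    """Protocol knobs shared by the evaluation entry points."""

    n_splits: int = 10
    tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID
    alphabet_sizes: tuple[int, ...] = (2, 3, 5)
    paa_ratio: float = 1.0
    n_candidates: int = 50
    seed: int = 0
    fold_seed: int | None = None  # separate so folds and sampling vary independently

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("need at least 2 folds")
        if any(not 0 < t <= 1 for t in self.tau_grid):
            raise ValueError("tau grid values must be in (0, 1]")


@dataclass
class CVResult:
    strategy: str
    tau_sp: float
    fold_aucs: list[float] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def make_classifier(random_state: int = 0) -> RandomForestClassifier:
    """The default classifier: RF, 100 trees, entropy splits, sqrt features."""
    return RandomForestClassifier(
        n_estimators=100,
        criterion="entropy",
        max_features="sqrt",
        random_state=random_state,
    )


def _auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    if classes.size == 2:
        pos = classes[-1]
        return float(roc_auc_score(y_true == pos, proba[:, -1]))
    return float(
        roc_auc_score(y_true, proba, multi_class="ovr", labels=list(classes))
    )


def cross_validate(dataset: SparseDataset, strategy: str, tau_sp: float = 1.0,
                   config: EvalConfig = EvalConfig(),
                   classifier_factory=make_classifier) -> CVResult:
    """Stratified k-fold AUC for one strategy at one sparsity tolerance.

    Per fold, the transform is fit on the training split only (shapelets,
    modal distances and left/right encodings never see the test fold), both
    splits are transformed, the classifier is trained, and AUC is measured on
    the held-out fold.
    """
    y = dataset.labels_array()
    ids = np.asarray(dataset.object_ids, dtype=object)
    fold_seed = config.seed if config.fold_seed is None else config.fold_seed
    skf = StratifiedKFold(n_splits=config.n_splits, shuffle=True,
                          random_state=fold_seed)
    result = CVResult(strategy=strategy, tau_sp=tau_sp)
    for train_idx, test_idx in skf.split(ids, y):
        train = dataset.subset(list(ids[train_idx]))
        test = dataset.subset(list(ids[test_idx]))
        est = SequenceShapeletTransform(
            strategy=strategy, tau_sp=tau_sp,
            alphabet_sizes=config.alphabet_sizes, paa_ratio=config.paa_ratio,
            n_candidates=config.n_candidates, random_state=config.seed,
        ).fit(train)
        clf = classifier_factory(config.seed)
        clf.fit(est.transform(train), train.labels_array())
        proba = clf.predict_proba(est.transform(test))
        result.fold_aucs.append(
            _auc(test.labels_array(), proba, np.asarray(clf.classes_))
        )
    return result


def sparsity_sweep(dataset: SparseDataset, strategies: tuple[str, ...],
                   config: EvalConfig = EvalConfig(),
                   classifier_factory=make_classifier) -> pd.DataFrame:
    """Grid evaluation over strategies and sparsity tolerances.

    Returns a tidy frame with columns strategy, tau_sp, fold, auc (one row
    per fold), ready for ``pivot_table`` summaries or CSV export.
    """
    rows = []
    for strategy in strategies:
        for tau in config.tau_grid:
            res = cross_validate(dataset, strategy, tau, config,
                                 classifier_factory)
            for k, auc in enumerate(res.fold_aucs):
                rows.append(
                    {"strategy": strategy, "tau_sp": tau, "fold": k, "auc": auc}
                )
    return pd.DataFrame(rows, columns=["strategy", "tau_sp", "fold", "auc"])


@dataclass(frozen=True)
class PairedComparison:
    name_a: str
    name_b: str
    wins_a: int
    wins_b: int
    ties: int
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def summary(self) -> str:
        """Winner with its win count, e.g. ``"lr (10)*"``."""
        if self.wins_a == self.wins_b:
            winner, wins = "tie", self.wins_a
        elif self.wins_a > self.wins_b:
            winner, wins = self.name_a, self.wins_a
        else:
            winner, wins = self.name_b, self.wins_b
        star = "*" if self.significant else ""
        return f"{winner} ({wins}){star}"


def paired_comparison(results_a, results_b, name_a: str = "A", name_b: str = "B",
                      alpha: float = 0.05) -> PairedComparison:
    """Win counts and a two-sided Wilcoxon signed-rank test on paired AUCs.

    Identical vectors (all pairs tied) yield p = 1.0, i.e. no rejection.
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired result vectors must be 1-D and equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for a meaningful comparison")
    diffs = a - b
    wins_a = int((diffs > 0).sum())
    wins_b = int((diffs < 0).sum())
    ties = int((diffs == 0).sum())
    if np.all(diffs == 0):
        statistic, p_value = 0.0, 1.0
    else:
        statistic, p_value = wilcoxon(a, b, alternative="two-sided")
    return PairedComparison(
        name_a=name_a, name_b=name_b, wins_a=wins_a, wins_b=wins_b, ties=ties,
        statistic=float(statistic), p_value=float(p_value), alpha=alpha,
    )
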