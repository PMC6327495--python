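"""Sequence-shapelet discovery on symbolic columns.

A *sequence shapelet* (s-shapelet) for a feature is the candidate subsequence
whose best distance threshold splits the training labels with maximum
information gain.  Candidates are random snippets of observed symbolic
records; the distance between a candidate ``s`` and a record is the minimum
edit distance between ``s`` and any contiguous window of the record of length
``|s|`` (full edit distance when the record is shorter).  Empty records are
handled by one of three strategies:

plain
    ``Dist(s, ∅) = |s|``; empty records compete in the threshold search like
    any other.
mc
    Empty records are excluded from the threshold search; at transform time
    they receive the modal training distance.
lr
    At every threshold, both bulk placements of the empty records — all on the
    left of the split (``Dist(s, ∅) = 0``) or all on the right (``Dist(s, ∅) =``
    max observed distance) — are evaluated and the better one kept.

All tie-breaks are deterministic: equal gain among thresholds -> smallest
threshold; among placements -> left; among candidates -> shorter sequence,
then lexicographic; among alphabets -> smaller alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import xlogy

from .data_model import SymbolicDataset

__all__ = [
    "Candidate",
    "SplitEvaluation",
    "SShapelet",
    "STRATEGIES",
    "entropy",
    "partition_gain",
    "subsequence_distance",
    "column_distances",
    "sample_candidates",
    "optimal_split",
    "select_shapelet",
]

STRATEGIES = ("plain", "mc", "lr")

_LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A contiguous snippet of an observed symbolic record."""

    sequence: str
    alphabet_size: int
    feature_id: str
    object_id: str
    start: int


@dataclass(frozen=True)
class SplitEvaluation:
    """Outcome of the optimal-split search for one candidate on one column."""

    threshold: int          # delta_osp
    gain: float
    empty_side: str         # "left" | "right" | "n/a"
    empty_distance: float   # Dist(s, ∅) implied by the strategy


@dataclass(frozen=True)
class SShapelet:
    """The selected shapelet for a feature, with its learned ∅ encoding."""

    feature_id: str
    sequence: str
    alphabet_size: int
    threshold: int
    gain: float
    strategy: str
    empty_distance: float
    empty_side: str = "n/a"


# ---------------------------------------------------------------------------
# entropy and gain
# ---------------------------------------------------------------------------

def _entropy_counts(counts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy (bits) of class-count vectors along ``axis``."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=axis, keepdims=True)
    p = counts / np.where(total > 0, total, 1.0)
    return -xlogy(p, p).sum(axis=axis) / _LOG2


def entropy(labels: Sequence) -> float:
    """Entropy (base 2) of a multiset of class labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("entropy of an empty label multiset is undefined")
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    return float(_entropy_counts(counts))


def partition_gain(parent: Sequence, parts: Iterable[Sequence]) -> float:
    """Information gain of splitting ``parent`` into ``parts``.

    ``parts`` must disjointly partition the parent multiset.
    """
    parent = list(parent)
    parts = [list(p) for p in parts]
    merged = sorted(map(str, (x for p in parts for x in p)))
    if merged != sorted(map(str, parent)):
        raise ValueError("parts do not partition the parent multiset")
    h_parent = entropy(parent)
    weighted = sum(
        len(p) / len(parent) * entropy(p) for p in parts if len(p) > 0
    )
    return h_parent - weighted


# ---------------------------------------------------------------------------
# subsequence edit distance
# ---------------------------------------------------------------------------

def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _levenshtein_block(s_codes: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Edit distance between ``s_codes`` and every row of ``block``.

    Vectorized over rows.  The within-row dependency of the standard DP (the
    insertion term) is resolved with a running prefix minimum:
    ``cur[j] = j + cummin(full - j)[j]`` where ``full`` stacks the boundary
    value and the deletion/substitution minima.
    """
    n_rows, width = block.shape
    k = s_codes.size
    j_idx = np.arange(width + 1)
    prev = np.broadcast_to(j_idx, (n_rows, width + 1)).astype(np.int64).copy()
    boundary = np.empty((n_rows, 1), dtype=np.int64)
    for i in range(1, k + 1):
        neq = block != s_codes[i - 1]
        base = np.minimum(prev[:, 1:] + 1, prev[:, :-1] + neq)
        boundary.fill(i)
        full = np.concatenate([boundary, base], axis=1)
        prev = j_idx + np.minimum.accumulate(full - j_idx, axis=1)
    return prev[:, -1]


def _distance_pair(s_codes: np.ndarray, t_codes: np.ndarray) -> int:
    if t_codes.size >= s_codes.size:
        windows = np.lib.stride_tricks.sliding_window_view(t_codes, s_codes.size)
        return int(_levenshtein_block(s_codes, windows).min())
    return int(_levenshtein_block(s_codes, t_codes[None, :])[0])


def subsequence_distance(s: str, target: str, *, empty_distance: float | None = None) -> int:
    """Distance from ``s`` to its best-matching window of ``target``.

    For a non-empty target at least as long as ``s``, the minimum edit
    distance over all contiguous windows of length ``|s|``; for a shorter
    target, the full edit distance.  For the empty record the caller's
    strategy supplies the value via ``empty_distance``.
    """
    if not s:
        raise ValueError("candidate subsequence must be non-empty")
    if not target:
        if empty_distance is None:
            raise ValueError(
                "distance to the empty record is strategy-defined; "
                "pass empty_distance"
            )
        return int(empty_distance)
    return _distance_pair(_encode(s), _encode(target))


class _ColumnIndex:
    """Pre-encoded non-empty records of one column, with cached window blocks.

    Evaluating many candidates against the same column re-uses the encoded
    records and, per candidate length k, the stacked window block; only the
    DP itself runs per candidate.
    """

    def __init__(self, sequences: Sequence[str]):
        if any(not t for t in sequences):
            raise ValueError("column index only accepts non-empty records")
        self.codes = [_encode(t) for t in sequences]
        self.lengths = np.asarray([c.size for c in self.codes])
        self._cache: dict[int, tuple] = {}

    def _layout(self, k: int):
        if k not in self._cache:
            long_idx, bounds, blocks, pos = [], [], [], 0
            short_by_len: dict[int, list[int]] = {}
            for i, c in enumerate(self.codes):
                if c.size >= k:
                    w = np.lib.stride_tricks.sliding_window_view(c, k)
                    blocks.append(w)
                    long_idx.append(i)
                    bounds.append(pos)
                    pos += w.shape[0]
                else:
                    short_by_len.setdefault(c.size, []).append(i)
            block = np.concatenate(blocks, axis=0) if blocks else None
            shorts = [
                (np.asarray(idxs), np.stack([self.codes[i] for i in idxs]))
                for idxs in short_by_len.values()
            ]
            self._cache[k] = (
                np.asarray(long_idx), np.asarray(bounds), block, shorts
            )
        return self._cache[k]

    def distances(self, s: str) -> np.ndarray:
        s_codes = _encode(s)
        long_idx, bounds, block, shorts = self._layout(s_codes.size)
        out = np.empty(self.lengths.size, dtype=np.int64)
        if block is not None:
            mins = np.minimum.reduceat(_levenshtein_block(s_codes, block), bounds)
            out[long_idx] = mins
        for idxs, short_block in shorts:
            out[idxs] = _levenshtein_block(s_codes, short_block)
        return out


def column_distances(s: str, sequences: Sequence[str]) -> np.ndarray:
    """Distances from ``s`` to each non-empty sequence, batched.

    Windows from all records long enough are stacked into one block so the
    DP runs once; shorter records are batched by length.
    """
    if not s:
        raise ValueError("candidate subsequence must be non-empty")
    return _ColumnIndex(sequences).distances(s)


# ---------------------------------------------------------------------------
# candidate sampling
# ---------------------------------------------------------------------------

def sample_candidates(symbolic: SymbolicDataset, feature_id: str, count: int,
                      rng: np.random.Generator | int) -> list[Candidate]:
    """Randomly sample candidate snippets from a feature's non-empty records.

    Each draw picks a length uniformly in [1, l_max] (l_max = longest record),
    a record uniformly among those long enough, and a start offset uniformly.
    When ``count`` meets or exceeds the number of distinct (record, start,
    length) positions, all positions are enumerated instead.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    eligible = [
        (o, symbolic.record(o, feature_id))
        for o in symbolic.object_ids
        if symbolic.record(o, feature_id)
    ]
    if not eligible:
        raise ValueError(f"feature {feature_id!r} has no non-empty records")
    alpha = symbolic.alphabet_size
    lengths = np.asarray([len(t) for _, t in eligible])
    l_max = int(lengths.max())
    total_positions = int((lengths * (lengths + 1) // 2).sum())

    if count >= total_positions:
        return [
            Candidate(t[start:start + size], alpha, feature_id, o, start)
            for o, t in eligible
            for size in range(1, len(t) + 1)
            for start in range(len(t) - size + 1)
        ]

    out: list[Candidate] = []
    order = np.argsort(lengths, kind="stable")
    sorted_lengths = lengths[order]
    for _ in range(count):
        size = int(rng.integers(1, l_max + 1))
        first = int(np.searchsorted(sorted_lengths, size, side="left"))
        pick = int(order[int(rng.integers(first, len(eligible)))])
        o, t = eligible[pick]
        start = int(rng.integers(0, len(t) - size + 1))
        out.append(Candidate(t[start:start + size], alpha, feature_id, o, start))
    return out


# ---------------------------------------------------------------------------
# optimal split search
# ---------------------------------------------------------------------------

def _threshold_grid(dists: np.ndarray) -> np.ndarray:
    uniq = np.unique(dists)
    return np.concatenate([uniq, [uniq[-1] + 1]])


def _split_gains(dists: np.ndarray, y_codes: np.ndarray, n_classes: int,
                 thresholds: np.ndarray,
                 extra_left: np.ndarray | None = None,
                 extra_right: np.ndarray | None = None,
                 parent_counts: np.ndarray | None = None) -> np.ndarray:
    """Gain of the split ``Dist < delta`` for every threshold, vectorized.

    ``extra_left``/``extra_right`` are class-count vectors force-assigned to
    one side at every threshold (the lr bulk placements of ∅ records).
    """
    order = np.argsort(dists, kind="stable")
    sorted_d = dists[order]
    onehot = np.zeros((dists.size, n_classes))
    onehot[np.arange(dists.size), y_codes[order]] = 1.0
    cum = np.vstack([np.zeros(n_classes), np.cumsum(onehot, axis=0)])

    n_left = np.searchsorted(sorted_d, thresholds, side="left")
    left = cum[n_left]
    right = cum[-1] - left
    if extra_left is not None:
        left = left + extra_left
    if extra_right is not None:
        right = right + extra_right
    if parent_counts is None:
        parent_counts = left[0] + right[0]
    n_total = parent_counts.sum()
    h_parent = _entropy_counts(parent_counts)
    weighted = (
        left.sum(axis=1) * _entropy_counts(left, axis=1)
        + right.sum(axis=1) * _entropy_counts(right, axis=1)
    ) / n_total
    return h_parent - weighted


# gains closer than this are ties (float noise between mathematically equal
# partitions); scans keep the earliest, making tie-breaks deterministic
GAIN_TIE_TOL = 1e-12


def _best_by_scan(thresholds: np.ndarray, gains: np.ndarray) -> tuple[int, float]:
    """First maximum in threshold order -> smallest-delta tie-break."""
    best_i = 0
    for i in range(1, gains.size):
        if gains[i] > gains[best_i] + GAIN_TIE_TOL:
            best_i = i
    return int(thresholds[best_i]), float(gains[best_i])


def _modal_distance(dists: np.ndarray) -> int:
    values, counts = np.unique(dists, return_counts=True)
    return int(values[np.argmax(counts)])  # argmax -> smallest value on ties


def _split_from_distances(s_length: int, d_ne: np.ndarray, nonempty: np.ndarray,
                          y_codes: np.ndarray, n_classes: int,
                          strategy: str) -> SplitEvaluation:
    """Threshold search given precomputed non-empty distances."""
    y_ne = y_codes[nonempty]
    n_empty = int((~nonempty).sum())

    if strategy == "plain":
        dists = np.empty(nonempty.size, dtype=np.int64)
        dists[nonempty] = d_ne
        dists[~nonempty] = s_length
        thresholds = _threshold_grid(dists)
        gains = _split_gains(dists, y_codes, n_classes, thresholds)
        delta, gain = _best_by_scan(thresholds, gains)
        return SplitEvaluation(delta, gain, "n/a", float(s_length))

    if strategy == "mc":
        # ∅ records are excluded from the threshold search entirely
        thresholds = _threshold_grid(d_ne)
        gains = _split_gains(d_ne, y_ne, n_classes, thresholds)
        delta, gain = _best_by_scan(thresholds, gains)
        return SplitEvaluation(delta, gain, "n/a", float(_modal_distance(d_ne)))

    # lr: both bulk placements of the ∅ records at every threshold
    empty_counts = np.zeros(n_classes)
    if n_empty:
        np.add.at(empty_counts, y_codes[~nonempty], 1.0)
    thresholds = _threshold_grid(d_ne)
    parent_counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    gains_left = _split_gains(d_ne, y_ne, n_classes, thresholds,
                              extra_left=empty_counts, parent_counts=parent_counts)
    gains_right = _split_gains(d_ne, y_ne, n_classes, thresholds,
                               extra_right=empty_counts, parent_counts=parent_counts)
    max_observed = int(d_ne.max())
    best = (int(thresholds[0]), float(gains_left[0]), "left")
    for i in range(thresholds.size):  # delta-major scan; left before right
        if gains_left[i] > best[1] + GAIN_TIE_TOL:
            best = (int(thresholds[i]), float(gains_left[i]), "left")
        if gains_right[i] > best[1] + GAIN_TIE_TOL:
            best = (int(thresholds[i]), float(gains_right[i]), "right")
    delta, gain, side = best
    empty_distance = 0.0 if side == "left" else float(max_observed)
    return SplitEvaluation(delta, gain, side, empty_distance)


def _column_arrays(column: Sequence[tuple[str, str]]):
    seqs = [t for t, _ in column]
    labels = np.asarray([y for _, y in column], dtype=object)
    classes, y_codes = np.unique(labels, return_inverse=True)
    nonempty = np.asarray([bool(t) for t in seqs])
    return seqs, y_codes, classes.size, nonempty


def optimal_split(candidate: "Candidate | str",
                  column: Sequence[tuple[str, str]],
                  strategy: str = "plain") -> SplitEvaluation:
    """Best distance threshold (and gain) for a candidate on one column.

    ``column`` is a list of (symbolic record or empty string, label) pairs.
    Candidate thresholds are all distinct observed distances plus max + 1;
    records go left when their distance is strictly below the threshold.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    s = candidate.sequence if isinstance(candidate, Candidate) else candidate
    if not s:
        raise ValueError("candidate sequence must be non-empty")
    if not column:
        raise ValueError("column must be non-empty")
    seqs, y_codes, n_classes, nonempty = _column_arrays(column)
    if not nonempty.any():
        raise ValueError("column has no non-empty records to split on")
    d_ne = column_distances(s, [t for t in seqs if t])
    return _split_from_distances(len(s), d_ne, nonempty, y_codes, n_classes,
                                 strategy)


# ---------------------------------------------------------------------------
# shapelet selection
# ---------------------------------------------------------------------------

def select_shapelet(symbolic_by_alpha: Mapping[int, SymbolicDataset],
                    feature_id: str,
                    candidates_by_alpha: Mapping[int, Sequence[Candidate]],
                    strategy: str = "plain") -> SShapelet:
    """Best candidate per alphabet by gain, then best alphabet by gain.

    Ties: among candidates, shorter sequence then lexicographic; among
    alphabets, smaller size.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    best: SShapelet | None = None
    for alpha in sorted(symbolic_by_alpha):
        column = symbolic_by_alpha[alpha].column(feature_id)
        pool = candidates_by_alpha.get(alpha, ())
        if not pool:
            continue
        seqs, y_codes, n_classes, nonempty = _column_arrays(column)
        if not nonempty.any():
            raise ValueError("column has no non-empty records to split on")
        index = _ColumnIndex([t for t in seqs if t])
        # deduplicate by sequence; sort so the scan's strict > implements
        # the shorter-then-lexicographic tie-break
        seen: dict[str, Candidate] = {}
        for cand in pool:
            seen.setdefault(cand.sequence, cand)
        ordered = sorted(seen.values(), key=lambda c: (len(c.sequence), c.sequence))
        alpha_best: tuple[Candidate, SplitEvaluation] | None = None
        for cand in ordered:
            ev = _split_from_distances(
                len(cand.sequence), index.distances(cand.sequence),
                nonempty, y_codes, n_classes, strategy,
            )
            if alpha_best is None or ev.gain > alpha_best[1].gain + GAIN_TIE_TOL:
                alpha_best = (cand, ev)
        if alpha_best is None:
            continue
        cand, ev = alpha_best
        if best is None or ev.gain > best.gain + GAIN_TIE_TOL:
            best = SShapelet(
                feature_id=feature_id,
                sequence=cand.sequence,
                alphabet_size=alpha,
                threshold=ev.threshold,
                gain=ev.gain,
                strategy=strategy,
                empty_distance=ev.empty_distance,
                empty_side=ev.empty_side,
            )
    if best is None:
        raise ValueError(f"no candidates available for feature {feature_id!r}")
    return best
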