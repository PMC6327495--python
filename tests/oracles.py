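"""Independent brute-force oracles used only by the tests.

Pure-Python, written directly from the definitions: classic Levenshtein DP,
minimum over equal-length windows, and exhaustive threshold/placement search
for the optimal split.  Deliberately naive and kept free of any code from the
package under test.
"""

from __future__ import annotations

import math


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_subsequence_distance(s: str, target: str) -> int:
    """Min edit distance of s to any |s|-length window (full DP if shorter)."""
    if len(target) >= len(s):
        return min(
            levenshtein(s, target[i:i + len(s)])
            for i in range(len(target) - len(s) + 1)
        )
    return levenshtein(s, target)


def _entropy(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    h = 0.0
    for y in set(labels):
        p = labels.count(y) / n
        h -= p * math.log2(p)
    return h


def _gain(parent, left, right) -> float:
    n = len(parent)
    return _entropy(parent) - (
        len(left) / n * _entropy(left) + len(right) / n * _entropy(right)
    )


TIE_TOL = 1e-12


def exhaustive_optimal_split(s: str, column, strategy: str):
    """Exhaustive search over all thresholds (and ∅ placements for lr).

    ``column`` is a list of (symbolic record or "", label) pairs.  Returns
    (threshold, gain, empty_side, empty_distance) with the documented
    tie-breaks: smallest threshold first, then left placement.
    """
    nonempty = [(t, y) for t, y in column if t]
    empties = [(t, y) for t, y in column if not t]
    d_ne = [brute_subsequence_distance(s, t) for t, _ in nonempty]
    y_ne = [y for _, y in nonempty]

    def grid(dists):
        return sorted(set(dists)) + [max(dists) + 1]

    if strategy == "plain":
        dists = d_ne + [len(s)] * len(empties)
        ys = y_ne + [y for _, y in empties]
        best = None
        for delta in grid(dists):
            left = [y for d, y in zip(dists, ys) if d < delta]
            right = [y for d, y in zip(dists, ys) if d >= delta]
            g = _gain(ys, left, right)
            if best is None or g > best[1] + TIE_TOL:
                best = (delta, g)
        return best[0], best[1], "n/a", float(len(s))

    if strategy == "mc":
        best = None
        for delta in grid(d_ne):
            left = [y for d, y in zip(d_ne, y_ne) if d < delta]
            right = [y for d, y in zip(d_ne, y_ne) if d >= delta]
            g = _gain(y_ne, left, right)
            if best is None or g > best[1] + TIE_TOL:
                best = (delta, g)
        counts = {}
        for d in d_ne:
            counts[d] = counts.get(d, 0) + 1
        top = max(counts.values())
        modal = min(d for d, c in counts.items() if c == top)
        return best[0], best[1], "n/a", float(modal)

    assert strategy == "lr"
    parent = [y for _, y in column]
    y_empty = [y for _, y in empties]
    max_obs = max(d_ne)
    best = None
    for delta in grid(d_ne):
        for side in ("left", "right"):
            left = [y for d, y in zip(d_ne, y_ne) if d < delta]
            right = [y for d, y in zip(d_ne, y_ne) if d >= delta]
            if side == "left":
                left = left + y_empty
            else:
                right = right + y_empty
            g = _gain(parent, left, right)
            if best is None or g > best[1] + TIE_TOL:
                best = (delta, g, side)
    delta, g, side = best
    return delta, g, side, (0.0 if side == "left" else float(max_obs))
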