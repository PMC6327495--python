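"""SAX discretization of real-valued series (z-norm -> PAA -> symbols).

Each non-empty record is z-normalized (population standard deviation),
optionally length-reduced by piecewise aggregate approximation (PAA), and then
mapped to a string over an alphabet whose breakpoints cut the standard normal
density into equiprobable regions.  Empty records stay empty.  Discretization
of a record depends only on that record.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.stats import norm

from .data_model import SparseDataset, SymbolicDataset

__all__ = ["Alphabet", "PAAConfig", "znormalize", "paa", "sax",
           "discretize_series", "discretize_dataset"]

_SYMBOLS = string.ascii_lowercase


@dataclass(frozen=True)
class Alphabet:
    """SAX alphabet of ``size`` symbols with Gaussian-equiprobable breakpoints.

    The size-1 breakpoints split N(0,1) into ``size`` regions of probability
    1/size each; for size 2 the single breakpoint is 0 (below vs above the
    mean).  Values exactly on a breakpoint map to the upper region.
    """

    size: int

    def __post_init__(self) -> None:
        if not 2 <= self.size <= len(_SYMBOLS):
            raise ValueError(f"alphabet size must be in [2, {len(_SYMBOLS)}]")

    @property
    def symbols(self) -> str:
        return _SYMBOLS[: self.size]

    @cached_property
    def breakpoints(self) -> np.ndarray:
        return norm.ppf(np.arange(1, self.size) / self.size)


@dataclass(frozen=True)
class PAAConfig:
    """PAA compression ratio r in (0, 1]; target length is ceil(r * d).

    r = 1 disables PAA (symbolic records keep the raw, variable lengths).
    """

    ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.ratio <= 1:
            raise ValueError("PAA ratio must be in (0, 1]")

    def target_length(self, d: int) -> int:
        return max(1, math.ceil(self.ratio * d))


def znormalize(series: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the population standard deviation.

    A zero-variance series maps to all zeros (its mean-centered value) so that
    constant records — legitimate in laboratory data — survive downstream.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot z-normalize an empty series")
    sd = x.std()  # population (1/n) convention
    centered = x - x.mean()
    return centered / sd if sd > 0 else centered


def paa(series: np.ndarray, config: PAAConfig) -> np.ndarray:
    """Piecewise aggregate approximation to length w = ceil(r * d).

    Each output value is the mean of one of w equal-width partitions of the
    index range; when w divides d the partitions are contiguous blocks of d/w
    points, and fractional boundaries assign each point to the partition whose
    real-valued interval holds its index.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot apply PAA to an empty series")
    d = x.size
    w = config.target_length(d)
    if w == d:
        return x.copy()
    part = (np.arange(d) * w) // d  # index j falls in partition floor(j*w/d)
    sums = np.bincount(part, weights=x, minlength=w)
    counts = np.bincount(part, minlength=w)
    return sums / counts


def sax(series: np.ndarray, alphabet: Alphabet) -> str:
    """Map a (normalized, summarized) series to its SAX symbol string."""
    x = np.asarray(series, dtype=float)
    # side="right": a value equal to a breakpoint belongs to the upper region
    idx = np.searchsorted(alphabet.breakpoints, x, side="right")
    syms = alphabet.symbols
    return "".join(syms[i] for i in idx)


def discretize_series(series: np.ndarray, alphabet: Alphabet,
                      config: PAAConfig = PAAConfig()) -> str:
    return sax(paa(znormalize(series), config), alphabet)


def discretize_dataset(dataset: SparseDataset, alphabet: Alphabet,
                       config: PAAConfig = PAAConfig()) -> SymbolicDataset:
    """Discretize every non-empty record; empty records stay ``∅``."""
    records = {
        key: discretize_series(series, alphabet, config)
        for key, series in dataset.records.items()
    }
    return SymbolicDataset(
        feature_ids=list(dataset.feature_ids),
        object_ids=list(dataset.object_ids),
        records=records,
        labels=dict(dataset.labels),
        alphabet_size=alphabet.size,
    )
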