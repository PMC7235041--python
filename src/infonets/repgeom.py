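"""Core representational-geometry primitives.

An :class:`ItemDM` is the universal currency of the pipeline: the condensed
(upper-triangle, row-major) vector of pairwise dissimilarities between the
item-level response patterns at some location.  Dissimilarity is correlation
distance, ``1 - Pearson r``, so entries lie in ``[0, 2]``.

Group statistics follow the standard variance-stabilized route: correlations
are Fisher z-transformed (``arctanh``) before averaging or t-testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform

from .exceptions import (
    DataError,
    DegenerateDMError,
    DegeneratePatternError,
    DegenerateSampleError,
    InvalidParameterError,
)

__all__ = [
    "ItemDM",
    "PatternMatrix",
    "TestResult",
    "compute_item_dm",
    "fisher_z",
    "normalized_correlation",
    "one_sample_t",
    "normalize_condensed",
]

DEFAULT_CLIP_EPS = 1e-7


def n_pairs(n_items: int) -> int:
    return n_items * (n_items - 1) // 2


@dataclass(frozen=True)
class ItemDM:
    """Condensed vector of pairwise dissimilarities over an ordered item set."""

    condensed: np.ndarray
    item_ids: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.condensed, dtype=np.float64)
        object.__setattr__(self, "condensed", c)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if c.ndim != 1:
            raise DataError("condensed DM must be one-dimensional")
        if len(c) != n_pairs(len(self.item_ids)):
            raise DataError(
                f"condensed length {len(c)} does not match "
                f"{len(self.item_ids)} items"
            )
        if not np.all(np.isfinite(c)):
            raise DataError("condensed DM entries must be finite")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def to_square(self) -> np.ndarray:
        return squareform(self.condensed)

    @classmethod
    def from_square(cls, square: np.ndarray, item_ids) -> "ItemDM":
        square = np.asarray(square, dtype=np.float64)
        if not np.allclose(square, square.T):
            raise DataError("square DM must be symmetric")
        return cls(condensed=squareform(square, checks=False), item_ids=tuple(item_ids))


@dataclass(frozen=True)
class PatternMatrix:
    """Per-item feature vectors (beta-like pattern estimates).

    ``features`` has shape ``(n_items, n_features)`` with ``n_features >= 2``.
    """

    item_ids: tuple
    features: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if f.ndim != 2 or f.shape[0] != len(self.item_ids):
            raise DataError("features must be (n_items, n_features)")
        if f.shape[1] < 2:
            raise DataError("each item needs at least 2 feature values")


@dataclass(frozen=True)
class TestResult:
    """One-sample t-test result against zero."""

    statistic: float
    df: int
    p: float
    mean: float


def compute_item_dm(patterns: PatternMatrix) -> ItemDM:
    """Correlation-distance DM: entry (i, j) = 1 - Pearson r of the items'
    feature vectors.

    Raises
    ------
    DegeneratePatternError
        If any item's feature vector has zero variance (the caller excludes
        such searchlight nodes from the map).
    """
    x = patterns.features
    if x.shape[0] < 2:
        raise DataError("need at least 2 items to form a DM")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    if np.any(norms == 0.0):
        bad = [patterns.item_ids[i] for i in np.flatnonzero(norms == 0.0)]
        raise DegeneratePatternError(f"zero-variance pattern for item(s) {bad}")
    xn = xc / norms[:, None]
    corr = np.clip(xn @ xn.T, -1.0, 1.0)
    return ItemDM(condensed=squareform(1.0 - corr, checks=False), item_ids=patterns.item_ids)


def fisher_z(r, clip_eps: float = DEFAULT_CLIP_EPS):
    """Fisher z-transform ``arctanh(r)`` with clipping away from the poles.

    Accepts scalars or arrays; raises on values outside ``[-1, 1]``.
    """
    r = np.asarray(r, dtype=np.float64)
    if clip_eps <= 0:
        raise InvalidParameterError("clip_eps must be positive")
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise InvalidParameterError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -1.0 + clip_eps, 1.0 - clip_eps))
    return float(z) if z.ndim == 0 else z


def normalize_condensed(condensed: np.ndarray) -> np.ndarray:
    """Mean-center and scale a condensed DM vector to unit norm."""
    c = np.asarray(condensed, dtype=np.float64)
    c = c - c.mean()
    norm = np.linalg.norm(c)
    if norm == 0.0:
        raise DegenerateDMError("constant condensed DM cannot be normalized")
    return c / norm


def normalized_correlation(dm_a: ItemDM, dm_b: ItemDM) -> float:
    """Dot product of the two mean-centered, unit-norm condensed DMs.

    Equals the Pearson correlation of the two condensed vectors; requires
    identical item sets in identical order.
    """
    if dm_a.item_ids != dm_b.item_ids:
        raise DataError("DMs must share the same items in the same order")
    r = float(np.dot(normalize_condensed(dm_a.condensed), normalize_condensed(dm_b.condensed)))
    return float(np.clip(r, -1.0, 1.0))


def one_sample_t(values) -> TestResult:
    """Two-sided one-sample t-test of ``values`` against zero."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) < 2:
        raise DataError("need at least 2 values for a t-test")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSampleError("zero sample variance: t statistic undefined")
    n = len(v)
    mean = v.mean()
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(statistic=float(t), df=n - 1, p=float(p), mean=float(mean))
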