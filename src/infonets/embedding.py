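"""Item-space visualization: nonmetric MDS and concentration ellipsoids."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.manifold import MDS

from .exceptions import DataError, DegenerateDMError, InvalidParameterError
from .repgeom import ItemDM

__all__ = [
    "Embedding3D",
    "ConcentrationEllipsoid",
    "nmds_embed",
    "concentration_ellipsoid",
    "ellipsoid_from_moments",
]


@dataclass
class Embedding3D:
    """Best-of-n-starts nonmetric MDS embedding of an item DM."""

    item_ids: tuple
    coords: np.ndarray       # (n_items, dims)
    stress: float            # Kruskal stress-1 in [0, 1]
    n_starts: int
    seed: int


@dataclass
class ConcentrationEllipsoid:
    """Ellipsoid containing a stated probability mass of a trivariate normal."""

    category: object
    center: np.ndarray
    axes: np.ndarray              # orthonormal eigenvectors as columns
    semi_axis_lengths: np.ndarray
    probability: float
    degenerate_axes: np.ndarray   # True where the covariance is rank-deficient

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test via the Mahalanobis quadratic form."""
        pts = np.atleast_2d(points) - self.center
        # (x-c)' V diag(1/len^2) V' (x-c) <= 1
        proj = pts @ self.axes
        lens = np.where(self.degenerate_axes, np.inf, self.semi_axis_lengths)
        return np.sum((proj / lens) ** 2, axis=1) <= 1.0


def nmds_embed(dm: ItemDM, dims: int = 3, n_starts: int = 8, seed: int = 0) -> Embedding3D:
    """Nonmetric (monotone-regression) MDS; best stress over random starts.

    Stress is the normalized Kruskal stress-1, in [0, 1].
    """
    if np.allclose(dm.condensed, 0.0):
        raise DegenerateDMError("all-zero DM cannot be embedded")
    if dims < 1 or n_starts < 1:
        raise InvalidParameterError("dims and n_starts must be positive")
    mds = MDS(
        n_components=dims,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_starts,
        max_iter=2000,
        eps=1e-12,
        random_state=int(seed),
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = mds.fit_transform(dm.to_square())
    return Embedding3D(
        item_ids=dm.item_ids,
        coords=coords,
        stress=float(mds.stress_),
        n_starts=int(n_starts),
        seed=int(seed),
    )


def concentration_ellipsoid(
    points: np.ndarray, probability: float = 0.95, category=None
) -> ConcentrationEllipsoid:
    """Concentration ellipsoid of 3-D points at the given probability.

    Center is the mean; axes are covariance eigenvectors; semi-axis lengths
    are ``sqrt(eigenvalue * chi2.ppf(probability, df=3))``, so a draw from
    the fitted trivariate normal falls inside with the stated probability.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DataError("points must be (n, 3)")
    if pts.shape[0] < 4:
        raise DataError("need at least 4 points for a 3-D ellipsoid")
    if not (0.0 < probability < 1.0):
        raise InvalidParameterError("probability must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    tol = max(eigvals.max(), 0.0) * 1e-10
    degenerate = eigvals <= tol
    if degenerate.any():
        warnings.warn("rank-deficient covariance: degenerate ellipsoid axis", stacklevel=2)
    q = stats.chi2.ppf(probability, df=3)
    lengths = np.sqrt(np.clip(eigvals, 0.0, None) * q)
    return ConcentrationEllipsoid(
        category=category,
        center=center,
        axes=eigvecs,
        semi_axis_lengths=lengths,
        probability=float(probability),
        degenerate_axes=degenerate,
    )


def ellipsoid_from_moments(
    mean: np.ndarray, cov: np.ndarray, probability: float = 0.95, category=None
) -> ConcentrationEllipsoid:
    """Concentration ellipsoid from known (population) mean and covariance."""
    mean = np.asarray(mean, dtype=np.float64)
    cov = np.asarray(cov, dtype=np.float64)
    if mean.shape != (3,) or cov.shape != (3, 3):
        raise DataError("mean must be (3,) and cov (3, 3)")
    if not (0.0 < probability < 1.0):
        raise InvalidParameterError("probability must be in (0, 1)")
    eigvals, eigvecs = np.linalg.eigh((cov + cov.T) / 2)
    tol = max(eigvals.max(), 0.0) * 1e-10
    degenerate = eigvals <= tol
    q = stats.chi2.ppf(probability, df=3)
    return ConcentrationEllipsoid(
        category=category,
        center=mean,
        axes=eigvecs,
        semi_axis_lengths=np.sqrt(np.clip(eigvals, 0.0, None) * q),
        probability=float(probability),
        degenerate_axes=degenerate,
    )
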