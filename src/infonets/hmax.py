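"""HMAX S1/C1 forward encoding of stimulus images.

The visual-similarity control model encodes each grayscale stimulus with
the first two layers of the standard HMAX model of primary visual cortex:
S1 units are Gabor filters (4 orientations x 16 sizes, paired into 8 scale
bands), and C1 units take local maxima over space and over the two filter
sizes of each band, giving tolerance to small shifts and scale changes.
Pairwise correlation distance between C1 feature vectors yields the visual
model DM, on the same metric as the neural DMs.

Gabor parameters follow the standard published HMAX parameterization:
for filter size ``s``, sigma = 0.0036 s^2 + 0.35 s + 0.18, wavelength =
sigma / 0.8, aspect ratio 0.3; filters are zero-mean and unit-norm, and S1
is the absolute local (mean-removed) normalized cross-correlation, which
makes responses invariant to global luminance offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import DataError, InvalidParameterError
from .repgeom import ItemDM
from .rsa import ModelDM, ModelKind

__all__ = [
    "StimulusImage",
    "GaborBank",
    "C1FeatureVector",
    "default_gabor_bank",
    "s1_responses",
    "c1_pool",
    "c1_features",
    "visual_model_dm",
]

MIN_IMAGE_SIDE = 64


@dataclass(frozen=True)
class StimulusImage:
    """A grayscale stimulus raster with pixel values in [0, 1]."""

    item_id: object
    pixels: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", p)
        if p.ndim != 2:
            raise DataError("pixels must be a 2-D grayscale raster")
        if min(p.shape) < MIN_IMAGE_SIDE:
            raise DataError(f"minimum image side is {MIN_IMAGE_SIDE}, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise DataError("pixels must be finite")


def _gabor(size: int, theta: float, sigma: float, wavelength: float, aspect: float) -> np.ndarray:
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    g = np.exp(-(xr**2 + (aspect * yr) ** 2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * xr / wavelength
    )
    g[x**2 + y**2 > (size / 2) ** 2] = 0.0
    g -= g.mean()
    norm = np.linalg.norm(g)
    if norm > 0:
        g /= norm
    return g


@dataclass
class GaborBank:
    """S1 Gabor filter bank: orientations x paired filter sizes per band."""

    orientations: tuple = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    scale_bands: tuple = ((7, 9), (11, 13), (15, 17), (19, 21), (23, 25), (27, 29), (31, 33), (35, 37))
    pool_sizes: tuple = (8, 10, 12, 14, 16, 18, 20, 22)
    aspect: float = 0.3
    _filters: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.pool_sizes) != len(self.scale_bands):
            raise InvalidParameterError("one pool size per scale band is required")

    def filter(self, size: int, theta: float) -> np.ndarray:
        key = (size, theta)
        if key not in self._filters:
            sigma = 0.0036 * size**2 + 0.35 * size + 0.18
            wavelength = sigma / 0.8
            self._filters[key] = _gabor(size, theta, sigma, wavelength, self.aspect)
        return self._filters[key]

    @property
    def all_sizes(self) -> tuple:
        return tuple(s for band in self.scale_bands for s in band)


def default_gabor_bank() -> GaborBank:
    return GaborBank()


def _local_centered_norm(img: np.ndarray, size: int) -> np.ndarray:
    """Norm of each size x size patch after removing the patch mean."""
    ones = np.ones((size, size))
    npix = float(size * size)
    s1 = fftconvolve(img, ones, mode="same")
    s2 = fftconvolve(img * img, ones, mode="same")
    var = np.maximum(s2 - s1 * s1 / npix, 0.0)
    return np.sqrt(var)


def s1_responses(image: StimulusImage, bank: GaborBank) -> dict:
    """Absolute normalized cross-correlation per orientation and filter size.

    Returns ``{(band_index, size, orientation_index): 2-D response}``; each
    response is in [0, 1] and invariant to adding a constant to the image.
    """
    img = image.pixels
    out = {}
    for b, band in enumerate(bank.scale_bands):
        for size in band:
            denom = _local_centered_norm(img, size)
            # flat patches (norm at FFT-noise level) give zero response
            denom = np.where(denom < 1e-4, np.inf, denom)
            half = size // 2
            for oi, theta in enumerate(bank.orientations):
                f = bank.filter(size, theta)
                num = fftconvolve(img, f[::-1, ::-1], mode="same")
                resp = np.abs(num) / denom
                # zero the half-filter border: padding there is not image content
                resp[:half, :] = 0.0
                resp[-half:, :] = 0.0
                resp[:, :half] = 0.0
                resp[:, -half:] = 0.0
                out[(b, size, oi)] = resp
    return out


def _pool_windows(n: int, pool: int) -> list[tuple[int, int]]:
    """Overlapping pool windows (stride pool//2) covering [0, n)."""
    stride = max(pool // 2, 1)
    starts = list(range(0, max(n - pool, 0) + 1, stride))
    if starts[-1] + pool < n:
        starts.append(n - pool)
    return [(s, min(s + pool, n)) for s in starts]


@dataclass(frozen=True)
class C1FeatureVector:
    item_id: object
    features: np.ndarray


def c1_pool(s1: dict, bank: GaborBank) -> np.ndarray:
    """C1 layer: max over the two filter sizes per band, then local max over
    an overlapping spatial pool grid, concatenated deterministically
    (band-major, then orientation, then grid row-major)."""
    feats = []
    for b, band in enumerate(bank.scale_bands):
        pool = bank.pool_sizes[b]
        for oi in range(len(bank.orientations)):
            merged = np.maximum(s1[(b, band[0], oi)], s1[(b, band[1], oi)])
            H, W = merged.shape
            rows = _pool_windows(H, pool)
            cols = _pool_windows(W, pool)
            for r0, r1 in rows:
                for c0, c1 in cols:
                    feats.append(merged[r0:r1, c0:c1].max())
    return np.asarray(feats)


def c1_features(image: StimulusImage, bank: GaborBank | None = None) -> C1FeatureVector:
    bank = bank or default_gabor_bank()
    return C1FeatureVector(item_id=image.item_id, features=c1_pool(s1_responses(image, bank), bank))


def visual_model_dm(images: list[StimulusImage], bank: GaborBank | None = None) -> ModelDM:
    """Visual-similarity model DM: 1 - Pearson r between C1 feature vectors."""
    if len(images) < 2:
        raise DataError("need at least 2 images")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) != 1:
        raise DataError("images must share a common size (resize upstream)")
    bank = bank or default_gabor_bank()
    feats = np.stack([c1_features(im, bank).features for im in images])
    sd = feats.std(axis=1)
    if np.any(sd == 0):
        bad = [images[i].item_id for i in np.flatnonzero(sd == 0)]
        raise DataError(f"constant C1 feature vector for image(s) {bad}")
    fc = feats - feats.mean(axis=1, keepdims=True)
    fn = fc / np.linalg.norm(fc, axis=1, keepdims=True)
    corr = np.clip(fn @ fn.T, -1.0, 1.0)
    iu = np.triu_indices(len(images), k=1)
    return ModelDM(
        model_kind=ModelKind.VISUAL_SIMILARITY,
        dm=ItemDM(condensed=1.0 - corr[iu], item_ids=tuple(im.item_id for im in images)),
        provenance="HMAX C1 correlation distance",
    )
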