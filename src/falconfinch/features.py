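"""Image preprocessing and feature extraction.

Preprocessing: non-local-means denoising followed by standardization to the
pipeline's fixed 224x224x3 raster in [0, 1]. Features: eight pixel
statistics of the grayscale luminance — mean, standard deviation, variance,
median, skewness, kurtosis, harmonic mean, geometric mean — concatenated
with a pluggable deterministic backbone. The default backbone is a fixed
seeded random projection of the standardized image to 101 features, so the
full vector has length 109.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, runtime_checkable

import numpy as np
from skimage.color import rgb2gray
from skimage.restoration import denoise_nl_means
from skimage.transform import resize

TARGET_SIZE = 224
#: offset applied to zero pixels before harmonic/geometric means
EPS = 1e-8

STAT_NAMES = ("mean", "std", "var", "median", "skew", "kurt", "hmean", "gmean")


@dataclass
class ImageRaster:
    """RGB (or grayscale) image with intensities in [0, 1]."""

    pixels: np.ndarray  # H x W x C (or H x W)
    provenance: str = "unknown"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(f"expected HxWx{{1,3}} pixels, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("empty image")
        if not np.all(np.isfinite(px)):
            raise ValueError("non-finite pixel values")
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def luminance(self) -> np.ndarray:
        """Grayscale luminance plane (H x W)."""
        if self.pixels.shape[2] == 1:
            return self.pixels[:, :, 0]
        return rgb2gray(self.pixels)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.names and len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# preprocessing


def denoise(
    image: ImageRaster,
    strength: float = 10.0 / 255.0,
    patch: int = 7,
    search: int = 21,
) -> ImageRaster:
    """Fast non-local-means denoising; ``strength`` 0 is the identity.

    ``patch`` is the square patch edge; ``search`` the search-window edge
    (both odd, in pixels); ``strength`` the filtering parameter h on the
    [0, 1] intensity scale.
    """
    if patch <= 0 or search <= 0:
        raise ValueError("patch and search sizes must be positive")
    if strength == 0:
        return image
    px = image.pixels
    multichannel = px.shape[2] == 3
    arr = px if multichannel else px[:, :, 0]
    out = denoise_nl_means(
        arr,
        h=strength,
        patch_size=patch,
        patch_distance=(search - 1) // 2,
        fast_mode=True,
        channel_axis=-1 if multichannel else None,
    )
    if not multichannel:
        out = out[:, :, None]
    return ImageRaster(np.clip(out, 0.0, 1.0), provenance=image.provenance)


def standardize(image: ImageRaster) -> ImageRaster:
    """Bilinear-resize to 224x224, replicate grayscale to RGB, clamp to [0, 1]."""
    px = image.pixels
    if px.max() > 1.0:  # tolerate 0..255 inputs
        px = px / 255.0
    if px.shape[:2] != (TARGET_SIZE, TARGET_SIZE):
        px = resize(
            px, (TARGET_SIZE, TARGET_SIZE), order=1, anti_aliasing=False,
            preserve_range=True,
        )
    if px.shape[2] == 1:
        px = np.repeat(px, 3, axis=2)
    return ImageRaster(np.clip(px, 0.0, 1.0), provenance=image.provenance)


# ---------------------------------------------------------------------------
# statistical features


def statistical_features(
    image: ImageRaster, paper_literal: bool = False
) -> FeatureVector:
    """The eight pixel statistics of the grayscale luminance.

    Standard definitions: population standard deviation, sample variance
    (divisor q-1), middle order statistic median, third/fourth standardized
    moments (kurtosis is m4/sigma^4, not excess), harmonic mean
    ``q / sum(1/Z)`` and geometric mean ``(prod Z)^(1/q)``. Zero pixels are
    offset by ``EPS`` for the harmonic/geometric means; a constant image
    gets skewness = kurtosis = 0 by convention.

    ``paper_literal`` evaluates an alternative set of printed formula
    variants kept for comparison only (a variance-like "standard
    deviation", the median's index rather than its value, a single-point
    z-score read at the median for skewness, ``(mu/sigma)^4`` for kurtosis,
    ``q * sum(Z)`` and the raw product); these are not used anywhere in the
    pipeline.
    """
    z = image.luminance().ravel()
    q = z.size
    if q <= 1:
        raise ValueError("need more than one pixel")
    mu = z.mean()
    sigma = z.std()  # population
    zpos = np.where(z <= 0, EPS, z)

    if paper_literal:
        var_like = float(np.mean(z**2) - mu**2)
        median_idx = (q + 1) / 2.0
        med_val = float(np.median(z))
        skew_lit = 0.0 if sigma == 0 else (med_val - mu) / sigma
        kurt_lit = 0.0 if sigma == 0 else (mu / sigma) ** 4
        h_lit = float(q * z.sum())
        with np.errstate(over="ignore", under="ignore"):
            g_lit = float(np.prod(zpos))
        vals = [mu, var_like, z.var(ddof=1), median_idx, skew_lit, kurt_lit, h_lit, g_lit]
        return FeatureVector(np.array(vals), list(STAT_NAMES))

    var = z.var(ddof=1)
    median = float(np.median(z))
    if sigma == 0:
        skew = kurt = 0.0
    else:
        centered = z - mu
        skew = float(np.mean(centered**3) / sigma**3)
        kurt = float(np.mean(centered**4) / sigma**4)
    hmean = q / np.sum(1.0 / zpos)
    gmean = float(np.exp(np.mean(np.log(zpos))))
    vals = [mu, sigma, var, median, skew, kurt, hmean, gmean]
    return FeatureVector(np.array(vals), list(STAT_NAMES))


# ---------------------------------------------------------------------------
# backbones


@runtime_checkable
class BackboneInterface(Protocol):
    """Deterministic map from a standardized raster to a fixed-length vector."""

    name: str
    dim: int

    def __call__(self, image: ImageRaster) -> np.ndarray: ...


class RandomProjectionBackbone:
    """Fixed seeded Gaussian random projection of the standardized image.

    The luminance plane is 4x4 block-averaged (224 -> 56) and projected by a
    frozen N(0, 1/n) matrix, then squashed with tanh. Deterministic for a
    given (dim, seed); no pretrained weights involved.
    """

    def __init__(self, dim: int = 101, seed: int = 13):
        if dim < 0:
            raise ValueError("dim must be >= 0")
        self.name = f"randproj-{dim}"
        self.dim = dim
        self.seed = seed
        n = (TARGET_SIZE // 4) ** 2
        rng = np.random.default_rng(seed)
        self._weights = rng.standard_normal((n, dim)) / np.sqrt(n)

    def __call__(self, image: ImageRaster) -> np.ndarray:
        lum = image.luminance()
        if lum.shape != (TARGET_SIZE, TARGET_SIZE):
            raise ValueError("backbone expects a standardized 224x224 image")
        pooled = lum.reshape(56, 4, 56, 4).mean(axis=(1, 3)).ravel()
        return np.tanh(pooled @ self._weights)


class NullBackbone:
    """Zero-dimensional backbone: features are purely statistical."""

    name = "null"
    dim = 0

    def __call__(self, image: ImageRaster) -> np.ndarray:
        return np.empty(0)


def extract(image: ImageRaster, backbone: Optional[BackboneInterface] = None) -> FeatureVector:
    """Concatenate the eight statistics with the backbone features."""
    if backbone is None:
        backbone = RandomProjectionBackbone()
    stats = statistical_features(image)
    deep = np.asarray(backbone(image), dtype=float).ravel()
    if deep.size != backbone.dim:
        raise ValueError(
            f"backbone {backbone.name!r} declared dim {backbone.dim} "
            f"but returned {deep.size}"
        )
    names = list(stats.names) + [f"{backbone.name}_{i}" for i in range(deep.size)]
    return FeatureVector(np.concatenate([stats.values, deep]), names)


# ---------------------------------------------------------------------------
# image I/O (class-per-folder PNG/JPEG trees)


def load_image(path) -> ImageRaster:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.max() > 1.0:
        arr = arr / 255.0
    return ImageRaster(arr, provenance=str(path))


def load_tree(root) -> list:
    """Load a class-per-folder tree; returns (ImageRaster, class-name) pairs."""
    root = Path(root)
    pairs = []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(cls_dir.iterdir()):
            if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                pairs.append((load_image(f), cls_dir.name))
    if not pairs:
        raise FileNotFoundError(f"no class folders with images under {root}")
    return pairs
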