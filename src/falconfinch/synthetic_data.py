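"""Seeded generator of two-class dermoscopy-like mole images.

Lesions are elliptical blobs whose boundary radius is modulated by a
low-order radial Fourier series. The two classes differ by construction:

* **benign** — near-circular (aspect 1.00-1.15), low border-irregularity
  amplitude (0.02-0.06), a single lesion color;
* **malignant** — elongated (aspect 1.45-2.00), strongly irregular border
  (amplitude 0.12-0.25), 2-4 intra-lesion color patches (Voronoi
  variegation).

Both sit on a textured skin background with additive Gaussian noise and
optional dark curvilinear "hair" strokes. The aspect ranges are disjoint
with a documented margin, so a one-dimensional threshold on the stored
asymmetry parameter separates the classes perfectly — the ceiling against
which pipeline accuracy is judged. The generator exercises code paths; it
makes no claim of photorealism or clinical validity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from falconfinch.features import ImageRaster, extract, standardize

BENIGN = "benign"
MALIGNANT = "malignant"

#: any aspect threshold in the open margin (1.15, 1.45) separates the classes
ASYMMETRY_THRESHOLD = 1.30


@dataclass
class SyntheticSpec:
    """Generation parameters; class regimes are disjoint by construction."""

    n_benign: int = 60
    n_malignant: int = 50
    image_size: int = 224
    benign_asymmetry: tuple[float, float] = (1.00, 1.15)
    malignant_asymmetry: tuple[float, float] = (1.45, 2.00)
    benign_irregularity: tuple[float, float] = (0.02, 0.06)
    malignant_irregularity: tuple[float, float] = (0.12, 0.25)
    benign_patches: tuple[int, int] = (1, 1)
    malignant_patches: tuple[int, int] = (2, 4)
    skin_tone: tuple[float, float, float] = (0.85, 0.72, 0.62)
    noise_sigma: float = 0.03
    hair_probability: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("counts must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if self.benign_asymmetry[1] >= self.malignant_asymmetry[0]:
            raise ValueError("class asymmetry ranges must be disjoint")


@dataclass
class LabeledImage:
    raster: ImageRaster
    label: str
    params: dict = field(default_factory=dict)


def paper_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Full-scale spec: 1800 benign + 1497 malignant images (total 3297)."""
    return SyntheticSpec(n_benign=1800, n_malignant=1497, seed=seed)


def small_spec(seed: int = 0) -> SyntheticSpec:
    """Desk-scale fixture spec: 60 benign + 50 malignant (total 110)."""
    return SyntheticSpec(n_benign=60, n_malignant=50, seed=seed)


def _smooth_noise(rng: np.random.Generator, size: int, coarse: int = 8) -> np.ndarray:
    """Low-frequency texture: coarse Gaussian noise upsampled bilinearly."""
    from skimage.transform import resize

    base = rng.standard_normal((coarse, coarse))
    return resize(base, (size, size), order=1, anti_aliasing=False)


def _draw_hair(rng: np.random.Generator, img: np.ndarray) -> None:
    """Paint 1-3 dark quadratic-curve strokes in place."""
    size = img.shape[0]
    for _ in range(rng.integers(1, 4)):
        pts = rng.uniform(0, size, (3, 2))
        t = np.linspace(0.0, 1.0, 3 * size)[:, None]
        curve = ((1 - t) ** 2) * pts[0] + 2 * t * (1 - t) * pts[1] + t**2 * pts[2]
        shade = rng.uniform(0.05, 0.2)
        for r, c in curve.astype(int):
            if 0 <= r < size and 0 <= c < size:
                img[max(r - 1, 0) : r + 1, max(c - 1, 0) : c + 1, :] = shade


def _render(rng: np.random.Generator, spec: SyntheticSpec, label: str) -> LabeledImage:
    size = spec.image_size
    benign = label == BENIGN
    aspect = rng.uniform(*(spec.benign_asymmetry if benign else spec.malignant_asymmetry))
    amp = rng.uniform(*(spec.benign_irregularity if benign else spec.malignant_irregularity))
    lo, hi = spec.benign_patches if benign else spec.malignant_patches
    n_patches = int(rng.integers(lo, hi + 1))
    # narrow nuisance range: wide radius jitter would drown the class
    # signal that the feature statistics are meant to pick up
    r0 = rng.uniform(0.26, 0.30) * size
    cy, cx = (size / 2 + rng.uniform(-0.05, 0.05, 2) * size)
    phi = rng.uniform(0, np.pi)
    # radial Fourier border perturbation, orders 2..6
    orders = np.arange(2, 7)
    coeffs = rng.standard_normal(orders.size)
    coeffs /= np.abs(coeffs).sum()
    phases = rng.uniform(0, 2 * np.pi, orders.size)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = (-dx * np.sin(phi) + dy * np.cos(phi)) * aspect
    dist = np.hypot(xr, yr)
    theta = np.arctan2(yr, xr)
    border = r0 * (
        1.0 + amp * np.sum(np.sin(orders[:, None, None] * theta[None] + phases[:, None, None])
                           * coeffs[:, None, None], axis=0)
    )
    mask = dist < border

    img = np.empty((size, size, 3), dtype=float)
    tone = np.asarray(spec.skin_tone) + rng.uniform(-0.03, 0.03, 3)
    texture = 0.02 * _smooth_noise(rng, size)
    for c in range(3):
        img[:, :, c] = tone[c] + texture

    base_color = np.array([0.35, 0.22, 0.15]) + rng.uniform(-0.05, 0.05, 3)
    if n_patches <= 1:
        img[mask] = base_color
    else:  # Voronoi color variegation inside the lesion
        ang = rng.uniform(0, 2 * np.pi, n_patches)
        rad = rng.uniform(0, 0.7 * r0, n_patches)
        seeds = np.stack([cy + rad * np.sin(ang), cx + rad * np.cos(ang)], axis=1)
        colors = np.clip(base_color + rng.uniform(-0.12, 0.12, (n_patches, 3)), 0, 1)
        my, mx = np.nonzero(mask)
        d2 = (my[:, None] - seeds[:, 0]) ** 2 + (mx[:, None] - seeds[:, 1]) ** 2
        img[my, mx] = colors[d2.argmin(axis=1)]

    hair = bool(rng.random() < spec.hair_probability)
    if hair:
        _draw_hair(rng, img)
    img += rng.standard_normal(img.shape) * spec.noise_sigma
    np.clip(img, 0.0, 1.0, out=img)

    params = {
        "asymmetry": float(aspect),
        "irregularity": float(amp),
        "n_patches": n_patches,
        "radius": float(r0),
        "hair": hair,
    }
    return LabeledImage(
        ImageRaster(img.astype(np.float32), provenance=f"synthetic:{label}"),
        label,
        params,
    )


def iter_generate(spec: SyntheticSpec) -> Iterator[LabeledImage]:
    """Stream labeled images (benign first) without holding them all in memory."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_benign):
        yield _render(rng, spec, BENIGN)
    for _ in range(spec.n_malignant):
        yield _render(rng, spec, MALIGNANT)


def generate(spec: SyntheticSpec) -> list[LabeledImage]:
    """Materialize the full image list; bit-identical under the same seed."""
    return list(iter_generate(spec))


def feature_table(spec: SyntheticSpec, backbone=None):
    """generate -> standardize -> extract for each image; labeled DataFrame."""
    import pandas as pd

    rows, labels = [], []
    names = None
    for li in iter_generate(spec):
        fv = extract(standardize(li.raster), backbone)
        if names is None:
            names = fv.names
        rows.append(fv.values)
        labels.append(li.label)
    df = pd.DataFrame(rows, columns=names)
    df["label"] = labels
    return df


def write_tree(images: list[LabeledImage], outdir, manifest: Optional[dict] = None) -> Path:
    """Write a class-per-folder PNG tree plus a JSON manifest."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    counts: dict[str, int] = {}
    for li in images:
        cls_dir = outdir / li.label
        cls_dir.mkdir(parents=True, exist_ok=True)
        idx = counts.get(li.label, 0)
        counts[li.label] = idx + 1
        arr = (np.clip(li.raster.pixels, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(cls_dir / f"{li.label}_{idx:05d}.png", arr)
    payload = {"counts": counts}
    if manifest:
        payload.update(manifest)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return outdir


def asymmetry_threshold_accuracy(images: list[LabeledImage]) -> float:
    """Fraction classified correctly by thresholding the stored asymmetry."""
    correct = sum(
        (li.params["asymmetry"] > ASYMMETRY_THRESHOLD) == (li.label == MALIGNANT)
        for li in images
    )
    return correct / len(images)
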