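"""Image I/O, ROI extraction, and the synthetic vein-image generator.

Finger-vein recognition pipelines consume small grayscale region-of-
interest (ROI) crops. This module loads and preprocesses such crops,
reconstructs ROIs from raw finger images via Canny contour detection, and
generates synthetic per-class vein patterns — bright curvilinear structures
on a darker noisy background with small intra-class geometric and intensity
jitter — so the whole pipeline can be exercised and tested without any
benchmark download.

Coordinates are row-major, 0-based, origin at the top-left, throughout.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.feature import canny
from skimage.transform import resize as _sk_resize

__all__ = [
    "RoiImage",
    "SyntheticSpec",
    "RoiExtractionError",
    "load_and_preprocess",
    "extract_roi_canny",
    "generate_synthetic_dataset",
    "synthetic_finger",
    "save_dataset",
    "load_dataset",
    "train_test_split_per_class",
]


class RoiExtractionError(RuntimeError):
    """Raised when no usable finger contours can be detected."""


@dataclass
class RoiImage:
    """A grayscale ROI crop in [0, 255] with its provenance."""

    pixels: np.ndarray
    source_id: tuple = ("unknown", "unknown")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("RoiImage must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("RoiImage values must lie in [0, 255]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic vein-image generator.

    Each class owns a fixed template of ``veins_per_class`` smooth random
    paths; each sample is the template under a small rigid + intensity
    perturbation plus fresh sensor noise. Veins are rendered bright on a
    dark background (set ``invert=True`` for the opposite polarity).
    """

    n_classes: int = 10
    n_per_class: int = 10
    size: tuple[int, int] = (48, 48)
    veins_per_class: int = 4
    vein_width: float = 1.5  # Gaussian cross-section std, pixels
    fg_mean: float = 180.0
    bg_mean: float = 60.0
    noise_sigma: float = 8.0
    max_shift: float = 2.0  # pixels
    max_rotation: float = 3.0  # degrees
    intensity_jitter: float = 0.1  # multiplicative fraction
    invert: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.bg_mean <= 255 and 0 <= self.fg_mean <= 255):
            raise ValueError("intensity means must lie in [0, 255]")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class for splits")
        if self.n_classes < 1 or self.veins_per_class < 1:
            raise ValueError("counts must be positive")


def load_and_preprocess(
    path, target_size: tuple[int, int] = (48, 48), rotate90: bool = False
) -> RoiImage:
    """Load an 8-bit image file, convert to grayscale luminance, optionally
    rotate 90 degrees counterclockwise, and bilinearly resize."""
    if target_size[0] <= 0 or target_size[1] <= 0:
        raise ValueError("target size must be positive")
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.float64)
    if rotate90:
        arr = np.rot90(arr)
    arr = _resize_bilinear(arr, target_size)
    stem = os.path.splitext(os.path.basename(path))[0]
    cls = os.path.basename(os.path.dirname(path)) or "unknown"
    return RoiImage(pixels=arr, source_id=(cls, stem))


def _resize_bilinear(arr: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    if arr.shape == tuple(target_size):
        return arr
    out = _sk_resize(
        arr, target_size, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    return np.clip(out, 0.0, 255.0)


def extract_roi_canny(
    raw: np.ndarray,
    top_crop: int = 45,
    bottom_crop: int = 25,
    target_size: tuple[int, int] = (48, 48),
    canny_sigma: float = 1.4,
    low_threshold: float = 0.1,
    high_threshold: float = 0.3,
    vertical_aspect: float = 3.0,
    return_bounds: bool = False,
):
    """Recover the vein-bearing ROI from a raw finger image.

    Rows are first cropped top and bottom to suppress device borders, then
    Canny edges locate the finger's upper and lower contours: per column the
    topmost and bottommost edge rows are taken and aggregated by the median,
    after discarding near-vertical edge runs (connected components whose
    vertical extent exceeds ``vertical_aspect`` times their horizontal
    extent — typically device contours). The band between the contours is
    cropped and bilinearly resized to ``target_size``.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape[0] <= top_crop + bottom_crop:
        raise ValueError("image shorter than the requested crops")
    body = raw[top_crop : raw.shape[0] - bottom_crop]
    edges = canny(
        body / 255.0,
        sigma=canny_sigma,
        low_threshold=low_threshold,
        high_threshold=high_threshold,
    )
    if not edges.any():
        raise RoiExtractionError("no edges detected")
    labels, n_comp = ndimage.label(edges, structure=np.ones((3, 3), dtype=int))
    keep = np.zeros_like(edges)
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == comp)
        v_extent = rows.max() - rows.min() + 1
        h_extent = cols.max() - cols.min() + 1
        if v_extent <= vertical_aspect * h_extent:
            keep |= labels == comp
    if not keep.any():
        raise RoiExtractionError("only vertical device contours detected")
    col_has = keep.any(axis=0)
    rows_idx = np.arange(body.shape[0])[:, None]
    top_rows = np.min(np.where(keep, rows_idx, body.shape[0]), axis=0)[col_has]
    bot_rows = np.max(np.where(keep, rows_idx, -1), axis=0)[col_has]
    upper = int(np.median(top_rows))
    lower = int(np.median(bot_rows))
    if lower <= upper:
        raise RoiExtractionError("degenerate contours")
    crop = body[upper : lower + 1]
    roi = RoiImage(pixels=_resize_bilinear(crop, target_size), source_id=("roi", "extracted"))
    if return_bounds:
        # bounds are row indices within the top/bottom-cropped frame
        return roi, upper, lower
    return roi


def synthetic_finger(
    height: int = 200,
    width: int = 300,
    band_top: int = 60,
    band_bottom: int = 150,
    bright: float = 200.0,
    dark: float = 20.0,
) -> tuple[np.ndarray, int, int]:
    """Bright horizontal "finger" band on a dark background, for exercising
    ROI extraction with known ground-truth boundaries."""
    img = np.full((height, width), dark)
    img[band_top : band_bottom + 1] = bright
    return img, band_top, band_bottom


def _render_template(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one class's vein template: smooth spline paths with a Gaussian
    cross-section, peak near fg_mean over a bg_mean background."""
    H, W = spec.size
    rows = np.arange(H, dtype=np.float64)[:, None]
    cols = np.arange(W, dtype=np.float64)
    accum = np.zeros((H, W))
    amplitude = spec.fg_mean - spec.bg_mean
    for _ in range(spec.veins_per_class):
        n_ctrl = int(rng.integers(3, 6))
        xs = np.sort(rng.uniform(0, W - 1, size=n_ctrl))
        xs[0], xs[-1] = 0.0, W - 1.0
        while np.any(np.diff(xs) <= 1e-6):
            xs = np.sort(rng.uniform(0, W - 1, size=n_ctrl))
            xs[0], xs[-1] = 0.0, W - 1.0
        ys = rng.uniform(0.12 * H, 0.88 * H, size=n_ctrl)
        path = CubicSpline(xs, ys)(cols)
        accum += np.exp(-((rows - path[None, :]) ** 2) / (2.0 * spec.vein_width**2))
    template = spec.bg_mean + amplitude * np.clip(accum, 0.0, 1.0)
    if spec.invert:
        template = 255.0 - template
    return np.clip(template, 0.0, 255.0)


def generate_synthetic_dataset(spec: SyntheticSpec) -> tuple[list[RoiImage], np.ndarray]:
    """Deterministic synthetic dataset: per class a fixed vein template,
    per sample a jittered, noisy view of it.

    Substream seeding is counter-based on (seed, class) and (seed, class,
    sample), so adding classes or samples never changes earlier pixels.
    """
    images: list[RoiImage] = []
    labels: list[int] = []
    for cls in range(spec.n_classes):
        template = _render_template(spec, np.random.default_rng([spec.seed, cls]))
        for idx in range(spec.n_per_class):
            rng = np.random.default_rng([spec.seed, cls, idx])
            sample = template
            angle = rng.uniform(-spec.max_rotation, spec.max_rotation)
            if spec.max_rotation > 0:
                sample = ndimage.rotate(
                    sample, angle, reshape=False, order=1, mode="nearest"
                )
            shift = rng.uniform(-spec.max_shift, spec.max_shift, size=2)
            if spec.max_shift > 0:
                sample = ndimage.shift(sample, shift, order=1, mode="nearest")
            gain = 1.0 + rng.uniform(-spec.intensity_jitter, spec.intensity_jitter)
            sample = sample * gain
            if spec.noise_sigma > 0:
                sample = sample + rng.normal(0.0, spec.noise_sigma, size=sample.shape)
            images.append(
                RoiImage(pixels=np.clip(sample, 0.0, 255.0), source_id=(cls, idx))
            )
            labels.append(cls)
    return images, np.asarray(labels)


def train_test_split_per_class(
    labels: np.ndarray, n_test: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic split: the last ``n_test`` samples of each class (in
    dataset order) go to the test set. Returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) <= n_test:
            raise ValueError("not enough samples per class for the requested split")
        train_idx.extend(idx[:-n_test])
        test_idx.extend(idx[-n_test:])
    return np.asarray(train_idx), np.asarray(test_idx)


def save_dataset(images: list[RoiImage], labels, directory) -> str:
    """Write images as DIR/<class_id>/<sample_id>.png plus a manifest CSV."""
    os.makedirs(directory, exist_ok=True)
    manifest = os.path.join(directory, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "sample"])
        counters: dict = {}
        for img, cls in zip(images, labels):
            counters[cls] = counters.get(cls, -1) + 1
            cls_dir = os.path.join(directory, str(cls))
            os.makedirs(cls_dir, exist_ok=True)
            rel = os.path.join(str(cls), f"{counters[cls]:04d}.png")
            Image.fromarray(np.round(img.pixels).astype(np.uint8)).save(
                os.path.join(directory, rel)
            )
            writer.writerow([rel, cls, counters[cls]])
    return manifest


def load_dataset(directory, target_size: tuple[int, int] | None = None):
    """Load a DIR/<class_id>/<sample>.png tree back into images + labels."""
    images, labels = [], []
    for cls in sorted(
        d for d in os.listdir(directory) if os.path.isdir(os.path.join(directory, d))
    ):
        cls_dir = os.path.join(directory, cls)
        for name in sorted(os.listdir(cls_dir)):
            if not name.lower().endswith((".png", ".bmp")):
                continue
            path = os.path.join(cls_dir, name)
            if target_size is None:
                with Image.open(path) as img:
                    arr = np.asarray(img.convert("L"), dtype=np.float64)
                images.append(RoiImage(pixels=arr, source_id=(cls, name)))
            else:
                images.append(load_and_preprocess(path, target_size))
            labels.append(cls)
    return images, np.asarray(labels)
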