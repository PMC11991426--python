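"""Gabor and difference-of-Gaussians filter banks for spike encoding.

The front end of the recognition pipeline mimics the early visual system:
DoG kernels model the center-surround receptive fields of retinal ganglion
cells (contrast), while oriented Gabor kernels model cortical simple cells
(edge orientation). Each kernel is mean-normalized so it responds to image
structure, not to overall brightness. Responses are rectified, rescaled to
the 8-bit range per channel, and thresholded so that only salient structure
survives into the spike encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "GaborParams",
    "DoGParams",
    "FilterBank",
    "IntensityMaps",
    "make_gabor_kernel",
    "make_dog_kernel",
    "apply_filter_bank",
    "default_filter_bank",
]

#: Default Gabor orientations (radians).
DEFAULT_ORIENTATIONS = (3 * np.pi / 8, 5 * np.pi / 8, 7 * np.pi / 8, 9 * np.pi / 8)
#: Default DoG standard-deviation pairs (on-center, off-center).
DEFAULT_DOG_PAIRS = ((1.0, 2.0), (2.0, 1.0))
#: Default post-rescale response cutoff on the 0-255 scale.
DEFAULT_CUTOFF = 50.0


def _check_window(window: int) -> None:
    if not isinstance(window, (int, np.integer)) or window < 3 or window % 2 == 0:
        raise ValueError(f"kernel window must be an odd integer >= 3, got {window!r}")


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one real Gabor kernel.

    Attributes
    ----------
    window : odd kernel side length in pixels.
    theta : orientation of the stripes' normal, radians.
    lam : wavelength of the cosine carrier, pixels.
    sigma : std of the Gaussian envelope, pixels.
    gamma : spatial aspect ratio (ellipticity of the envelope).
    phi : phase offset of the carrier, radians.
    """

    window: int
    theta: float
    lam: float
    sigma: float
    gamma: float = 0.3
    phi: float = 0.0

    def __post_init__(self) -> None:
        _check_window(self.window)
        if self.lam <= 0 or self.sigma <= 0 or self.gamma <= 0:
            raise ValueError("lam, sigma and gamma must all be positive")


@dataclass(frozen=True)
class DoGParams:
    """Parameters of one difference-of-Gaussians kernel.

    delta1 < delta2 gives an on-center kernel (excitatory center),
    delta1 > delta2 an off-center one.
    """

    window: int
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        _check_window(self.window)
        if self.delta1 <= 0 or self.delta2 <= 0:
            raise ValueError("Gaussian standard deviations must be positive")


FilterParams = Union[GaborParams, DoGParams]


@dataclass
class FilterBank:
    """Ordered stack of normalized 2-D kernels plus the response cutoff."""

    kernels: list[np.ndarray]
    params: list[FilterParams]
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be nonnegative")
        if len(self.kernels) != len(self.params):
            raise ValueError("kernels and params must have equal length")

    def __len__(self) -> int:
        return len(self.kernels)

    def export_csv(self, directory) -> list[str]:
        """Write each kernel to ``directory`` as CSV; returns the file names."""
        import os

        os.makedirs(directory, exist_ok=True)
        names = []
        for i, (k, p) in enumerate(zip(self.kernels, self.params)):
            kind = "gabor" if isinstance(p, GaborParams) else "dog"
            name = f"channel{i:02d}_{kind}.csv"
            np.savetxt(os.path.join(directory, name), k, delimiter=",")
            names.append(name)
        return names


@dataclass
class IntensityMaps:
    """F x H x W stack of nonnegative filter responses with provenance."""

    data: np.ndarray
    channel_meta: list[FilterParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("IntensityMaps.data must be F x H x W")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("IntensityMaps must be finite")


def _grid(window: int) -> tuple[np.ndarray, np.ndarray]:
    half = window // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    # x runs along columns, y along rows; origin at the kernel midpoint
    return x.astype(np.float64), y.astype(np.float64)


def _mean_max_normalize(raw: np.ndarray) -> np.ndarray:
    centered = raw - raw.mean()
    peak = centered.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: no positive deviation from its mean")
    return centered / peak


def make_gabor_kernel(p: GaborParams) -> np.ndarray:
    """Real-part Gabor kernel, mean-subtracted and peak-normalized.

    G(x, y) = exp(-(X^2 + gamma^2 Y^2) / (2 sigma^2)) * cos(2 pi X / lam + phi)
    with rotated coordinates X = x cos(theta) + y sin(theta),
    Y = -x sin(theta) + y cos(theta). The normalized kernel is
    (G - mean(G)) / max(G - mean(G)), which has exactly zero mean.
    """
    x, y = _grid(p.window)
    X = x * np.cos(p.theta) + y * np.sin(p.theta)
    Y = -x * np.sin(p.theta) + y * np.cos(p.theta)
    envelope = np.exp(-(X**2 + p.gamma**2 * Y**2) / (2.0 * p.sigma**2))
    raw = envelope * np.cos(2.0 * np.pi * X / p.lam + p.phi)
    return _mean_max_normalize(raw)


def make_dog_kernel(p: DoGParams) -> np.ndarray:
    """Difference-of-Gaussians kernel, mean-subtracted and peak-normalized.

    D(x, y) = N(0, delta1^2) - N(0, delta2^2) evaluated on the pixel grid
    (2-D isotropic Gaussians with their 1/(2 pi delta^2) amplitudes), then
    normalized like the Gabor kernel. Raises if delta1 == delta2, where the
    raw kernel vanishes identically.
    """
    x, y = _grid(p.window)
    r2 = x**2 + y**2
    g1 = np.exp(-r2 / (2.0 * p.delta1**2)) / (2.0 * np.pi * p.delta1**2)
    g2 = np.exp(-r2 / (2.0 * p.delta2**2)) / (2.0 * np.pi * p.delta2**2)
    return _mean_max_normalize(g1 - g2)


def raw_dog_kernel(p: DoGParams) -> np.ndarray:
    """Un-normalized DoG kernel (exposed for inspection and testing)."""
    x, y = _grid(p.window)
    r2 = x**2 + y**2
    g1 = np.exp(-r2 / (2.0 * p.delta1**2)) / (2.0 * np.pi * p.delta1**2)
    g2 = np.exp(-r2 / (2.0 * p.delta2**2)) / (2.0 * np.pi * p.delta2**2)
    return g1 - g2


def default_filter_bank(
    gabor_window: int = 15,
    orientations: Sequence[float] = DEFAULT_ORIENTATIONS,
    dog_window: int = 7,
    dog_pairs: Sequence[tuple[float, float]] = DEFAULT_DOG_PAIRS,
    cutoff: float = DEFAULT_CUTOFF,
    lam: float | None = None,
    sigma: float | None = None,
    gamma: float = 0.3,
    phi: float = 0.0,
) -> FilterBank:
    """Standard 6-channel bank: four oriented Gabors plus an on- and an
    off-center DoG.

    Wavelength defaults to half the window and the envelope std to 0.8
    wavelengths — conventional settings for spiking-vision front ends; the
    mean/max normalization makes the absolute scale second-order.
    """
    lam = gabor_window / 2.0 if lam is None else lam
    sigma = 0.8 * lam if sigma is None else sigma
    params: list[FilterParams] = [
        GaborParams(gabor_window, float(th), lam, sigma, gamma, phi)
        for th in orientations
    ]
    params += [DoGParams(dog_window, d1, d2) for d1, d2 in dog_pairs]
    kernels = [
        make_gabor_kernel(p) if isinstance(p, GaborParams) else make_dog_kernel(p)
        for p in params
    ]
    return FilterBank(kernels=kernels, params=params, cutoff=cutoff)


def apply_filter_bank(image: np.ndarray, bank: FilterBank) -> IntensityMaps:
    """Filter a grayscale image with every kernel in the bank.

    Each channel is the "same"-size zero-padded cross-correlation of the
    image with one kernel (no kernel flip, matching conv-layer semantics),
    rectified at zero, rescaled so the channel maximum maps to 255 (when
    positive), and finally hard-thresholded: values below ``bank.cutoff``
    are set to zero.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    if len(bank) == 0:
        raise ValueError("filter bank has no kernels")

    channels = []
    for kernel in bank.kernels:
        # correlate2d flips nothing when given the flipped kernel; use the
        # correlation identity corr(a, k) = conv(a, flip(k))
        resp = correlate2d(image, kernel, mode="same", boundary="fill", fillvalue=0.0)
        resp = np.clip(resp, 0.0, None)
        peak = resp.max()
        # peaks at rounding-noise level mean "no response"; rescaling them
        # would amplify float noise to full intensity
        if peak > 1e-8:
            resp = resp * (255.0 / peak)
        else:
            resp = np.zeros_like(resp)
        resp[resp < bank.cutoff] = 0.0
        channels.append(resp)
    return IntensityMaps(data=np.stack(channels), channel_meta=list(bank.params))
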