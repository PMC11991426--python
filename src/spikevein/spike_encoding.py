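"""Intensity-to-latency spike encoding.

Filtered intensity maps are turned into a cumulative binary spike-wave
tensor S[t, f, r, c]: a neuron representing a bright pixel fires early and
keeps firing at every later time step, so S is non-decreasing along t.
Before encoding, each channel is contrast-normalized by its local mean and
a pointwise cross-channel inhibition keeps only the strongest channel at
each pixel, enforcing sparse, near-orthogonal channel responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .filterbank import IntensityMaps

__all__ = [
    "NEVER",
    "LatencyMap",
    "SpikeWave",
    "local_normalize",
    "pointwise_intensity_inhibition",
    "encode_to_spike_wave",
    "encode_image_maps",
]

#: Sentinel latency for neurons that never fire (the "infinity" latency).
NEVER = -1

_EPS = 1e-12


@dataclass
class LatencyMap:
    """First-spike times per neuron: F x H x W int array, NEVER = no spike."""

    t_first: np.ndarray
    t_max: int

    def __post_init__(self) -> None:
        finite = self.t_first[self.t_first != NEVER]
        if finite.size and (finite.min() < 0 or finite.max() >= self.t_max):
            raise ValueError("latencies must lie in [0, t_max)")


@dataclass
class SpikeWave:
    """Cumulative binary spike tensor s[t, f, r, c] of shape Tmax x F x H x W."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s)
        if self.s.ndim != 4:
            raise ValueError("SpikeWave must be 4-D (t, f, r, c)")

    @property
    def t_max(self) -> int:
        return self.s.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s.shape

    def is_cumulative(self) -> bool:
        return bool(np.all(self.s[:-1] <= self.s[1:])) if self.t_max > 1 else True

    def save(self, path) -> None:
        """Serialize as a compressed archive with arrays `s` and `t_first`."""
        t_first = first_spike_times(self.s)
        np.savez_compressed(path, s=self.s.astype(np.uint8), t_first=t_first.astype(np.int16))

    @classmethod
    def load(cls, path) -> "SpikeWave":
        with np.load(path) as archive:
            return cls(s=archive["s"].astype(np.uint8))


def first_spike_times(s: np.ndarray) -> np.ndarray:
    """First-spike time per neuron of a cumulative spike tensor (NEVER if none)."""
    t_max = s.shape[0]
    counts = s.sum(axis=0)
    t_first = t_max - counts
    return np.where(counts == 0, NEVER, t_first).astype(np.int64)


def local_normalize(maps: IntensityMaps, radius: int = 8) -> IntensityMaps:
    """Divide each value by the mean of its zero-padded square neighborhood.

    The window is (2 radius + 1)^2, treated independently per channel, with a
    small epsilon guarding all-zero regions. Scale-invariant: multiplying a
    channel by a positive constant leaves interior outputs unchanged.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    out = np.empty_like(maps.data)
    for f in range(maps.data.shape[0]):
        local_mean = uniform_filter(maps.data[f], size=size, mode="constant", cval=0.0)
        out[f] = maps.data[f] / (local_mean + _EPS)
    return IntensityMaps(data=out, channel_meta=list(maps.channel_meta))


def pointwise_intensity_inhibition(maps: IntensityMaps) -> IntensityMaps:
    """Keep, at each pixel, only the channel with the maximal value.

    Ties go to the lowest channel index. Mimics lateral inhibition across
    feature channels: at most one neuron per retinotopic location stays
    active.
    """
    data = maps.data
    if data.shape[0] < 1:
        raise ValueError("need at least one channel")
    winner = np.argmax(data, axis=0)  # ties -> lowest index
    mask = winner[None, :, :] == np.arange(data.shape[0])[:, None, None]
    return IntensityMaps(data=np.where(mask, data, 0.0), channel_meta=list(maps.channel_meta))


def encode_to_spike_wave(
    maps: IntensityMaps, t_max: int = 15, binning: str = "rank"
) -> tuple[LatencyMap, SpikeWave]:
    """Rank-order encode nonnegative intensity maps into a spike wave.

    All strictly positive values (across every channel) are sorted in
    descending order — ties broken by (channel, row, col) lexicographic
    order — and the sorted sequence is split into ``t_max`` contiguous bins
    of near-equal count; a value's bin index is its first-spike latency.
    Zero values never fire. The spike wave is cumulative: s[t] = 1 iff
    t >= latency.

    ``binning="linear"`` instead maps intensity linearly onto latency
    (maximum intensity -> time 0).
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    data = maps.data
    if data.min() < 0:
        raise ValueError("maps must be nonnegative")
    F, H, W = data.shape
    flat = data.reshape(-1)
    t_first_flat = np.full(flat.shape, NEVER, dtype=np.int64)
    nonzero = np.flatnonzero(flat > 0)
    if nonzero.size:
        if binning == "rank":
            # stable sort on negated values: ties keep flat (f, r, c) order
            order = nonzero[np.argsort(-flat[nonzero], kind="stable")]
            ranks = np.arange(order.size, dtype=np.int64)
            t_first_flat[order] = (ranks * t_max) // order.size
        elif binning == "linear":
            vmax = flat[nonzero].max()
            lat = np.floor((1.0 - flat[nonzero] / vmax) * t_max).astype(np.int64)
            t_first_flat[nonzero] = np.clip(lat, 0, t_max - 1)
        else:
            raise ValueError(f"unknown binning scheme {binning!r}")
    t_first = t_first_flat.reshape(F, H, W)
    latency = LatencyMap(t_first=t_first, t_max=t_max)
    steps = np.arange(t_max).reshape(t_max, 1, 1, 1)
    s = ((t_first[None] != NEVER) & (steps >= t_first[None])).astype(np.uint8)
    wave = SpikeWave(s=s)
    assert wave.is_cumulative()
    return latency, wave


def encode_image_maps(
    maps: IntensityMaps,
    t_max: int = 15,
    norm_radius: int = 8,
    binning: str = "rank",
) -> SpikeWave:
    """Full encoder pipeline: local normalization -> pointwise inhibition ->
    intensity-to-latency encoding. Expects cutoff-thresholded filter maps."""
    normalized = local_normalize(maps, radius=norm_radius)
    inhibited = pointwise_intensity_inhibition(normalized)
    _, wave = encode_to_spike_wave(inhibited, t_max=t_max, binning=binning)
    return wave
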