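"""Non-leaky integrate-and-fire spiking convolution.

A spiking convolutional layer turns an input spike wave into a membrane
potential tensor: at every time step the potential of an output neuron is
the weighted sum of the (cumulative) input spikes in its receptive field.
Potentials are optionally batch-normalized per output channel, compared
against a firing threshold, and every neuron at or above threshold emits a
spike. The threshold can be fixed, or adaptive: during training it equals
the mean of the current sample's potential tensor, and an exponential
moving average of those per-sample values (momentum M) is carried over for
use at test time:

    test_threshold <- test_threshold * M + train_threshold * (1 - M)

initialized to the adaptive threshold of the first training sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spike_encoding import SpikeWave

__all__ = [
    "WeightTensor",
    "ThresholdState",
    "BNState",
    "init_weights",
    "conv_potentials",
    "batch_norm_potentials",
    "sample_threshold",
    "update_test_threshold",
    "fire",
]

# Default synaptic weight bounds; the STDP stabilizer (W-LB)(UB-W) and the
# 0.8 +/- 0.05 initialization both presuppose the unit interval.
DEFAULT_LB = 0.0
DEFAULT_UB = 1.0


@dataclass
class WeightTensor:
    """Synaptic weights, shape Fout x Fin x kh x kw, clamped to [lb, ub]."""

    w: np.ndarray
    lb: float = DEFAULT_LB
    ub: float = DEFAULT_UB

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 4:
            raise ValueError("weights must be 4-D (Fout, Fin, kh, kw)")
        if self.lb >= self.ub:
            raise ValueError("lb must be < ub")
        if self.w.min() < self.lb or self.w.max() > self.ub:
            raise ValueError("weights out of [lb, ub]")


@dataclass
class ThresholdState:
    """Firing-threshold bookkeeping for one layer."""

    mode: str = "adaptive"  # "adaptive" | "fixed"
    fixed_value: float = 1.0
    momentum: float = 0.9
    test_threshold: float = float("nan")
    initialized: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "fixed"):
            raise ValueError("mode must be 'adaptive' or 'fixed'")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")

    def inference_threshold(self) -> float:
        if self.mode == "fixed":
            return self.fixed_value
        if not self.initialized:
            raise RuntimeError("adaptive threshold never initialized (layer untrained)")
        return self.test_threshold


@dataclass
class BNState:
    """Per-output-channel running statistics for batch normalization.

    Training uses the current sample's statistics (online, batch size 1)
    and updates the running averages; inference uses the running averages.
    No learned affine — there is no gradient pathway to train one.
    """

    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None
    momentum: float = 0.1
    eps: float = 1e-5
    enabled: bool = True

    def _ensure(self, channels: int) -> None:
        if self.running_mean is None:
            self.running_mean = np.zeros(channels)
            self.running_var = np.ones(channels)


def init_weights(
    shape: tuple[int, int, int, int],
    mu: float = 0.8,
    sigma: float = 0.05,
    rng_seed: int | np.random.Generator = 0,
    lb: float = DEFAULT_LB,
    ub: float = DEFAULT_UB,
) -> WeightTensor:
    """Normal(mu, sigma) i.i.d. weights clamped to [lb, ub], reproducible."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if any(s <= 0 for s in shape):
        raise ValueError("shape entries must be positive")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    w = np.clip(rng.normal(mu, sigma, size=shape), lb, ub)
    return WeightTensor(w=w, lb=lb, ub=ub)


def conv_potentials(s: SpikeWave, weights: WeightTensor) -> np.ndarray:
    """Valid cross-correlation of the spike wave with the weight tensor,
    applied independently at every time step.

    v[t, o, h, w] = sum_{i, p, q} W[o, i, p, q] * s[t, i, h+p, w+q]

    With cumulative spikes and nonnegative weights the potentials are
    themselves non-decreasing in t. Output spatial size is
    (H - kh + 1) x (W - kw + 1).
    """
    arr = s.s
    T, Fin, H, W = arr.shape
    Fout, Fin_w, kh, kw = weights.w.shape
    if Fin != Fin_w:
        raise ValueError(f"channel mismatch: spikes {Fin}, weights {Fin_w}")
    if kh > H or kw > W:
        raise ValueError("kernel larger than input")
    windows = np.lib.stride_tricks.sliding_window_view(arr, (kh, kw), axis=(2, 3))
    # windows: T x Fin x H' x W' x kh x kw
    v = np.einsum(
        "tihwpq,oipq->tohw",
        windows.astype(np.float64),
        weights.w,
        optimize=True,
    )
    return v


def batch_norm_potentials(v: np.ndarray, bn: BNState, training: bool) -> np.ndarray:
    """Standardize potentials per output channel over (time x space).

    Training mode normalizes with the current sample's statistics and folds
    them into the running averages; inference mode normalizes with the
    running averages. Channels with zero variance map to all zeros.
    """
    if not bn.enabled:
        raise ValueError("batch_norm_potentials called with bn.enabled=False")
    channels = v.shape[1]
    bn._ensure(channels)
    if training:
        mean = v.mean(axis=(0, 2, 3))
        var = v.var(axis=(0, 2, 3))
        bn.running_mean = (1 - bn.momentum) * bn.running_mean + bn.momentum * mean
        bn.running_var = (1 - bn.momentum) * bn.running_var + bn.momentum * var
    else:
        mean = bn.running_mean
        var = bn.running_var
    shape = (1, channels, 1, 1)
    return (v - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + bn.eps)


def sample_threshold(v: np.ndarray) -> float:
    """Adaptive per-sample threshold: the mean of the whole potential tensor."""
    if v.size == 0:
        raise ValueError("empty potential tensor")
    return float(v.mean())


def update_test_threshold(state: ThresholdState, train_threshold: float) -> ThresholdState:
    """Fold one per-sample adaptive threshold into the test-time EMA (in place).

    First call seeds the EMA with the sample's value; later calls apply
    test <- test * M + train * (1 - M).
    """
    if state.mode != "adaptive":
        raise ValueError("update_test_threshold requires adaptive mode")
    if not state.initialized:
        state.test_threshold = float(train_threshold)
        state.initialized = True
    else:
        state.test_threshold = (
            state.test_threshold * state.momentum
            + float(train_threshold) * (1.0 - state.momentum)
        )
    return state


def fire(v: np.ndarray, threshold: float) -> tuple[np.ndarray, SpikeWave]:
    """Emit spikes wherever the potential reaches the threshold.

    A neuron exactly at threshold fires (>= convention). Returns the
    thresholded potentials (potential where spiking, else 0) and the spike
    wave. Monotone potentials yield a cumulative spike wave.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    spikes = (v >= threshold).astype(np.uint8)
    thresholded = np.where(spikes, v, 0.0)
    return thresholded, SpikeWave(s=spikes)
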