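"""Two-layer spiking convolutional network: assembly, layer-wise training,
pooling, and spike-feature extraction.

The default architecture follows the reference design: a 6-channel encoder
(4 Gabor + 2 DoG), a 16-map 5x5 spiking conv layer (5 winners, inhibition
radius 2, 2 epochs, with learning-rate doubling), and a 20-map 2x2 layer
(8 winners, radius 1, 20 epochs), each followed by 2x2/stride-2/padding-1
max pooling. Training is strictly layer-wise and per-image (batch size 1):
a layer's weights are frozen before the next layer starts learning. The
final pooled spike wave, reduced by a maximum over the temporal dimension
(= its last slice, by cumulativity), flattened in (channel, row, col)
order, is the binary feature vector handed to the classifier.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .competition_plasticity import (
    CompetitionConfig,
    PlasticityConfig,
    get_k_winners,
    lateral_inhibit_potentials,
    lr_schedule_step,
    pointwise_spike_inhibition,
    stdp_update,
)
from .filterbank import FilterBank, apply_filter_bank, default_filter_bank
from .spike_encoding import SpikeWave, encode_image_maps
from .spiking_conv import (
    BNState,
    ThresholdState,
    WeightTensor,
    batch_norm_potentials,
    conv_potentials,
    fire,
    init_weights,
    sample_threshold,
    update_test_threshold,
)

__all__ = [
    "LayerSpec",
    "NetworkConfig",
    "LayerState",
    "default_network_config",
    "build_layers",
    "pool_spikes",
    "forward_layer",
    "train_layerwise",
    "extract_features",
    "count_trainable_parameters",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LayerSpec:
    """Static description of one spiking convolutional layer."""

    out_channels: int
    kernel: int
    kwta: int
    inhibition_radius: int
    epochs: int
    threshold_mode: str = "adaptive"
    fixed_value: float = 1.0
    threshold_momentum: float = 0.9
    bn_enabled: bool = True
    threshold_source: str = "post_bn"  # "post_bn" | "pre_bn"
    lateral_inhibition: bool = True
    lr_doubling: bool = False


@dataclass(frozen=True)
class NetworkConfig:
    """Full architecture + training hyperparameters."""

    layers: tuple[LayerSpec, ...]
    t_max: int = 15
    norm_radius: int = 8
    binning: str = "rank"
    pool_window: int = 2
    pool_stride: int = 2
    pool_padding: int = 1
    spike_inhibition: bool = True  # between-layer pointwise spike inhibition
    stdp: PlasticityConfig = field(default_factory=PlasticityConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        if any(spec.epochs < 1 for spec in self.layers):
            raise ValueError("epochs must be >= 1")


def default_network_config(seed: int = 0) -> NetworkConfig:
    """Reference two-layer architecture and its published hyperparameters."""
    layer1 = LayerSpec(
        out_channels=16, kernel=5, kwta=5, inhibition_radius=2, epochs=2,
        lr_doubling=True,
    )
    layer2 = LayerSpec(
        out_channels=20, kernel=2, kwta=8, inhibition_radius=1, epochs=20,
    )
    return NetworkConfig(layers=(layer1, layer2), seed=seed)


@dataclass
class LayerState:
    """Mutable runtime state of one layer (weights, thresholds, BN, rates)."""

    spec: LayerSpec
    weights: WeightTensor
    threshold: ThresholdState
    bn: BNState
    plasticity: PlasticityConfig
    competition: CompetitionConfig
    trained: bool = False


def build_layers(cfg: NetworkConfig, in_channels: int = 6) -> list[LayerState]:
    """Initialize all layer states; weights are seeded per layer so adding a
    layer never perturbs earlier layers' initial weights."""
    layers = []
    fan_in = in_channels
    for idx, spec in enumerate(cfg.layers):
        rng = np.random.default_rng([cfg.seed, idx])
        weights = init_weights(
            (spec.out_channels, fan_in, spec.kernel, spec.kernel),
            rng_seed=rng, lb=cfg.stdp.lb, ub=cfg.stdp.ub,
        )
        layers.append(
            LayerState(
                spec=spec,
                weights=weights,
                threshold=ThresholdState(
                    mode=spec.threshold_mode,
                    fixed_value=spec.fixed_value,
                    momentum=spec.threshold_momentum,
                ),
                bn=BNState(enabled=spec.bn_enabled),
                plasticity=cfg.stdp,
                competition=CompetitionConfig(
                    kwta=spec.kwta, inhibition_radius=spec.inhibition_radius
                ),
            )
        )
        fan_in = spec.out_channels
    return layers


def pool_spikes(
    s: SpikeWave, window: int = 2, stride: int = 2, padding: int = 1
) -> SpikeWave:
    """Per-time-slice max pooling with zero padding.

    Output height = floor((H + 2 padding - window) / stride) + 1. Max
    pooling of a binary cumulative tensor stays binary and cumulative.
    """
    pooled = _pool_tensor(s.s, window, stride, padding)
    return SpikeWave(s=pooled.astype(s.s.dtype))


def _pool_tensor(arr: np.ndarray, window: int, stride: int, padding: int) -> np.ndarray:
    if padding:
        arr = np.pad(arr, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    if window > arr.shape[2] or window > arr.shape[3]:
        raise ValueError("pooling window larger than padded input")
    win = np.lib.stride_tricks.sliding_window_view(arr, (window, window), axis=(2, 3))
    return win[:, :, ::stride, ::stride].max(axis=(-2, -1))


def forward_layer(
    s_in: SpikeWave, layer: LayerState, training: bool
) -> tuple[SpikeWave, np.ndarray, np.ndarray]:
    """One layer's forward pass: conv -> BN -> threshold -> fire -> inhibit.

    In training mode with an adaptive threshold, the per-sample threshold
    (mean of the potential tensor) is used for firing and folded into the
    test-time EMA; in inference mode the stored test threshold (or the
    fixed value) is used. Returns (spikes, potentials, thresholded
    potentials), where potentials are the tensor firing was decided on.
    """
    v_raw = conv_potentials(s_in, layer.weights)
    if layer.bn.enabled:
        v_bn = batch_norm_potentials(v_raw, layer.bn, training=training)
        v = v_bn if layer.spec.threshold_source == "post_bn" else v_raw
    else:
        v = v_raw
    if layer.threshold.mode == "fixed":
        thr = layer.threshold.fixed_value
    elif training:
        thr = sample_threshold(v)
        update_test_threshold(layer.threshold, thr)
    else:
        thr = layer.threshold.inference_threshold()
    tp, spikes = fire(v, thr)
    if layer.spec.lateral_inhibition:
        tp, spikes = lateral_inhibit_potentials(tp, spikes)
    return spikes, v, tp


def _forward_frozen(
    wave: SpikeWave, layers: list[LayerState], cfg: NetworkConfig, upto: int
) -> SpikeWave:
    """Inference pass through layers [0, upto): conv block + pool (+ spike
    inhibition feeding the next layer)."""
    current = wave
    for layer in layers[:upto]:
        spikes, _, tp = forward_layer(current, layer, training=False)
        pooled = pool_spikes(spikes, cfg.pool_window, cfg.pool_stride, cfg.pool_padding)
        if cfg.spike_inhibition:
            tp_pooled = _pool_tensor(tp, cfg.pool_window, cfg.pool_stride, cfg.pool_padding)
            pooled = pointwise_spike_inhibition(pooled, tp_pooled)
        current = pooled
    return current


def encode_images(
    images,
    cfg: NetworkConfig,
    bank: FilterBank | None = None,
) -> list[SpikeWave]:
    """Run the filter-bank + spike encoder on a list of grayscale images."""
    bank = bank if bank is not None else default_filter_bank()
    waves = []
    for img in images:
        maps = apply_filter_bank(np.asarray(img, dtype=np.float64), bank)
        waves.append(
            encode_image_maps(
                maps, t_max=cfg.t_max, norm_radius=cfg.norm_radius, binning=cfg.binning
            )
        )
    return waves


def train_layerwise(
    images,
    cfg: NetworkConfig,
    bank: FilterBank | None = None,
    precoded: list[SpikeWave] | None = None,
) -> list[LayerState]:
    """Layer-wise unsupervised STDP training over the image set.

    For each layer in order: iterate ``epochs`` passes over every image,
    forwarding through the already-trained (frozen) prefix, firing the
    current layer in training mode, selecting WTA winners and applying the
    STDP update; layer 1 additionally runs the learning-rate doubling
    schedule. No labels are used. Frozen-prefix activations are cached per
    image since they never change during a layer's training.
    """
    if precoded is not None:
        waves = precoded
    else:
        images = list(images)
        if not images:
            raise ValueError("empty training set")
        waves = encode_images(images, cfg, bank)
    if not waves:
        raise ValueError("empty training set")
    layers = build_layers(cfg, in_channels=waves[0].shape[1])

    for li, layer in enumerate(layers):
        inputs = [_forward_frozen(w, layers, cfg, upto=li) for w in waves]
        images_seen = 0
        for _ in range(layer.spec.epochs):
            for s_in in inputs:
                spikes, _, tp = forward_layer(s_in, layer, training=True)
                winners = get_k_winners(tp, layer.competition, spikes)
                if winners:
                    layer.weights = stdp_update(
                        s_in, tp, spikes, winners, layer.weights, layer.plasticity
                    )
                images_seen += 1
                if layer.spec.lr_doubling:
                    layer.plasticity = lr_schedule_step(layer.plasticity, images_seen)
        layer.trained = True
    return layers


def extract_features(
    image,
    layers: list[LayerState],
    cfg: NetworkConfig,
    bank: FilterBank | None = None,
    wave: SpikeWave | None = None,
) -> np.ndarray:
    """Full inference pass yielding the 1-D binary spike feature vector.

    The final pooled spike wave is reduced by max over the temporal
    dimension (equal to its last slice under cumulative coding) and
    flattened in (channel, row, col) order.
    """
    if not all(layer.trained for layer in layers):
        raise RuntimeError("all layers must be trained before feature extraction")
    if wave is None:
        wave = encode_images([image], cfg, bank)[0]
    out = _forward_frozen(wave, layers, cfg, upto=len(layers))
    return out.s.max(axis=0).reshape(-1)


def count_trainable_parameters(cfg: NetworkConfig, in_channels: int = 6) -> int:
    """Number of trainable synapses (no biases): sum of Fout*Fin*kh*kw."""
    total = 0
    fan_in = in_channels
    for spec in cfg.layers:
        total += spec.out_channels * fan_in * spec.kernel * spec.kernel
        fan_in = spec.out_channels
    return total


def feature_dimension(cfg: NetworkConfig, input_size: tuple[int, int]) -> int:
    """Length of the extracted feature vector for a given input size."""
    h, w = input_size
    for spec in cfg.layers:
        h, w = h - spec.kernel + 1, w - spec.kernel + 1
        h = (h + 2 * cfg.pool_padding - cfg.pool_window) // cfg.pool_stride + 1
        w = (w + 2 * cfg.pool_padding - cfg.pool_window) // cfg.pool_stride + 1
    return cfg.layers[-1].out_channels * h * w


def save_model(directory, layers: list[LayerState], cfg: NetworkConfig) -> None:
    """Persist trained weights, thresholds and BN stats plus a JSON manifest."""
    os.makedirs(directory, exist_ok=True)
    arrays = {}
    meta = {"seed": cfg.seed, "t_max": cfg.t_max, "layers": []}
    for i, layer in enumerate(layers):
        arrays[f"weights_{i}"] = layer.weights.w
        if layer.bn.running_mean is not None:
            arrays[f"bn_mean_{i}"] = layer.bn.running_mean
            arrays[f"bn_var_{i}"] = layer.bn.running_var
        meta["layers"].append(
            {
                "spec": layer.spec.__dict__,
                "test_threshold": layer.threshold.test_threshold,
                "initialized": layer.threshold.initialized,
                "trained": layer.trained,
            }
        )
    np.savez_compressed(os.path.join(directory, "model.npz"), **arrays)
    meta["config"] = {
        "t_max": cfg.t_max, "norm_radius": cfg.norm_radius, "binning": cfg.binning,
        "pool_window": cfg.pool_window, "pool_stride": cfg.pool_stride,
        "pool_padding": cfg.pool_padding, "spike_inhibition": cfg.spike_inhibition,
        "seed": cfg.seed,
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(directory) -> tuple[list[LayerState], NetworkConfig]:
    with open(os.path.join(directory, "manifest.json")) as fh:
        meta = json.load(fh)
    specs = tuple(LayerSpec(**entry["spec"]) for entry in meta["layers"])
    cfg = NetworkConfig(layers=specs, **meta["config"])
    with np.load(os.path.join(directory, "model.npz")) as archive:
        layers = []
        for i, entry in enumerate(meta["layers"]):
            spec = specs[i]
            w = archive[f"weights_{i}"]
            state = LayerState(
                spec=spec,
                weights=WeightTensor(w=w, lb=cfg.stdp.lb, ub=cfg.stdp.ub),
                threshold=ThresholdState(
                    mode=spec.threshold_mode,
                    fixed_value=spec.fixed_value,
                    momentum=spec.threshold_momentum,
                    test_threshold=entry["test_threshold"],
                    initialized=entry["initialized"],
                ),
                bn=BNState(
                    enabled=spec.bn_enabled,
                    running_mean=archive[f"bn_mean_{i}"] if f"bn_mean_{i}" in archive else None,
                    running_var=archive[f"bn_var_{i}"] if f"bn_var_{i}" in archive else None,
                ),
                plasticity=cfg.stdp,
                competition=CompetitionConfig(
                    kwta=spec.kwta, inhibition_radius=spec.inhibition_radius
                ),
                trained=entry["trained"],
            )
            layers.append(state)
    return layers, cfg
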