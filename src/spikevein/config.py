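"""YAML configuration for the pipeline.

A single nested mapping drives the filter bank, the encoder, both spiking
layers and the STDP schedule. ``default_config()`` returns the reference
settings; ``load_config(path)`` deep-merges a user YAML file over them.
"""

from __future__ import annotations

import copy
import logging
import math

import yaml

from .competition_plasticity import PlasticityConfig
from .filterbank import FilterBank, default_filter_bank
from .network import LayerSpec, NetworkConfig

__all__ = ["default_config", "load_config", "bank_from_config", "network_from_config", "setup_logging"]


def default_config() -> dict:
    return {
        "image": {"size": [48, 48]},
        "filters": {
            "gabor": {
                "window": 15,
                "orientations": [3 * math.pi / 8, 5 * math.pi / 8, 7 * math.pi / 8, 9 * math.pi / 8],
            },
            "dog": {"window": 7, "pairs": [[1.0, 2.0], [2.0, 1.0]]},
            "cutoff": 50.0,
        },
        "encode": {"t_max": 15, "norm_radius": 8, "binning": "rank"},
        "pool": {"window": 2, "stride": 2, "padding": 1},
        "spike_inhibition": True,
        "layer1": {
            "out_channels": 16, "kernel": 5, "kwta": 5, "inhibition_radius": 2,
            "epochs": 2, "lr_doubling": True, "lateral_inhibition": True,
            "threshold": {"mode": "adaptive", "fixed_value": 1.0, "momentum": 0.9, "source": "post_bn"},
            "bn": {"enabled": True},
        },
        "layer2": {
            "out_channels": 20, "kernel": 2, "kwta": 8, "inhibition_radius": 1,
            "epochs": 20, "lr_doubling": False, "lateral_inhibition": True,
            "threshold": {"mode": "adaptive", "fixed_value": 1.0, "momentum": 0.9, "source": "post_bn"},
            "bn": {"enabled": True},
        },
        "stdp": {
            "a_plus": 0.004, "a_minus": -0.003, "lb": 0.0, "ub": 1.0, "eta": 1.0,
            "stabilizer": True, "double_every": 500, "rate_cap": 0.15,
        },
        "classifier": {"C": 2.4, "percentile": 100},
        "seed": 0,
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Defaults, with the YAML file at ``path`` (if any) merged on top."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def bank_from_config(cfg: dict) -> FilterBank:
    f = cfg["filters"]
    return default_filter_bank(
        gabor_window=f["gabor"]["window"],
        orientations=f["gabor"]["orientations"],
        dog_window=f["dog"]["window"],
        dog_pairs=[tuple(p) for p in f["dog"]["pairs"]],
        cutoff=f["cutoff"],
    )


def _layer_spec(layer: dict) -> LayerSpec:
    thr = layer["threshold"]
    return LayerSpec(
        out_channels=layer["out_channels"],
        kernel=layer["kernel"],
        kwta=layer["kwta"],
        inhibition_radius=layer["inhibition_radius"],
        epochs=layer["epochs"],
        threshold_mode=thr["mode"],
        fixed_value=thr["fixed_value"],
        threshold_momentum=thr["momentum"],
        bn_enabled=layer["bn"]["enabled"],
        threshold_source=thr.get("source", "post_bn"),
        lateral_inhibition=layer.get("lateral_inhibition", True),
        lr_doubling=layer.get("lr_doubling", False),
    )


def network_from_config(cfg: dict, seed: int | None = None) -> NetworkConfig:
    stdp = cfg["stdp"]
    specs = tuple(
        _layer_spec(cfg[name]) for name in sorted(k for k in cfg if k.startswith("layer"))
    )
    return NetworkConfig(
        layers=specs,
        t_max=cfg["encode"]["t_max"],
        norm_radius=cfg["encode"]["norm_radius"],
        binning=cfg["encode"]["binning"],
        pool_window=cfg["pool"]["window"],
        pool_stride=cfg["pool"]["stride"],
        pool_padding=cfg["pool"]["padding"],
        spike_inhibition=cfg["spike_inhibition"],
        stdp=PlasticityConfig(
            a_plus=stdp["a_plus"], a_minus=stdp["a_minus"], lb=stdp["lb"],
            ub=stdp["ub"], eta=stdp["eta"], use_stabilizer=stdp["stabilizer"],
            double_every=stdp["double_every"], rate_cap=stdp["rate_cap"],
        ),
        seed=cfg["seed"] if seed is None else seed,
    )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
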