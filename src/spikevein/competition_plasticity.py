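"""Lateral inhibition, winner-take-all competition, and STDP plasticity.

Learning is local and unsupervised. After a layer fires, lateral inhibition
keeps only the most salient neuron per spatial location (earliest spike,
then highest potential). A winner-take-all (WTA) pass then picks up to k
winners for plasticity — each winner silences its whole feature map and a
Chebyshev neighborhood across all maps, so different maps specialize on
different patterns. Winning kernels are updated by a simplified STDP rule
that depends only on spike order, with a multiplicative stabilizer
(W - LB)(UB - W) that freezes weights at their bounds:

    dW = A+ * (W - LB) * (UB - W)   if the presynaptic neuron fired no
                                    later than the postsynaptic one,
    dW = A- * (W - LB) * (UB - W)   otherwise.

A learning-rate schedule doubles A+ every ``double_every`` training images
(preserving the A-/A+ ratio) until A+ reaches ``rate_cap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spike_encoding import NEVER, SpikeWave, first_spike_times
from .spiking_conv import WeightTensor

__all__ = [
    "CompetitionConfig",
    "Winner",
    "PlasticityConfig",
    "lateral_inhibit_potentials",
    "pointwise_spike_inhibition",
    "get_k_winners",
    "stdp_update",
    "lr_schedule_step",
]


@dataclass(frozen=True)
class CompetitionConfig:
    """WTA parameters: number of winners and lateral-inhibition radius."""

    kwta: int = 5
    inhibition_radius: int = 2

    def __post_init__(self) -> None:
        if self.kwta < 1:
            raise ValueError("kwta must be >= 1")
        if self.inhibition_radius < 0:
            raise ValueError("inhibition_radius must be >= 0")


@dataclass(frozen=True)
class Winner:
    """One WTA winner: feature map and spatial position."""

    f: int
    h: int
    w: int


@dataclass(frozen=True)
class PlasticityConfig:
    """STDP rates, weight bounds and the learning-rate doubling schedule.

    ``a_minus / a_plus`` at construction time is remembered as the initial
    ratio, which the doubling schedule preserves.
    """

    a_plus: float = 0.004
    a_minus: float = -0.003
    lb: float = 0.0
    ub: float = 1.0
    eta: float = 1.0
    use_stabilizer: bool = True
    double_every: int = 500
    rate_cap: float = 0.15
    initial_ratio: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.a_plus > 0 > self.a_minus):
            raise ValueError("need a_plus > 0 > a_minus")
        if self.lb >= self.ub:
            raise ValueError("lb must be < ub")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.initial_ratio is None:
            object.__setattr__(self, "initial_ratio", self.a_minus / self.a_plus)


_BIG = np.iinfo(np.int64).max


def _first_times_and_values(tp: np.ndarray, spikes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per neuron: first-spike time (BIG if silent) and the potential at it."""
    T = spikes.shape[0]
    t_first = first_spike_times(spikes)
    fired = t_first != NEVER
    t_idx = np.where(fired, t_first, 0)
    val_at_first = np.take_along_axis(tp, t_idx[None], axis=0)[0]
    t_key = np.where(fired, t_first, _BIG)
    val = np.where(fired, val_at_first, -np.inf)
    return t_key, val


def _pixel_winner_mask(tp: np.ndarray, spikes: np.ndarray) -> np.ndarray:
    """Boolean F x H x W mask keeping, per pixel, the winning channel.

    Winner = earliest first-spike time; ties broken by larger potential at
    that time, then by lower channel index. Pixels where no channel fired
    keep all channels (there is nothing to suppress).
    """
    t_key, val = _first_times_and_values(tp, spikes)
    any_fired = (t_key != _BIG).any(axis=0)
    min_t = t_key.min(axis=0)
    candidates = t_key == min_t[None]
    val_masked = np.where(candidates, val, -np.inf)
    winner = np.argmax(val_masked, axis=0)  # ties -> lowest channel
    F = tp.shape[1]
    mask = winner[None] == np.arange(F)[:, None, None]
    return np.where(any_fired[None], mask, True)


def lateral_inhibit_potentials(
    tp: np.ndarray, spikes: SpikeWave
) -> tuple[np.ndarray, SpikeWave]:
    """Suppress all but one channel per spatial location.

    The surviving channel has the earliest first-spike time (ties: higher
    potential at that time, then lower channel index); all other channels
    are zeroed across every time step in both the thresholded potentials
    and the spike wave.
    """
    if tp.shape != spikes.s.shape:
        raise ValueError("tensor shapes must match")
    if tp.shape[1] == 1:
        return tp, spikes
    mask = _pixel_winner_mask(tp, spikes.s)
    return tp * mask[None], SpikeWave(s=spikes.s * mask[None].astype(spikes.s.dtype))


def pointwise_spike_inhibition(spikes: SpikeWave, tp: np.ndarray) -> SpikeWave:
    """Same winner rule, applied to the spike wave feeding the next layer."""
    _, out = lateral_inhibit_potentials(tp, spikes)
    return out


def get_k_winners(
    tp: np.ndarray, cfg: CompetitionConfig, spikes: SpikeWave
) -> list[Winner]:
    """Iterative winner-take-all selection.

    Each pick is the eligible neuron with the earliest first-spike time
    (ties: highest potential at that time, then lowest (f, h, w)). After a
    pick, the whole winning feature map and the Chebyshev-radius spatial
    neighborhood across all maps become ineligible. Stops early once no
    eligible neuron has fired.
    """
    s = spikes.s
    if tp.shape != s.shape:
        raise ValueError("tensor shapes must match")
    F, H, W = tp.shape[1:]
    t_key, val = _first_times_and_values(tp, s)
    eligible = np.ones((F, H, W), dtype=bool)
    r = cfg.inhibition_radius
    winners: list[Winner] = []
    for _ in range(cfg.kwta):
        cand_t = np.where(eligible, t_key, _BIG)
        best_t = cand_t.min()
        if best_t == _BIG:
            break  # nothing eligible fired
        at_best = cand_t == best_t
        cand_val = np.where(at_best, val, -np.inf)
        f, h, w = np.unravel_index(np.argmax(cand_val), cand_val.shape)
        winners.append(Winner(int(f), int(h), int(w)))
        eligible[f] = False  # feature inhibition
        if r > 0:
            eligible[:, max(0, h - r) : h + r + 1, max(0, w - r) : w + r + 1] = False
    return winners


def stdp_update(
    input_spikes: SpikeWave,
    tp: np.ndarray,
    output_spikes: SpikeWave,
    winners: list[Winner],
    weights: WeightTensor,
    cfg: PlasticityConfig,
) -> WeightTensor:
    """Apply the order-based STDP rule at every winner's receptive field.

    With cumulative coding, "pre fired no later than post" is equivalent to
    the pre synapse's spike count over time being at least the winner's
    spike count tau_post, which is how pairing is evaluated. Only winning
    feature maps' kernels change; everything is clamped back to [lb, ub].
    """
    if not winners:
        raise ValueError("winners must be nonempty")
    w = weights.w.copy()
    Fout, Fin, kh, kw = w.shape
    in_arr = input_spikes.s
    H_in, W_in = in_arr.shape[2:]
    for win in winners:
        if not (0 <= win.f < Fout and 0 <= win.h <= H_in - kh and 0 <= win.w <= W_in - kw):
            raise ValueError(f"winner {win} out of bounds")
        tau_post = output_spikes.s[:, win.f, win.h, win.w].sum()
        pre_window = in_arr[:, :, win.h : win.h + kh, win.w : win.w + kw]
        pairing = pre_window.sum(axis=0) >= tau_post  # Fin x kh x kw
        dw = np.where(pairing, cfg.a_plus, cfg.a_minus)
        if cfg.use_stabilizer:
            dw = dw * (w[win.f] - cfg.lb) * (cfg.ub - w[win.f])
        w[win.f] = np.clip(w[win.f] + cfg.eta * dw, cfg.lb, cfg.ub)
    return WeightTensor(w=w, lb=weights.lb, ub=weights.ub)


def lr_schedule_step(cfg: PlasticityConfig, images_seen: int) -> PlasticityConfig:
    """Double A+ at every ``double_every``-image boundary below the rate cap.

    A- is rescaled so A-/A+ keeps its initial ratio. Returns a new config
    (unchanged when no boundary is crossed or the cap is reached).
    """
    if images_seen < 0:
        raise ValueError("images_seen must be >= 0")
    if (
        cfg.a_plus < cfg.rate_cap
        and images_seen > 0
        and images_seen % cfg.double_every == 0
    ):
        new_plus = cfg.a_plus * 2.0
        return replace(cfg, a_plus=new_plus, a_minus=new_plus * cfg.initial_ratio)
    return cfg
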