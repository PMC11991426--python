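"""Lateral inhibition, winner-take-all selection, and STDP updates."""

import numpy as np
import pytest

from spikevein import (
    CompetitionConfig,
    PlasticityConfig,
    SpikeWave,
    WeightTensor,
    Winner,
    get_k_winners,
    lateral_inhibit_potentials,
    lr_schedule_step,
    pointwise_spike_inhibition,
    stdp_update,
)
from spikevein.spike_encoding import NEVER, first_spike_times
from conftest import random_cumulative_spikes


def make_tp(rng, spikes):
    """Thresholded potentials consistent with a spike wave: positive where
    spiking, growing in t, zero elsewhere."""
    T = spikes.s.shape[0]
    base = rng.uniform(0.1, 5.0, size=spikes.s.shape[1:])
    growth = np.cumsum(rng.uniform(0, 0.5, size=spikes.s.shape), axis=0)
    return (base[None] + growth) * spikes.s


def pixel_winner_oracle(tp, s):
    """Per-pixel lexicographic-min winner on (first-spike time, -potential
    at that time, channel index); None when no channel fired."""
    T, F, H, W = s.shape
    winners = {}
    for h in range(H):
        for w in range(W):
            best = None
            for f in range(F):
                times = np.flatnonzero(s[:, f, h, w])
                if times.size == 0:
                    continue
                t0 = times[0]
                key = (t0, -tp[t0, f, h, w], f)
                if best is None or key < best[0]:
                    best = (key, f)
            if best is not None:
                winners[(h, w)] = best[1]
    return winners


def k_winners_oracle(tp, s, kwta, r):
    """Exhaustive WTA: rescan eligibility after every pick."""
    T, F, H, W = s.shape
    eligible = np.ones((F, H, W), dtype=bool)
    out = []
    for _ in range(kwta):
        best = None
        for f in range(F):
            for h in range(H):
                for w in range(W):
                    if not eligible[f, h, w]:
                        continue
                    times = np.flatnonzero(s[:, f, h, w])
                    if times.size == 0:
                        continue
                    t0 = times[0]
                    key = (t0, -tp[t0, f, h, w], f, h, w)
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        _, _, f, h, w = best
        out.append((f, h, w))
        eligible[f] = False
        if r > 0:
            eligible[:, max(0, h - r) : h + r + 1, max(0, w - r) : w + r + 1] = False
    return out


class TestLateralInhibition:
    def test_single_channel_identity(self, rng):
        s = random_cumulative_spikes(rng, 4, 1, 5, 5)
        tp = make_tp(rng, s)
        tp2, s2 = lateral_inhibit_potentials(tp, s)
        np.testing.assert_array_equal(tp2, tp)
        np.testing.assert_array_equal(s2.s, s.s)

    def test_earliest_spike_wins_regardless_of_potential(self):
        # channel 0 fires at t=1 with small potential, channel 1 at t=2 huge
        s = np.zeros((4, 2, 1, 1), dtype=np.uint8)
        s[1:, 0] = 1
        s[2:, 1] = 1
        tp = np.zeros((4, 2, 1, 1))
        tp[1:, 0] = 0.1
        tp[2:, 1] = 99.0
        tp2, s2 = lateral_inhibit_potentials(tp, SpikeWave(s=s))
        assert s2.s[:, 0].sum() == 3 and s2.s[:, 1].sum() == 0
        assert np.all(tp2[:, 1] == 0)

    def test_matches_pixel_oracle(self, rng):
        for _ in range(5):
            s = random_cumulative_spikes(rng, 5, 4, 6, 6)
            tp = make_tp(rng, s)
            tp2, s2 = lateral_inhibit_potentials(tp, s)
            expected = pixel_winner_oracle(tp, s.s)
            for h in range(6):
                for w in range(6):
                    for f in range(4):
                        if (h, w) in expected and f != expected[(h, w)]:
                            assert s2.s[:, f, h, w].sum() == 0
                            assert np.all(tp2[:, f, h, w] == 0)
                        else:
                            np.testing.assert_array_equal(
                                s2.s[:, f, h, w], s.s[:, f, h, w]
                            )


class TestPointwiseSpikeInhibition:
    def test_zero_spikes_stay_zero(self):
        s = SpikeWave(s=np.zeros((3, 2, 4, 4), dtype=np.uint8))
        out = pointwise_spike_inhibition(s, np.zeros((3, 2, 4, 4)))
        assert out.s.sum() == 0

    def test_at_most_one_channel_per_pixel(self, rng):
        s = random_cumulative_spikes(rng, 4, 5, 6, 6, p_never=0.2)
        out = pointwise_spike_inhibition(s, make_tp(rng, s))
        fired = out.s[-1]  # final slice: who fired at all
        assert np.all(fired.sum(axis=0) <= 1)

    def test_removal_only(self, rng):
        s = random_cumulative_spikes(rng, 4, 3, 5, 5)
        out = pointwise_spike_inhibition(s, make_tp(rng, s))
        assert np.all(out.s <= s.s)


class TestGetKWinners:
    def test_silent_input_yields_no_winners(self):
        s = SpikeWave(s=np.zeros((3, 4, 5, 5), dtype=np.uint8))
        winners = get_k_winners(np.zeros((3, 4, 5, 5)), CompetitionConfig(3, 1), s)
        assert winners == []

    def test_structural_constraints(self, rng):
        for _ in range(20):
            s = random_cumulative_spikes(rng, 4, 5, 6, 6, p_never=0.4)
            tp = make_tp(rng, s)
            r = int(rng.integers(1, 3))
            winners = get_k_winners(tp, CompetitionConfig(4, r), s)
            maps = [w.f for w in winners]
            assert len(maps) == len(set(maps))  # distinct feature maps
            for i, a in enumerate(winners):
                for b in winners[i + 1 :]:
                    cheb = max(abs(a.h - b.h), abs(a.w - b.w))
                    assert cheb > r

    def test_matches_exhaustive_oracle(self, rng):
        agree = 0
        n_instances = 200
        for _ in range(n_instances):
            s = random_cumulative_spikes(rng, 5, 5, 6, 6, p_never=0.35)
            tp = make_tp(rng, s)
            kwta = int(rng.integers(1, 5))
            r = int(rng.integers(0, 3))
            got = [(w.f, w.h, w.w) for w in get_k_winners(tp, CompetitionConfig(kwta, r), s)]
            if got == k_winners_oracle(tp, s.s, kwta, r):
                agree += 1
        assert agree == n_instances


class TestStdpUpdate:
    def _one_synapse(self, t_pre, t_post, T=4, w0=0.5, cfg=None):
        """1-in/1-out single-synapse network; t == T means never fires."""
        cfg = cfg or PlasticityConfig()
        s_in = np.zeros((T, 1, 1, 1), dtype=np.uint8)
        if t_pre < T:
            s_in[t_pre:] = 1
        s_out = np.zeros((T, 1, 1, 1), dtype=np.uint8)
        if t_post < T:
            s_out[t_post:] = 1
        tp = s_out.astype(float)
        w = WeightTensor(w=np.full((1, 1, 1, 1), w0), lb=cfg.lb, ub=cfg.ub)
        new = stdp_update(
            SpikeWave(s=s_in), tp, SpikeWave(s=s_out), [Winner(0, 0, 0)], w, cfg
        )
        return new.w[0, 0, 0, 0] - w0

    def test_potentiation_hand_case(self):
        # pre t=1, post t=2, W=0.5, A+=0.004: dW = 0.004 * 0.5 * 0.5 = 0.001
        dw = self._one_synapse(t_pre=1, t_post=2)
        assert dw == pytest.approx(0.001, abs=1e-12)

    def test_stabilizer_freezes_at_bounds(self):
        for w0 in (0.0, 1.0):
            assert self._one_synapse(1, 2, w0=w0) == pytest.approx(0.0, abs=1e-15)

    def test_silent_pre_is_depressed(self):
        dw = self._one_synapse(t_pre=4, t_post=1)  # pre never fires
        assert dw < 0

    def test_post_before_pre_is_depressed(self):
        dw = self._one_synapse(t_pre=3, t_post=1)
        assert dw < 0

    def test_pairing_rule_equals_spike_order_exhaustively(self):
        """Counting rule (sum_t pre >= tau_post) == order rule (t_pre <=
        t_post, never = +inf), for every cumulative pattern up to T=6."""
        for T in range(1, 7):
            for t_pre in range(T + 1):  # T means never
                for t_post in range(T):  # winners always fired
                    dw = self._one_synapse(t_pre, t_post, T=T)
                    order_pairs = t_pre <= t_post  # never (= T) > any t_post
                    assert (dw > 0) == order_pairs and (dw < 0) == (not order_pairs)

    def test_only_winning_maps_change_and_bounds_hold(self, rng):
        cfg = PlasticityConfig(a_plus=0.1, a_minus=-0.08)
        w = WeightTensor(w=rng.uniform(0.05, 0.95, size=(4, 2, 2, 2)))
        for _ in range(1000):
            s_in = random_cumulative_spikes(rng, 3, 2, 4, 4)
            s_out = random_cumulative_spikes(rng, 3, 4, 3, 3)
            tp = make_tp(rng, s_out)
            fired = first_spike_times(s_out.s)
            candidates = np.argwhere(fired != NEVER)
            if candidates.size == 0:
                continue
            f, h, w_ = candidates[rng.integers(len(candidates))]
            before = w.w.copy()
            w = stdp_update(s_in, tp, s_out, [Winner(int(f), int(h), int(w_))], w, cfg)
            assert w.w.min() >= 0.0 and w.w.max() <= 1.0
            others = [m for m in range(4) if m != f]
            np.testing.assert_array_equal(w.w[others], before[others])

    def test_winner_out_of_bounds_rejected(self, rng):
        s_in = random_cumulative_spikes(rng, 3, 2, 4, 4)
        s_out = random_cumulative_spikes(rng, 3, 4, 3, 3)
        w = WeightTensor(w=np.full((4, 2, 2, 2), 0.5))
        with pytest.raises(ValueError):
            stdp_update(s_in, make_tp(rng, s_out), s_out, [Winner(0, 3, 0)], w, PlasticityConfig())


class TestLearningRateSchedule:
    def test_doubling_preserves_ratio(self):
        cfg = PlasticityConfig(a_plus=0.004, a_minus=-0.003)
        out = lr_schedule_step(cfg, images_seen=500)
        assert out.a_plus == pytest.approx(0.008)
        assert out.a_minus == pytest.approx(-0.006)

    def test_no_change_off_boundary(self):
        cfg = PlasticityConfig()
        assert lr_schedule_step(cfg, 499) is cfg
        assert lr_schedule_step(cfg, 0) is cfg

    def test_cap_stops_doubling(self):
        cfg = PlasticityConfig(a_plus=0.16, a_minus=-0.12)
        assert lr_schedule_step(cfg, 500) is cfg

    def test_ratio_invariant_over_many_doublings(self):
        cfg = PlasticityConfig(a_plus=0.004, a_minus=-0.003)
        ratio0 = cfg.a_minus / cfg.a_plus
        for k in range(1, 6):
            cfg = lr_schedule_step(cfg, 500 * k)
        assert cfg.a_minus / cfg.a_plus == pytest.approx(ratio0, abs=1e-12)
        assert cfg.a_plus == pytest.approx(0.004 * 2**5)
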