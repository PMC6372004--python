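"""Additive STDP with homeostatic LTD, and optimality classification."""

import numpy as np
import pytest

from spikepattern import plasticity, spikegen
from spikepattern.plasticity import STDPConfig
from spikepattern.spikegen import PatternConfig, SpikeTrainSet


class TestInitialWeight:
    def test_reference_values(self):
        w_hi = plasticity.initial_weight(370, 0.018, 3.2, 10_000)
        w_lo = plasticity.initial_weight(250, 0.018, 3.2, 10_000)
        assert round(w_hi, 2) == 0.68
        # self-consistency of the rule: V_noise_mean = theta + 2 sigma_noise
        tfn = 0.018 * 3.2 * 10_000
        for theta, w0 in ((370, w_hi), (250, w_lo)):
            assert w0 * tfn == pytest.approx(theta + 2 * w0 * np.sqrt(tfn / 2))

    def test_linear_in_theta(self):
        w1 = plasticity.initial_weight(100, 0.018, 3.2, 10_000)
        w2 = plasticity.initial_weight(300, 0.018, 3.2, 10_000)
        assert w2 == pytest.approx(3 * w1)

    def test_rejects_tiny_networks(self):
        with pytest.raises(ValueError):
            plasticity.initial_weight(10, 0.018, 3.2, 5)


class TestSimulateStdp:
    def test_single_pair_rule(self):
        """One pre spike then one forced post spike: the paired synapse
        changes by dApre * exp(-delta/tau_pre) + w_out, silent synapses by
        w_out, and the trigger synapse (same-bin spike) by dApre + w_out."""
        delta = 0.005
        cfg = STDPConfig(theta=5.0, w_out=-1e-3, dApre=0.01, tau_pre=0.02)
        # afferent 0: pre spike at t; afferent 1: trigger (weight >= theta);
        # afferent 2: silent
        spikes = SpikeTrainSet(
            afferents=np.array([0, 1]), times=np.array([0.01, 0.01 + delta]),
            duration=0.05, N=3,
        )
        w0 = np.array([0.5, 1.0, 0.5])
        # theta = 1 reachable by afferent 1 alone through weight 1
        cfg = STDPConfig(theta=0.9, w_out=-1e-3, dApre=0.01, tau_pre=0.02)
        w, posts, dead = plasticity.simulate_stdp(spikes, w0, cfg)
        assert not dead
        assert len(posts) == 1
        d_paired = w[0] - 0.5
        d_trigger = w[1] - 1.0  # clipped at 1: dApre + w_out > 0 -> stays 1
        d_silent = w[2] - 0.5
        # spikes are stamped on the 0.1-ms bin grid, so the pair interval is
        # accurate to one bin: tolerance dApre * dt_bin / tau_pre
        assert d_paired == pytest.approx(0.01 * np.exp(-delta / 0.02) - 1e-3, abs=1e-4)
        assert d_trigger == 0.0
        assert d_silent == pytest.approx(-1e-3, abs=1e-9)

    def test_pure_ltp_saturates_weights(self):
        """w_out ~ 0 and steady firing drive every weight to 1."""
        rng = np.random.default_rng(0)
        N, rate, dur = 20, 50.0, 5.0
        k = rng.poisson(N * rate * dur)
        spikes = SpikeTrainSet(
            afferents=np.sort(rng.integers(0, N, k)).astype(np.int64),
            times=np.sort(rng.uniform(0, dur, k)),
            duration=dur,
            N=N,
        )
        order = np.lexsort((spikes.afferents, spikes.times))
        spikes.afferents = spikes.afferents[order]
        spikes.times = spikes.times[order]
        cfg = STDPConfig(theta=3.0, w_out=-1e-9, dApre=0.01, tau_pre=0.02)
        w, posts, _ = plasticity.simulate_stdp(spikes, np.full(N, 0.3), cfg)
        assert len(posts) > 50
        assert np.all(w > 0.99)

    def test_weights_stay_in_bounds(self):
        cfg = PatternConfig(N=2000, f=3.2, L=0.1, T=0.0032, interval=0.4,
                            n_presentations=60, seed=3)
        pattern = spikegen.generate_pattern(cfg)
        session, _ = spikegen.build_session(pattern, cfg)
        stdp = STDPConfig(theta=74.0, w_out=-3.5e-3)
        w0 = np.full(2000, plasticity.initial_weight(74.0, 0.018, 3.2, 2000))
        w, posts, _ = plasticity.simulate_stdp(session, w0, stdp)
        assert np.all(w >= 0.0) and np.all(w <= 1.0)
        assert len(posts) > 0

    def test_dead_neuron_reported_not_hung(self):
        cfg = PatternConfig(N=200, f=3.2, L=0.1, T=0.0, interval=0.4,
                            n_presentations=60, seed=1)
        pattern = spikegen.generate_pattern(cfg)
        out = plasticity.run_stdp(pattern, cfg, STDPConfig(theta=1e7, w_out=-1e-3))
        assert out.dead
        assert out.post_spike_times.size == 0


class TestClassifyOptimal:
    def test_exact_indicator_is_optimal(self, small_pattern):
        sel = spikegen.select_afferents(small_pattern, 1, 0.023, 0.0)
        w = np.zeros(small_pattern.N)
        w[sel.selected] = 1.0
        ok, window = plasticity.classify_optimal(w, small_pattern, 0.023)
        assert ok
        assert window[1] == pytest.approx(0.023, rel=0.1)

    def test_all_reinforced_is_not_optimal(self, small_pattern):
        ok, _ = plasticity.classify_optimal(
            np.ones(small_pattern.N), small_pattern, 0.023
        )
        assert not ok

    def test_wrong_duration_fails_margin(self, small_pattern):
        sel = spikegen.select_afferents(small_pattern, 1, 0.040, 0.0)
        w = np.zeros(small_pattern.N)
        w[sel.selected] = 1.0
        ok, window = plasticity.classify_optimal(w, small_pattern, 0.023)
        assert not ok
        assert window[1] == pytest.approx(0.040, abs=0.002)

    def test_unconverged_weights_rejected(self, small_pattern):
        w = np.full(small_pattern.N, 0.5)
        ok, window = plasticity.classify_optimal(w, small_pattern, 0.023)
        assert not ok and window is None

    def test_offset_window_found(self, small_pattern):
        sel = spikegen.select_afferents(small_pattern, 1, 0.022, 0.030)
        w = np.zeros(small_pattern.N)
        w[sel.selected] = 1.0
        ok, window = plasticity.classify_optimal(w, small_pattern, 0.023)
        assert ok
        assert window[0] == pytest.approx(0.030, abs=0.002)

    def test_matches_brute_force_scan(self):
        """Oracle equivalence on small fixtures: exhaustive (t0, t1) scan at
        0.1-ms resolution agrees with the kernel's verdict."""
        rng = np.random.default_rng(8)
        for trial in range(6):
            cfg = PatternConfig(N=60, f=8.0, L=0.05, seed=100 + trial)
            pat = spikegen.generate_pattern(cfg)
            dt_opt = 0.015
            # random reinforced set: sometimes a window's set, sometimes not
            if trial % 2 == 0:
                t0 = float(rng.uniform(0, 0.03))
                sel = spikegen.select_afferents(pat, 1, 0.015, t0)
                S = sel.selected
            else:
                S = rng.choice(60, size=rng.integers(5, 25), replace=False)
            w = np.zeros(60)
            w[S] = 1.0
            ours, _ = plasticity.classify_optimal(w, pat, dt_opt)
            # brute force: any window with duration within 10% and symmetric
            # difference <= 5% of |S|
            grid = 1e-4
            ok = False
            Sset = set(S.tolist())
            for b0 in np.arange(0, 0.05, grid):
                for b1 in np.arange(b0 + 0.0135, min(b0 + 0.0165, 0.05), grid):
                    m = (pat.times >= b0 - 1e-12) & (pat.times < b1 - 1e-12)
                    selw = set(pat.afferents[m].tolist())
                    if len(selw ^ Sset) <= 0.05 * len(Sset):
                        ok = True
                        break
                if ok:
                    break
            assert ours == ok, f"trial {trial}: kernel {ours} vs brute {ok}"


class TestLearningEndToEnd:
    @pytest.fixture(scope="class")
    def mode1_outcome(self):
        cfg = PatternConfig(N=10_000, f=3.2, L=0.1, T=0.0032, interval=0.4,
                            n_presentations=500, seed=1)
        pattern = spikegen.generate_pattern(cfg)
        out = plasticity.run_stdp(
            pattern, cfg, STDPConfig(theta=370.0, w_out=-3.5e-3), dt_opt=0.023
        )
        return pattern, out

    def test_mode1_phenomenology(self, mode1_outcome):
        """High threshold + strong LTD: ~1 postsynaptic spike per
        presentation, bimodal weights."""
        _, out = mode1_outcome
        assert not out.dead
        assert out.converged
        assert out.spikes_per_presentation == pytest.approx(1.0, abs=0.25)
        w = out.final_weights
        assert np.mean(np.minimum(w, 1 - w) <= 0.05) >= 0.95

    def test_selectivity_precedes_convergence(self, mode1_outcome):
        """Postsynaptic spikes confine to presentation windows long before
        the weights binarize."""
        _, out = mode1_outcome
        posts = out.post_spike_times
        early = posts[(posts > 20.0) & (posts < 60.0)]  # pres. 50-150 of 500
        onset0, interval, L, T = 0.15, 0.4, 0.1, 0.0032
        rel = (early - onset0) % interval
        frac_in = np.mean(rel <= L + 2 * T)
        assert frac_in >= 0.90

    def test_learned_window_at_pattern_start(self, mode1_outcome):
        """STDP tracks back through the pattern: when learning anchors, the
        matched window starts in the first half of the pattern."""
        _, out = mode1_outcome
        assert out.matched_window is not None
        assert out.matched_window[0] < 0.05
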