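"""Clock-based LIF simulation and SNR measurement.

The simulator integrates ``tau dV/dt = -V + tau * sum_i w_i delta(t - t_i)``
by forward Euler on a fixed bin (default 0.1 ms):

    V[k+1] = V[k] * (1 - dt/tau) + sum of w_i over spikes in bin k.

Potential is expressed in unit-EPSP units: one spike through weight ``w``
deflects ``V`` by exactly ``w``.  With a threshold ``theta`` configured the
neuron spikes and resets to 0 (no refractory period); threshold-free traces
are used for SNR measurement, where

    SNR = (mean per-presentation peak - noise mean) / noise s.d.

with noise statistics taken from bins farther than ``5 tau`` after any
presentation window (decay transients excluded) and peaks searched on
``[onset - T, onset + L + T]`` (jitter can push the peak slightly out of
the nominal window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import analytic, spikegen
from ._kernels import lif_threshold_kernel
from .spikegen import PatternConfig, SpikeTrainSet

__all__ = [
    "LIFConfig",
    "PotentialTrace",
    "SNREstimate",
    "simulate_lif",
    "measure_snr",
    "validate_theory",
]


@dataclass
class LIFConfig:
    """Detector parameters.

    ``theta=None`` tracks the free (threshold-less) potential.  ``weights``
    is a per-afferent array in [0, 1]; index ``i`` weights afferent ``i``.
    """

    tau: float
    weights: np.ndarray
    theta: Optional[float] = None
    dt_bin: float = 1e-4

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.dt_bin > self.tau / 10.0:
            raise ValueError("dt_bin must be <= tau/10 for a faithful Euler step")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class PotentialTrace:
    """Simulated membrane potential on the Euler grid plus output spikes."""

    times: np.ndarray
    V: np.ndarray
    out_spikes: np.ndarray  # s; empty when threshold-free
    dt_bin: float


@dataclass
class SNREstimate:
    """Empirical SNR of one threshold-free trace (one pattern)."""

    v_max_mean: float
    noise_mean: float
    noise_sd: float
    snr: float
    n_presentations: int


def _binned_input(spikes: SpikeTrainSet, weights: np.ndarray, dt: float, n_bins: int):
    idx = np.floor(spikes.times / dt).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    return np.bincount(idx, weights=weights[spikes.afferents], minlength=n_bins)


def simulate_lif(spikes: SpikeTrainSet, config: LIFConfig) -> PotentialTrace:
    """Forward-Euler integration of the LIF driven by ``spikes``.

    Spikes in bin ``k`` act on the update from ``t_k`` to ``t_{k+1}``; a
    threshold crossing is recorded at ``t_{k+1}`` and resets the potential
    to 0, with the next bin's inputs integrating on top of the reset value.
    """
    if config.weights.size != spikes.N:
        raise ValueError("weights length must equal the afferent count N")
    dt = config.dt_bin
    n_bins = int(np.ceil(spikes.duration / dt - 1e-9))
    s = _binned_input(spikes, config.weights, dt, n_bins)
    alpha = 1.0 - dt / config.tau
    if config.theta is None:
        # linear recursion V[k+1] = alpha*V[k] + s[k]
        V = np.empty(n_bins + 1)
        V[0] = 0.0
        V[1:] = lfilter([1.0], [1.0, -alpha], s)
        out = np.empty(0)
    else:
        V, out_idx = lif_threshold_kernel(s, alpha, float(config.theta))
        out = out_idx * dt
    times = np.arange(n_bins + 1) * dt
    return PotentialTrace(times=times, V=V, out_spikes=out, dt_bin=dt)


def measure_snr(
    trace: PotentialTrace,
    onsets: Sequence[float],
    L: float,
    T: float,
    tau: float,
    buffer_factor: float = 5.0,
) -> SNREstimate:
    """Empirical SNR of a threshold-free trace.

    Per-presentation peaks are taken over ``[onset - T, onset + L + T]``;
    noise mean/s.d. over bins farther than ``buffer_factor * tau`` after any
    presentation window.  Raises when no noise bins remain or when the noise
    s.d. degenerates to 0.
    """
    if trace.out_spikes.size:
        raise ValueError("SNR measurement needs a threshold-free trace")
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("need at least one presentation onset")
    t = trace.times
    vmaxes = np.empty(onsets.size)
    noise_mask = np.ones(t.size, bool)
    for j, onset in enumerate(onsets):
        lo = np.searchsorted(t, onset - T)
        hi = np.searchsorted(t, onset + L + T, side="right")
        if hi <= lo:
            raise ValueError("presentation window contains no bins")
        vmaxes[j] = trace.V[lo:hi].max()
        cut = np.searchsorted(t, onset + L + T + buffer_factor * tau, side="right")
        noise_mask[lo:cut] = False
    if not noise_mask.any():
        raise ValueError("no noise bins remain outside presentation windows")
    noise = trace.V[noise_mask]
    noise_mean = float(noise.mean())
    noise_sd = float(noise.std(ddof=1))
    if noise_sd == 0.0:
        raise ValueError("degenerate noise: sigma = 0")
    v_max_mean = float(vmaxes.mean())
    return SNREstimate(
        v_max_mean=v_max_mean,
        noise_mean=noise_mean,
        noise_sd=noise_sd,
        snr=(v_max_mean - noise_mean) / noise_sd,
        n_presentations=int(onsets.size),
    )


def validate_theory(
    f: float,
    N: int,
    L: float,
    strategies: Sequence[int],
    T_grid: Sequence[float],
    n_patterns: int,
    n_presentations: int,
    seed: int,
    tau: float = 0.018,
    interval: float = 0.4,
    dt_bin: float = 1e-4,
) -> pd.DataFrame:
    """Compare simulated and closed-form SNR over a jitter grid.

    For each (strategy, T): generate ``n_patterns`` frozen patterns, wire the
    detector per Strategy #n with ``dt_window = L`` (unit weights on the
    selected afferents), replay each pattern ``n_presentations`` times and
    measure the SNR of the threshold-free trace.  Only the selected
    afferents are simulated — the others carry zero weight and cannot move
    the potential.

    Returns one row per (strategy, T) with the mean and s.d. of the
    simulated SNR across patterns and the theoretical value.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for n in strategies:
        for T in T_grid:
            theory = float(analytic.snr_value(f, T, N, tau, L, n))
            snrs = np.empty(n_patterns)
            for p in range(n_patterns):
                child = int(
                    np.random.SeedSequence(
                        seed, spawn_key=(n, int(round(T * 1e6)), p)
                    ).generate_state(1)[0]
                    % 2**31
                )
                cfg = PatternConfig(
                    N=N,
                    f=f,
                    L=L,
                    T=T,
                    interval=interval,
                    n_presentations=n_presentations,
                    seed=child,
                )
                pattern = spikegen.generate_pattern(cfg)
                sel = spikegen.select_afferents(pattern, n, dt_window=L, t0=0.0, f=f)
                weights = np.zeros(N)
                weights[sel.selected] = 1.0
                session, onsets = spikegen.build_session(
                    pattern, cfg, afferents=sel.selected
                )
                trace = simulate_lif(
                    session, LIFConfig(tau=tau, weights=weights, dt_bin=dt_bin)
                )
                snrs[p] = measure_snr(trace, onsets, L, T, tau).snr
            rows.append(
                dict(
                    strategy=n,
                    T=T,
                    snr_sim_mean=float(snrs.mean()),
                    snr_sim_sd=float(snrs.std(ddof=1)) if n_patterns > 1 else 0.0,
                    snr_theory=theory,
                    n_patterns=n_patterns,
                    n_presentations=n_presentations,
                    tau=tau,
                )
            )
    return pd.DataFrame(rows)
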