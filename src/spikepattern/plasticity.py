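"""Unsupervised STDP learning of a repeating spike pattern.

A LIF with plastic weights ``w_i in [0, 1]`` listens to all ``N`` afferents.
Learning is additive all-to-all LTP driven by a presynaptic trace, with a
homeostatic depression term standing in for LTD:

* each synapse carries a trace ``Apre_i`` decaying with time constant
  ``tau_pre`` and jumping by ``dApre`` at each presynaptic spike;
* at each postsynaptic spike every weight receives ``Apre_i + w_out``
  (``w_out < 0``) and is clipped to ``[0, 1]``.

Afferents that reliably fire just before the neuron's spike accumulate
potentiation faster than the homeostatic drain; the rest are driven to 0.
With a repeating frozen-noise pattern this concentrates the weights on the
afferents firing in a short window of the pattern — i.e. the weight vector
converges to a Strategy-#1 selection — and the window duration can be
compared against the SNR-optimal ``dt``.

Initial weights are uniform at the value that puts the mean noise potential
two standard deviations above threshold, ``V_noise_mean = theta +
2 sigma_noise``, which makes the naive neuron fire at a healthy rate
(~20 Hz in the reference regime) so that learning can bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import stdp_kernel, window_match_kernel
from .spikegen import FrozenPattern, PatternConfig, SpikeTrainSet, build_session, generate_pattern

__all__ = [
    "STDPConfig",
    "LearningOutcome",
    "initial_weight",
    "simulate_stdp",
    "run_stdp",
    "classify_optimal",
    "best_matching_window",
    "mode_analysis",
]


@dataclass(frozen=True)
class STDPConfig:
    """Learning-rule and neuron parameters for one STDP session."""

    theta: float  # threshold, unit-EPSP units
    w_out: float  # homeostatic LTD per postsynaptic spike (< 0)
    dApre: float = 0.01  # trace increment per presynaptic spike
    tau_pre: float = 0.02  # s, presynaptic trace time constant
    tau: float = 0.018  # s, membrane time constant
    dt_bin: float = 1e-4  # s, Euler step

    def __post_init__(self) -> None:
        if self.dApre <= 0:
            raise ValueError("dApre must be > 0")
        if self.w_out >= 0:
            raise ValueError("w_out must be negative")
        if self.tau_pre <= 0 or self.tau <= 0:
            raise ValueError("time constants must be positive")
        if self.dt_bin > self.tau / 10:
            raise ValueError("dt_bin must be <= tau/10")


@dataclass
class LearningOutcome:
    """Final state of one STDP session."""

    final_weights: np.ndarray
    post_spike_times: np.ndarray
    spikes_per_presentation: float
    converged: bool
    optimal: Optional[bool]
    matched_window: Optional[tuple]  # (t0, duration) in pattern time
    dead: bool  # no postsynaptic spike in the first 50 presentations

    @property
    def reinforced(self) -> np.ndarray:
        return np.flatnonzero(self.final_weights >= 1.0 - 0.05)


def initial_weight(theta: float, tau: float, f: float, N: int) -> float:
    """Uniform weight solving ``V_noise_mean = theta + 2 * sigma_noise``.

    With every synapse at ``w0``: mean ``w0 * tau * f * N`` and s.d.
    ``w0 * sqrt(tau * f * N / 2)``, hence
    ``w0 = theta / (tau * f * N - 2 * sqrt(tau * f * N / 2))``.
    """
    tfn = tau * f * N
    denom = tfn - 2.0 * np.sqrt(tfn / 2.0)
    if denom <= 0:
        raise ValueError("tau*f*N too small: no positive-weight solution")
    return float(theta / denom)


def simulate_stdp(
    session: SpikeTrainSet,
    weights0: np.ndarray,
    cfg: STDPConfig,
    abort_time: Optional[float] = None,
) -> tuple:
    """Run the plasticity kernel over one spike session.

    Returns ``(final_weights, post_spike_times, dead)``.  ``abort_time``
    implements the dead-neuron guard: if no postsynaptic spike has occurred
    by then the run is truncated and flagged instead of continuing silently.
    """
    w = np.array(weights0, dtype=float, copy=True)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("initial weights must lie in [0, 1]")
    n_bins = int(np.ceil(session.duration / cfg.dt_bin - 1e-9))
    abort_bin = n_bins + 1 if abort_time is None else int(np.ceil(abort_time / cfg.dt_bin))
    posts, dead = stdp_kernel(
        session.times,
        session.afferents,
        session.N,
        n_bins,
        cfg.dt_bin,
        cfg.tau,
        float(cfg.theta),
        w,
        cfg.dApre,
        cfg.tau_pre,
        cfg.w_out,
        abort_bin,
    )
    return w, posts, bool(dead)


def run_stdp(
    pattern: FrozenPattern,
    session_config: PatternConfig,
    stdp: STDPConfig,
    dt_opt: Optional[float] = None,
    margin: float = 0.10,
) -> LearningOutcome:
    """Full learning experiment on one frozen pattern.

    Builds the jittered presentation session, initializes uniform weights
    from :func:`initial_weight`, runs the STDP kernel, and (when the optimal
    window duration ``dt_opt`` is given) classifies the converged weight
    vector against the Strategy-#1 window criterion.
    """
    session, onsets = build_session(pattern, session_config)
    w0 = initial_weight(stdp.theta, stdp.tau, session_config.f, session_config.N)
    weights0 = np.full(session_config.N, min(w0, 1.0))
    abort = 50 * session_config.interval if session_config.n_presentations >= 50 else None
    w, posts, dead = simulate_stdp(session, weights0, stdp, abort_time=abort)

    P = max(session_config.n_presentations, 1)
    L, T = pattern.L, session_config.T
    in_window = np.zeros(posts.size, bool)
    for onset in onsets:
        in_window |= (posts >= onset - T) & (posts <= onset + L + T)
    spikes_per_pres = float(in_window.sum()) / P

    # saturation: the bulk of the weights has binarized.  A small fraction of
    # afferents sits exactly at the LTP/LTD balance point (pattern spikes
    # ~tau_pre*log(dApre/|w_out|) before the postsynaptic spike) and drifts
    # only diffusively, so full binarization is never reached in finite time.
    converged = bool(np.mean(np.minimum(w, 1.0 - w) <= 0.05) >= 0.95)
    optimal = None
    window = None
    if dt_opt is not None:
        optimal, window = classify_optimal(w, pattern, dt_opt, margin=margin)
    return LearningOutcome(
        final_weights=w,
        post_spike_times=posts,
        spikes_per_presentation=spikes_per_pres,
        converged=converged,
        optimal=optimal,
        matched_window=window,
        dead=dead,
    )


def best_matching_window(
    pattern: FrozenPattern,
    reinforced: np.ndarray,
    dt_opt: float,
    margin: float = 0.10,
    grid: float = 1e-4,
) -> dict:
    """Best Strategy-#1 window match to a set of reinforced afferents.

    Scans every window of the pattern on a ``grid``-resolution lattice and
    scores it by the symmetric difference between {afferents with >= 1
    spike in the window} and ``reinforced``.  Returns both the overall
    minimal-mismatch window and the minimal-mismatch window among those
    whose duration lies within ``margin`` of ``dt_opt``.
    """
    n_bins = int(np.round(pattern.L / grid))
    in_set = np.zeros(pattern.N, np.bool_)
    in_set[np.asarray(reinforced, np.int64)] = True
    sb = np.minimum((pattern.times / grid).astype(np.int64), n_bins - 1)
    lo = int(np.ceil((1.0 - margin) * dt_opt / grid))
    hi = int(np.floor((1.0 + margin) * dt_opt / grid))
    best_m, best_b0, best_w, band_m, band_b0, band_w = window_match_kernel(
        sb, pattern.afferents, in_set, pattern.N, n_bins, int(in_set.sum()), lo, hi
    )
    out = dict(
        mismatch=int(best_m),
        t0=best_b0 * grid if best_b0 >= 0 else None,
        duration=best_w * grid if best_b0 >= 0 else None,
        band_mismatch=int(band_m),
        band_t0=band_b0 * grid if band_b0 >= 0 else None,
        band_duration=band_w * grid if band_b0 >= 0 else None,
    )
    return out


def classify_optimal(
    weights_or_outcome,
    pattern: FrozenPattern,
    dt_opt: float,
    margin: float = 0.10,
    tol: float = 0.05,
    mismatch_tol: float = 0.05,
) -> tuple:
    """Decide whether a learned weight vector is the optimal detector.

    Requirements, in order:

    1. *Converged*: at least 95% of the weights are within ``tol`` of 0 or
       1 (additive STDP saturates the bulk of the weights; a small residue
       of afferents sits at the LTP/LTD balance point and only drifts
       diffusively, so demanding full binarization would reject every
       finite run).
    2. The weight vector, partitioned at 0.5 into reinforced/depressed,
       must correspond to a Strategy-#1 selection: some window of the
       pattern whose >= 1-spike afferent set matches the reinforced set up
       to a symmetric difference of ``mismatch_tol`` times the reinforced
       count (the same balance-point residue makes exact set equality
       unattainable at realistic N).
    3. The window's duration must match ``dt_opt`` within ``margin``
       (relative, duration only).

    Returns ``(optimal, matched_window)``; ``matched_window`` is ``(t0,
    duration)`` of the qualifying window (or of the overall best-matching
    window when classification fails downstream of convergence, for
    diagnostics; None when unconverged or the reinforced set is empty).
    """
    w = (
        weights_or_outcome.final_weights
        if isinstance(weights_or_outcome, LearningOutcome)
        else np.asarray(weights_or_outcome, float)
    )
    if np.mean(np.minimum(w, 1.0 - w) <= tol) < 0.95:
        return False, None  # unconverged
    reinforced = np.flatnonzero(w >= 0.5)
    if reinforced.size == 0:
        return False, None
    match = best_matching_window(pattern, reinforced, dt_opt, margin=margin)
    allowed = mismatch_tol * reinforced.size
    if match["band_t0"] is not None and match["band_mismatch"] <= allowed:
        return True, (match["band_t0"], match["band_duration"])
    if match["t0"] is None:
        return False, None
    return False, (match["t0"], match["duration"])


def mode_analysis(
    theta_grid: Sequence[float],
    wout_grid: Sequence[float],
    n_replicates: int,
    session_config: PatternConfig,
    dt_opt: float,
    dApre: float = 0.01,
    tau_pre: float = 0.02,
    tau: float = 0.018,
    seed: int = 0,
    margin: float = 0.10,
) -> pd.DataFrame:
    """Fraction of patterns learned optimally over a (theta, w_out) grid.

    For each grid point, ``n_replicates`` independent frozen patterns are
    generated and learned; the table reports the optimal fraction ``p``, the
    mean number of in-window postsynaptic spikes per presentation, and the
    convergence fraction.  Per-replicate failures are logged in the ``errors``
    column and do not abort the sweep.
    """
    rows = []
    for theta in theta_grid:
        for w_out in wout_grid:
            stdp = STDPConfig(theta=theta, w_out=w_out, dApre=dApre, tau_pre=tau_pre, tau=tau)
            n_opt = n_conv = n_fail = 0
            spk = []
            for rep in range(n_replicates):
                child = int(
                    np.random.SeedSequence(
                        seed,
                        spawn_key=(int(round(theta * 1e3)), int(round(-w_out * 1e7)), rep),
                    ).generate_state(1)[0]
                    % 2**31
                )
                cfg = session_config.replace(seed=child)
                try:
                    pattern = generate_pattern(cfg)
                    out = run_stdp(pattern, cfg, stdp, dt_opt=dt_opt, margin=margin)
                except Exception:  # noqa: BLE001 - logged, sweep continues
                    n_fail += 1
                    continue
                n_opt += bool(out.optimal)
                n_conv += out.converged
                spk.append(out.spikes_per_presentation)
            n_done = n_replicates - n_fail
            rows.append(
                dict(
                    theta=theta,
                    w_out=w_out,
                    p_optimal=n_opt / n_done if n_done else np.nan,
                    n_optimal=n_opt,
                    n_replicates=n_done,
                    mean_spikes_per_presentation=float(np.mean(spk)) if spk else np.nan,
                    convergence_fraction=n_conv / n_done if n_done else np.nan,
                    errors=n_fail,
                )
            )
    return pd.DataFrame(rows)
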