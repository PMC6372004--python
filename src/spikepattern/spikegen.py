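"""Synthetic spike-train generation and afferent-selection combinatorics.

All inputs of the detection problem are synthetic: ``N`` afferents fire as
independent homogeneous Poisson processes with rate ``f``.  A *frozen-noise
pattern* is one fixed realization of that process over a window of duration
``L``; a *session* replays the pattern at regular onsets, with every pattern
spike independently jittered by a uniform lag on ``[-T, T]``, and fills the
time between presentations with fresh Poisson background.

Strategy #n wires a downstream coincidence detector to the ``M`` afferents
that emit at least ``n`` spikes inside a window of duration ``dt_window`` of
the pattern.  The ensemble expectations of ``M`` and of the selected
afferents' total in-window rate ``r`` are Poisson tail sums:

    M = N * P(X >= n),      r = N * f * P(X >= n - 1),   X ~ Poisson(f * dt_window)

Randomness is driven by one root seed per :class:`PatternConfig`; the
pattern, the background and the jitters each consume a deterministic child
stream, so any one component can be regenerated independently and
bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import poisson

__all__ = [
    "PatternConfig",
    "FrozenPattern",
    "SpikeTrainSet",
    "SelectionSpec",
    "generate_pattern",
    "build_session",
    "poisson_background",
    "select_afferents",
    "expected_M",
    "expected_r",
    "expected_pattern_census",
]

# child-stream indices of the root seed
_STREAM_PATTERN = 0
_STREAM_BACKGROUND = 1
_STREAM_JITTER = 2


def _stream(seed: int, purpose: int) -> np.random.Generator:
    """Deterministic child generator of ``seed`` for one purpose."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(purpose,)))


@dataclass(frozen=True)
class PatternConfig:
    """Parameters of a frozen-noise pattern and its presentation schedule.

    Parameters
    ----------
    N : int
        Number of afferents.
    f : float
        Per-afferent firing rate, Hz.
    L : float
        Pattern duration, s.
    T : float
        Maximal jitter half-width, s; each pattern spike is shifted by an
        independent uniform lag on ``[-T, T]`` at each presentation.
    interval : float
        Time between consecutive pattern onsets, s.
    n_presentations : int
        Number of pattern presentations in a session.
    seed : int
        Root RNG seed.
    """

    N: int
    f: float
    L: float
    T: float = 0.0
    interval: float = 0.4
    n_presentations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.f <= 0:
            raise ValueError("f must be > 0")
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.n_presentations < 0:
            raise ValueError("n_presentations must be >= 0")
        if self.n_presentations > 0 and self.interval < self.L:
            raise ValueError("interval must be >= L")

    def replace(self, **kw) -> "PatternConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class FrozenPattern:
    """One fixed Poisson realization over ``N`` afferents and duration ``L``."""

    afferents: np.ndarray  # int64, 0-based
    times: np.ndarray  # float64 s, in [0, L)
    L: float
    N: int

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def spike_counts(self) -> np.ndarray:
        """Per-afferent spike count, length ``N``."""
        return np.bincount(self.afferents, minlength=self.N)


@dataclass
class SpikeTrainSet:
    """A set of (afferent, time) events over ``N`` afferents.

    Events are sorted by time, ties broken by afferent index.
    """

    afferents: np.ndarray
    times: np.ndarray
    duration: float
    N: int

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class SelectionSpec:
    """Result of Strategy-#n afferent selection on one pattern."""

    n: int
    dt_window: float
    t0: float
    selected: np.ndarray  # sorted int64 afferent indices
    M_expected: float
    r_expected: float

    @property
    def M(self) -> int:
        """Realized number of selected afferents."""
        return int(self.selected.size)


def _sort_events(afferents: np.ndarray, times: np.ndarray):
    order = np.lexsort((afferents, times))
    return afferents[order], times[order]


def generate_pattern(config: PatternConfig) -> FrozenPattern:
    """Draw the frozen-noise pattern: one Poisson realization over ``[0, L)``.

    Each afferent's spike count is Poisson(``f * L``) and spike times are
    i.i.d. uniform on ``[0, L)``.  Deterministic given ``config.seed``.
    """
    rng = _stream(config.seed, _STREAM_PATTERN)
    total = rng.poisson(config.N * config.f * config.L)
    aff = rng.integers(0, config.N, size=total)
    t = rng.uniform(0.0, config.L, size=total)
    aff, t = _sort_events(aff.astype(np.int64), t)
    return FrozenPattern(afferents=aff, times=t, L=config.L, N=config.N)


def _background_chunks(
    rng: np.random.Generator,
    gaps: Sequence[tuple],
    rate_per_afferent: float,
    afferent_pool: np.ndarray,
) -> tuple:
    """Poisson background over a pool of afferents, restricted to time gaps."""
    affs, times = [], []
    m = afferent_pool.size
    for lo, hi in gaps:
        span = hi - lo
        if span <= 0:
            continue
        k = rng.poisson(m * rate_per_afferent * span)
        times.append(rng.uniform(lo, hi, size=k))
        affs.append(afferent_pool[rng.integers(0, m, size=k)])
    if not affs:
        return np.empty(0, np.int64), np.empty(0, float)
    return np.concatenate(affs), np.concatenate(times)


def poisson_background(
    N: int, f: float, duration: float, seed: int, afferents: Optional[np.ndarray] = None
) -> SpikeTrainSet:
    """Pure Poisson noise session (no pattern presentations)."""
    rng = _stream(seed, _STREAM_BACKGROUND)
    pool = np.arange(N, dtype=np.int64) if afferents is None else np.asarray(afferents, np.int64)
    aff, t = _background_chunks(rng, [(0.0, duration)], f, pool)
    aff, t = _sort_events(aff, t)
    return SpikeTrainSet(afferents=aff, times=t, duration=duration, N=N)


def build_session(
    pattern: FrozenPattern,
    config: PatternConfig,
    afferents: Optional[np.ndarray] = None,
) -> tuple:
    """Assemble a presentation session: jittered pattern replays + background.

    The pattern is replayed at onsets ``offset + k * interval`` with
    ``offset = (interval - L) / 2``, every spike shifted by an independent
    uniform jitter on ``[-T, T]`` per presentation.  During a presentation
    window the pattern *replaces* background activity: background is generated
    only outside ``[onset, onset + L]``.  Jittered spikes falling slightly
    outside their window are kept.

    Parameters
    ----------
    pattern, config
        The frozen pattern and session parameters (``config.seed`` drives the
        background and jitter streams).
    afferents : array of int, optional
        Restrict the session to this subset of afferents (useful when only
        the detector's selected afferents matter; the others carry zero
        synaptic weight).  Default: all ``N``.

    Returns
    -------
    (SpikeTrainSet, ndarray of onsets in s)
    """
    if config.n_presentations > 0 and config.interval < pattern.L:
        raise ValueError("interval must be >= pattern duration L")
    offset = (config.interval - pattern.L) / 2.0
    if config.n_presentations > 0 and config.T > offset:
        raise ValueError(
            "guard band violated: need T <= (interval - L)/2 so that jittered "
            "spikes stay inside the session"
        )
    P = config.n_presentations
    duration = P * config.interval if P > 0 else config.interval
    onsets = offset + config.interval * np.arange(P)

    if afferents is None:
        pool = np.arange(config.N, dtype=np.int64)
        pat_aff, pat_t = pattern.afferents, pattern.times
    else:
        pool = np.asarray(afferents, np.int64)
        keep = np.isin(pattern.afferents, pool)
        pat_aff, pat_t = pattern.afferents[keep], pattern.times[keep]

    # background outside the presentation windows
    bounds = [0.0]
    for onset in onsets:
        bounds += [onset, onset + pattern.L]
    bounds.append(duration)
    gaps = list(zip(bounds[::2], bounds[1::2]))
    bg_rng = _stream(config.seed, _STREAM_BACKGROUND)
    bg_aff, bg_t = _background_chunks(bg_rng, gaps, config.f, pool)

    # jittered pattern replays
    jit_rng = _stream(config.seed, _STREAM_JITTER)
    k = pat_t.size
    rep_aff = np.tile(pat_aff, P)
    rep_t = (onsets[:, None] + pat_t[None, :]).ravel()
    if config.T > 0 and k > 0:
        rep_t = rep_t + jit_rng.uniform(-config.T, config.T, size=P * k)

    aff = np.concatenate([bg_aff, rep_aff])
    t = np.concatenate([bg_t, rep_t])
    aff, t = _sort_events(aff, t)
    return SpikeTrainSet(afferents=aff, times=t, duration=duration, N=config.N), onsets


def select_afferents(
    pattern: FrozenPattern,
    n: int,
    dt_window: float,
    t0: float = 0.0,
    f: Optional[float] = None,
) -> SelectionSpec:
    """Strategy #n: afferents with >= n spikes in ``[t0, t0 + dt_window)``.

    When the generating rate ``f`` is given, the ensemble expectations
    ``M_expected`` and ``r_expected`` are filled in; otherwise they are NaN.
    """
    if n < 1:
        raise ValueError("strategy number n must be >= 1")
    if dt_window <= 0 or dt_window > pattern.L * (1 + 1e-12):
        raise ValueError("dt_window must be in (0, L]")
    if t0 < 0 or t0 > pattern.L - dt_window + 1e-12:
        raise ValueError("window [t0, t0+dt_window] must lie within [0, L]")
    in_win = (pattern.times >= t0) & (pattern.times < t0 + dt_window)
    counts = np.bincount(pattern.afferents[in_win], minlength=pattern.N)
    selected = np.flatnonzero(counts >= n).astype(np.int64)
    return SelectionSpec(
        n=n,
        dt_window=dt_window,
        t0=t0,
        selected=selected,
        M_expected=expected_M(pattern.N, f, dt_window, n) if f is not None else float("nan"),
        r_expected=expected_r(pattern.N, f, dt_window, n) if f is not None else float("nan"),
    )


def expected_M(N: int, f: float, dt_window: float, n: int) -> float:
    """Ensemble-mean number of afferents with >= n spikes in the window.

    ``M = N * (1 - e^{-lam} * sum_{k<n} lam^k / k!)`` with ``lam = f*dt``,
    i.e. ``N`` times the Poisson survival function.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = np.asarray(f, float) * np.asarray(dt_window, float)
    out = N * poisson.sf(n - 1, lam)
    return out if np.ndim(out) else float(out)


def expected_r(N: int, f: float, dt_window: float, n: int) -> float:
    """Ensemble-mean total in-window rate of the selected afferents, Hz.

    ``r = N * f * (1 - e^{-lam} * sum_{k<n-1} lam^k / k!)``; the discarded
    spikes are those of afferents firing fewer than ``n`` times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return float(N * f)
    lam = np.asarray(f, float) * np.asarray(dt_window, float)
    out = N * f * poisson.sf(n - 2, lam)
    return out if np.ndim(out) else float(out)


def expected_pattern_census(N: int, f: float, L: float, k_max: int = 4) -> np.ndarray:
    """Expected number of afferents emitting exactly k spikes in the pattern,
    for k = 0..k_max, rounded to the nearest integer."""
    lam = f * L
    return np.rint(N * poisson.pmf(np.arange(k_max + 1), lam)).astype(int)
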