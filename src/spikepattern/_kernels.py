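"""Numba hot loops: thresholded LIF integration and the STDP session.

Both kernels use the clock-based forward-Euler contract
``V <- V*(1 - dt/tau) + sum of synaptic weights arriving in the bin``;
on a threshold crossing the potential resets to 0 with no refractory
period, and inputs of the crossing bin have already been integrated.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lif_threshold_kernel(s: np.ndarray, alpha: float, theta: float):
    """Integrate per-bin summed input ``s`` with threshold/reset.

    Returns the potential trace (length ``len(s) + 1``, ``V[0] = 0``) and
    the indices of the bins whose *end* is a postsynaptic spike time.
    """
    n = s.shape[0]
    V = np.zeros(n + 1)
    out = np.empty(n, np.int64)
    m = 0
    v = 0.0
    for k in range(n):
        v = v * alpha + s[k]
        if v >= theta:
            out[m] = k + 1
            m += 1
            v = 0.0
        V[k + 1] = v
    return V, out[:m]


@njit(cache=True)
def window_match_kernel(
    spike_bins: np.ndarray,
    spike_affs: np.ndarray,
    in_set: np.ndarray,
    N: int,
    n_bins: int,
    set_size: int,
    lo_bin: int,
    hi_bin: int,
):
    """Scan all windows on the bin grid for the best match to a target set.

    For every half-open window ``[b0, b1)`` (bin indices), the mismatch is
    the symmetric difference between the afferents spiking in the window
    and the target set (``in_set`` indicator).  Returns the minimal
    mismatch overall with its (shortest) window, and the same restricted to
    windows whose width lies in ``[lo_bin, hi_bin]``.

    ``spike_bins`` must be sorted ascending.
    """
    counts = np.zeros(N, np.int64)
    n_ev = spike_bins.shape[0]
    best_m = set_size + N + 1
    best_b0 = -1
    best_w = n_bins + 1
    band_m = set_size + N + 1
    band_b0 = -1
    band_w = n_bins + 1
    # pointer to first spike with bin >= b0
    start = 0
    for b0 in range(n_bins):
        while start < n_ev and spike_bins[start] < b0:
            start += 1
        if start >= n_ev:
            break
        n_in = 0
        n_out = 0
        idx = start
        for b1 in range(b0 + 1, n_bins + 1):
            while idx < n_ev and spike_bins[idx] < b1:
                a = spike_affs[idx]
                counts[a] += 1
                if counts[a] == 1:
                    if in_set[a]:
                        n_in += 1
                    else:
                        n_out += 1
                idx += 1
            m = (set_size - n_in) + n_out
            w = b1 - b0
            if m < best_m or (m == best_m and w < best_w):
                best_m = m
                best_b0 = b0
                best_w = w
            if lo_bin <= w <= hi_bin and (m < band_m or (m == band_m and w < band_w)):
                band_m = m
                band_b0 = b0
                band_w = w
        # reset touched counters
        for k in range(start, idx):
            counts[spike_affs[k]] = 0
    return best_m, best_b0, best_w, band_m, band_b0, band_w


@njit(cache=True)
def stdp_kernel(
    times: np.ndarray,
    affs: np.ndarray,
    N: int,
    n_bins: int,
    dt: float,
    tau: float,
    theta: float,
    w: np.ndarray,
    d_apre: float,
    tau_pre: float,
    w_out: float,
    abort_bin: int,
):
    """All-to-all LTP + homeostatic LTD over one session; mutates ``w``.

    Presynaptic traces decay exponentially with ``tau_pre`` and jump by
    ``d_apre`` at each presynaptic spike; at each postsynaptic spike every
    weight receives its (lazily decayed) trace plus ``w_out`` and is clipped
    to [0, 1].  Spike times are quantized to the end of their bin, so trace
    decays use exact exponentials of bin-aligned intervals.

    Returns ``(post_spike_times, dead)``; ``dead`` is True when no
    postsynaptic spike occurred before ``abort_bin`` (the run is then
    truncated there and reported, rather than silently continuing).
    """
    apre = np.zeros(N)
    last = np.zeros(N)
    posts = np.empty(n_bins, np.float64)
    m = 0
    v = 0.0
    alpha = 1.0 - dt / tau
    idx = 0
    n_ev = times.shape[0]
    for k in range(n_bins):
        t_next = (k + 1) * dt
        inc = 0.0
        while idx < n_ev and times[idx] < t_next:
            i = affs[idx]
            apre[i] = apre[i] * np.exp(-(t_next - last[i]) / tau_pre) + d_apre
            last[i] = t_next
            inc += w[i]
            idx += 1
        v = v * alpha + inc
        if v >= theta:
            for i in range(N):
                a = apre[i] * np.exp(-(t_next - last[i]) / tau_pre)
                apre[i] = a
                last[i] = t_next
                wi = w[i] + a + w_out
                if wi < 0.0:
                    wi = 0.0
                elif wi > 1.0:
                    wi = 1.0
                w[i] = wi
            posts[m] = t_next
            m += 1
            v = 0.0
        if m == 0 and k + 1 >= abort_bin:
            return posts[:0], True
    return posts[:m].copy(), False
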