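"""Closed-form signal-to-noise ratio of the LIF coincidence detector.

Model.  A LIF with membrane time constant ``tau`` and instantaneous (Dirac)
synapses of unit weight integrates the ``M`` afferents selected by Strategy
#n.  During noise periods the input is Poisson at total rate ``f*M``, so the
membrane potential (in unit-EPSP units) fluctuates around

    V_noise_mean = tau * f * M,        V_noise_sd = sqrt(tau * f * M / 2),

Gaussian to good approximation when ``tau*f*M >> 1``.  During a pattern
presentation the selected afferents deliver their in-window spikes, total
rate ``r``; per-spike uniform jitter on ``[-T, T]`` smears the rectangular
rate profile into a trapezoid of height ``h = min(1, dt/2T)`` and rise/fall
time ``min(dt, 2T)`` (its area is always ``dt``: jitter moves spikes, it
does not create or destroy them).

In the reduced variable ``v = (V - V_noise_mean) / (V_inf - V_noise_mean)``
with ``V_inf = tau * r``, the membrane obeys ``tau dv/dt = -v + i(t)`` with
the trapezoidal drive ``i``.  Because ``i`` is piecewise linear the ODE
integrates exactly piece by piece, giving the peak reduced response

    v_max = min(1, dt/2T) - tau/(2T) * log(1 - e^{-max(dt,2T)/tau}
                                             + e^{-|dt-2T|/tau}),

reached a time ``t_max = tau * log(1 + 2T(h - v2)/tau)`` into the falling
edge (the peak sits on the trapezoid's falling edge: before the crossing
``i > v`` so ``v`` rises, after it ``i < v`` so ``v`` falls).  Finally

    SNR = v_max * e^{-lam} lam^{n-1}/(n-1)! * sqrt(2 tau N f / P(X >= n)),

with ``lam = f * dt`` and ``X ~ Poisson(lam)``.

Degenerate limits (``T = 0`` and other divisions by ``2T``) are handled by
explicit limit branches rather than epsilon perturbation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .spikegen import expected_M, expected_r

__all__ = [
    "AnalyticParams",
    "TrapezoidCurrent",
    "SNRBreakdown",
    "noise_stats",
    "trapezoid",
    "integrate_linear_piece",
    "vmax",
    "snr",
    "snr_value",
    "LowInputWarning",
]


class LowInputWarning(UserWarning):
    """Gaussian approximation is dubious: tau*f*M below 10."""


@dataclass(frozen=True)
class AnalyticParams:
    """Parameter point for the closed-form SNR."""

    N: int
    f: float  # Hz
    T: float  # s, jitter half-width (>= 0)
    tau: float  # s, membrane time constant
    dt_window: float  # s, selection window
    n: int  # strategy number

    def __post_init__(self) -> None:
        if min(self.N, self.f, self.tau, self.dt_window) <= 0:
            raise ValueError("N, f, tau, dt_window must be positive")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TrapezoidCurrent:
    """Jittered input-current profile: rise t1, plateau t2, fall t3, height h."""

    t1: float
    t2: float
    t3: float
    h: float

    @property
    def area(self) -> float:
        # plateau h*t2 plus two triangles h*t1/2 each (t1 == t3); always == dt
        return self.h * (self.t2 + self.t1)


@dataclass
class SNRBreakdown:
    """Every intermediate quantity of the closed-form SNR at one point."""

    lam: float
    M: float
    r: float
    V_noise_mean: float
    V_noise_sd: float
    V_inf: float
    v1: float
    v2: float
    t_max: float
    v_max: float
    snr: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def noise_stats(tau: float, f: float, M: float) -> tuple:
    """Mean and s.d. of the noise-period potential, unit-EPSP units.

    Shot noise of Poisson rate ``f*M`` filtered by ``exp(-t/tau)``:
    mean ``tau*f*M``, variance ``tau*f*M/2``.  Warns when ``tau*f*M < 10``
    (the Gaussian approximation degrades; the distribution skews positive).
    """
    tfm = tau * f * M
    if 0 < tfm < 10:
        warnings.warn(
            f"tau*f*M = {tfm:.3g} < 10: noise potential distribution is "
            "noticeably non-Gaussian",
            LowInputWarning,
            stacklevel=2,
        )
    return tfm, float(np.sqrt(tfm / 2.0))


def trapezoid(dt_window: float, T: float) -> TrapezoidCurrent:
    """Trapezoidal reduced input current produced by uniform jitter.

    ``t1 = t3 = min(dt, 2T)``, ``t2 = |dt - 2T|``, ``h = min(1, dt/2T)``;
    at ``T = 0`` the degenerate rectangle (0, dt, 0, 1).
    """
    if dt_window <= 0:
        raise ValueError("dt_window must be > 0")
    if T < 0:
        raise ValueError("T must be >= 0")
    if T == 0.0:
        return TrapezoidCurrent(0.0, dt_window, 0.0, 1.0)
    edge = min(dt_window, 2.0 * T)
    return TrapezoidCurrent(
        t1=edge,
        t2=abs(dt_window - 2.0 * T),
        t3=edge,
        h=min(1.0, dt_window / (2.0 * T)),
    )


def integrate_linear_piece(v0: float, a: float, b: float, t, tau: float):
    """Exact response of ``tau dv/dt = -v + i`` to the ramp ``i = a*t + b``.

    Derived directly from the ODE (particular solution ``a*(t - tau) + b``
    plus relaxing exponential):

        v(t) = a*(t - tau) + b + (v0 - b + a*tau) * exp(-t/tau)
    """
    t = np.asarray(t, dtype=float)
    out = a * (t - tau) + b + (v0 - b + a * tau) * np.exp(-t / tau)
    return out if out.ndim else float(out)


def vmax(dt_window, T, tau):
    """Peak of the reduced response to the jittered trapezoid.

    Returns ``(v_max, t_max, v1, v2)`` where ``v1 = v(t1)``,
    ``v2 = v(t1 + t2)`` and ``t_max`` is measured from the start of the
    falling edge.  Accepts scalars or broadcastable arrays; ``T = 0`` is the
    exact step-response limit ``v_max = 1 - exp(-dt/tau)``.
    """
    dt_window, T, tau = np.broadcast_arrays(
        *(np.asarray(x, float) for x in (dt_window, T, tau))
    )
    scalar = dt_window.ndim == 0
    dt_window, T, tau = np.atleast_1d(dt_window, T, tau)
    if np.any(dt_window <= 0) or np.any(tau <= 0) or np.any(T < 0):
        raise ValueError("need dt_window > 0, tau > 0, T >= 0")

    with np.errstate(divide="ignore", invalid="ignore"):
        twoT = np.where(T > 0, 2.0 * T, 1.0)  # placeholder where the T=0 limit applies
        t1 = np.minimum(dt_window, 2.0 * T)
        t2 = np.abs(dt_window - 2.0 * T)
        h = np.where(T > 0, np.minimum(1.0, dt_window / twoT), 1.0)
        # rising edge: i = t/2T from v=0, evaluated at t1
        v1 = np.where(T > 0, (t1 + tau * (np.exp(-t1 / tau) - 1.0)) / twoT, 0.0)
        # plateau: relax toward h over t2
        v2 = h + (v1 - h) * np.exp(-t2 / tau)
        # falling edge: dv/dt = 0 where e^{-t/tau} = 1/(1 + 2T(h - v2)/tau).
        # 2T(h - v2)/tau = (1 - e^{-t1/tau}) e^{-t2/tau} exactly, a cancellation-
        # free form of the log argument (1 - e^{-max(dt,2T)/tau} + e^{-|dt-2T|/tau}).
        c = -np.exp(-t2 / tau) * np.expm1(-t1 / tau)
        t_max = np.where(T > 0, tau * np.log1p(c), 0.0)
        # the peak sits on the trapezoid edge: v_max = h - t_max/2T (exact)
        v_max = np.where(T > 0, h - t_max / twoT, -np.expm1(-dt_window / tau))
    if scalar:
        return float(v_max[0]), float(t_max[0]), float(v1[0]), float(v2[0])
    return v_max, t_max, v1, v2


def snr_value(f, T, N, tau, dt_window, n):
    """Closed-form SNR; accepts broadcastable arrays for plane sweeps."""
    lam = np.asarray(f, float) * np.asarray(dt_window, float)
    v_max = vmax(dt_window, T, tau)[0]
    tail = poisson.sf(n - 1, lam)  # P(X >= n), overflow-safe for large n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = v_max * poisson.pmf(n - 1, lam) * np.sqrt(
            2.0 * np.asarray(tau, float) * N * np.asarray(f, float) / tail
        )
    return out


def snr(params: AnalyticParams) -> SNRBreakdown:
    """Full analytic chain at one parameter point.

    Populates every intermediate quantity (lam, M, r, noise stats, v1, v2,
    t_max, v_max) and the SNR.  Warns — does not fail — when ``tau*f*M``
    drops below 10.
    """
    p = params
    lam = p.f * p.dt_window
    M = expected_M(p.N, p.f, p.dt_window, p.n)
    r = expected_r(p.N, p.f, p.dt_window, p.n)
    noise_mean, noise_sd = noise_stats(p.tau, p.f, M)
    v_max, t_max, v1, v2 = vmax(p.dt_window, p.T, p.tau)
    value = float(snr_value(p.f, p.T, p.N, p.tau, p.dt_window, p.n))
    return SNRBreakdown(
        lam=lam,
        M=M,
        r=r,
        V_noise_mean=noise_mean,
        V_noise_sd=noise_sd,
        V_inf=p.tau * r,
        v1=v1,
        v2=v2,
        t_max=t_max,
        v_max=v_max,
        snr=value,
    )
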