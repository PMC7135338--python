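"""Input-signal generation and transformation.

All signals live on a uniform time grid with step ``dt`` expressed in units
of the membrane time constant τ (τ ≡ 1 throughout the package).  A signal
bundle carries both the input currents ``c(t)`` that drive the network and
their leaky integrals ``x(t)``, which are the quantities the spike code is
asked to represent: x obeys dx/dt = -x + c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SignalBundle",
    "leaky_integrate",
    "make_smooth_noise",
    "make_sinusoid_pair",
    "make_constant_angle",
    "make_structured_bank",
    "calibrate_gain",
]


@dataclass
class SignalBundle:
    """An M-channel input signal on a uniform time grid.

    Attributes
    ----------
    c : ndarray, shape (M, n_steps)
        Input currents, in units of threshold per membrane time constant.
    x : ndarray, shape (M, n_steps)
        Leaky integrals of ``c`` (dx/dt = -x + c); the signals the network
        learns to encode.
    dt : float
        Step size in units of the membrane time constant.
    meta : dict
        Provenance: generator name, parameters, seed.
    """

    c: np.ndarray
    x: np.ndarray
    dt: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.c.ndim != 2 or self.x.shape != self.c.shape:
            raise ValueError(
                f"c and x must be 2-D with identical shape, got {self.c.shape} vs {self.x.shape}"
            )
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        for name, arr in (("c", self.c), ("x", self.x)):
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                raise ValueError(
                    f"non-finite entry in {name} at index {tuple(int(i) for i in bad)}"
                )

    @property
    def n_channels(self) -> int:
        return self.c.shape[0]

    @property
    def n_steps(self) -> int:
        return self.c.shape[1]

    @property
    def duration(self) -> float:
        return self.c.shape[1] * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def scaled(self, gain: float) -> "SignalBundle":
        """Return a copy with both c and x multiplied by ``gain``."""
        meta = dict(self.meta)
        meta["gain"] = gain * meta.get("gain", 1.0)
        return SignalBundle(c=self.c * gain, x=self.x * gain, dt=self.dt, meta=meta)

    def split(self, fraction: float) -> tuple["SignalBundle", "SignalBundle"]:
        """Split along time into (head, tail) at ``fraction`` of the steps."""
        k = int(round(self.n_steps * fraction))
        if not 0 < k < self.n_steps:
            raise ValueError("split fraction leaves an empty segment")
        head = SignalBundle(self.c[:, :k], self.x[:, :k], self.dt, dict(self.meta))
        tail = SignalBundle(self.c[:, k:], self.x[:, k:], self.dt, dict(self.meta))
        return head, tail

    def to_frame(self):
        """Columnar representation: one time column plus one column per channel of x."""
        import pandas as pd

        data = {"time": self.times}
        for j in range(self.n_channels):
            data[f"c{j}"] = self.c[j]
            data[f"x{j}"] = self.x[j]
        return pd.DataFrame(data)


def leaky_integrate(
    c: np.ndarray, dt: float, x0: np.ndarray | float = 0.0
) -> np.ndarray:
    """Forward-Euler leaky integration of input currents.

    Solves dx/dt = -x + c on the grid of ``c`` with x[:, 0] = x0, i.e.
    x[t+1] = x[t] + dt·(-x[t] + c[t]).

    Parameters
    ----------
    c : ndarray, shape (M, n_steps)
    dt : float, step in units of τ
    x0 : initial state, scalar or length-M vector

    Returns
    -------
    ndarray of the same shape as ``c``.
    """
    c = np.atleast_2d(np.asarray(c, dtype=np.float64))
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not np.all(np.isfinite(c)):
        bad = np.argwhere(~np.isfinite(c))[0]
        raise ValueError(
            f"non-finite entry in c at index {tuple(int(i) for i in bad)}"
        )
    M, n = c.shape
    x0 = np.broadcast_to(np.asarray(x0, dtype=np.float64), (M,)).copy()
    x = np.empty_like(c)
    x[:, 0] = x0
    decay = 1.0 - dt
    for t in range(n - 1):
        x[:, t + 1] = decay * x[:, t] + dt * c[:, t]
    return x


def _currents_for(x: np.ndarray, dt: float) -> np.ndarray:
    """Currents c whose forward-Euler leaky integral reproduces ``x`` exactly.

    Inverts x[t+1] = (1-dt)·x[t] + dt·c[t]; the last column repeats the
    previous current (it never influences x on the grid).
    """
    c = np.empty_like(x)
    c[:, :-1] = (x[:, 1:] - (1.0 - dt) * x[:, :-1]) / dt
    c[:, -1] = c[:, -2] if x.shape[1] > 1 else 0.0
    return c


def make_smooth_noise(
    M: int,
    duration: float,
    dt: float,
    covariance: np.ndarray | None = None,
    smoothing_tau: float = 0.5,
    seed: int = 0,
) -> SignalBundle:
    """Smoothed Gaussian noise with a prescribed cross-channel covariance of x.

    White Gaussian noise is low-pass filtered with time constant
    ``smoothing_tau`` (an Ornstein–Uhlenbeck process per channel), mixed
    through the Cholesky factor of ``covariance``, and used as the current
    c(t); x is its leaky integral.  The filtered process is normalized to
    unit stationary variance in x before mixing, so the stationary covariance
    of x across channels matches ``covariance``.

    This is the package's stand-in for the randomly varying input signals
    used to train the networks.
    """
    if covariance is None:
        covariance = np.eye(M)
    covariance = np.asarray(covariance, dtype=np.float64)
    if covariance.shape != (M, M):
        raise ValueError(f"covariance must be {M}x{M}, got {covariance.shape}")
    if not np.allclose(covariance, covariance.T, atol=1e-12):
        raise ValueError("covariance must be symmetric")
    eigs = np.linalg.eigvalsh(covariance)
    if eigs.min() < -1e-10 * max(1.0, eigs.max()):
        raise ValueError("covariance must be positive semidefinite")
    if not smoothing_tau > 0:
        raise ValueError("smoothing_tau must be positive")

    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    # OU process u with correlation time smoothing_tau, unit variance:
    #   u[t+1] = (1 - dt/τs) u[t] + σ √dt ξ,  σ = √(2/τs)
    a = 1.0 - dt / smoothing_tau
    sig = np.sqrt(2.0 / smoothing_tau) * np.sqrt(dt)
    u = np.empty((M, n))
    u[:, 0] = rng.standard_normal(M)
    noise = sig * rng.standard_normal((M, n - 1))
    for t in range(n - 1):
        u[:, t + 1] = a * u[:, t] + noise[:, t]

    # variance of x = leaky integral of u: for an OU current with unit
    # variance and time constant τs, Var[x] = τs/(1+τs) (two cascaded
    # exponential filters with time constants 1 and τs).
    x_std = np.sqrt(smoothing_tau / (1.0 + smoothing_tau))
    L = np.linalg.cholesky(covariance + 1e-12 * np.eye(M))
    c = (L @ u) / x_std
    x = leaky_integrate(c, dt, x0=np.zeros(M))
    return SignalBundle(
        c=c,
        x=x,
        dt=dt,
        meta={
            "generator": "smooth_noise",
            "M": M,
            "duration": duration,
            "smoothing_tau": smoothing_tau,
            "seed": seed,
        },
    )


def make_sinusoid_pair(
    duration: float, dt: float, amplitude: float = 1.0, period: float = 2.0
) -> SignalBundle:
    """Sine/cosine test pair: x = (A sin ωt, A cos ωt), c chosen so that
    leaky integration of c reproduces x exactly on the grid."""
    if not period > dt:
        raise ValueError("period must exceed dt")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    w = 2.0 * np.pi / period
    x = np.vstack([amplitude * np.sin(w * t), amplitude * np.cos(w * t)])
    c = _currents_for(x, dt)
    return SignalBundle(
        c=c,
        x=x,
        dt=dt,
        meta={
            "generator": "sinusoid_pair",
            "amplitude": amplitude,
            "period": period,
        },
    )


def make_constant_angle(
    angle: float,
    radius: float,
    duration: float,
    dt: float,
    ramp: float = 1.0,
) -> SignalBundle:
    """Two-channel probe held at a fixed angle in signal space.

    x ramps linearly from 0 over ``ramp`` membrane time constants to
    (radius·cos θ, radius·sin θ) and then stays constant; the angle is in
    degrees.  Used to measure tuning curves.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    n = int(round(duration / dt))
    theta = np.deg2rad(angle)
    target = np.array([radius * np.cos(theta), radius * np.sin(theta)])
    t = np.arange(n) * dt
    envelope = np.clip(t / ramp, 0.0, 1.0) if ramp > 0 else np.ones(n)
    x = target[:, None] * envelope[None, :]
    c = _currents_for(x, dt)
    return SignalBundle(
        c=c,
        x=x,
        dt=dt,
        meta={"generator": "constant_angle", "angle": angle, "radius": radius},
    )


def make_structured_bank(
    channels: int = 25,
    duration: float = 50.0,
    dt: float = 1e-3,
    n_components: int = 5,
    smoothing_tau: float = 0.5,
    seed: int = 0,
) -> SignalBundle:
    """Synthetic correlated multichannel bank.

    A low-rank, non-negative, temporally smooth signal: ``n_components``
    smooth latent time courses (rectified OU processes) mixed through
    localized band-like loading vectors, emulating the strong cross-channel
    correlations of a spectrogram-like input.  Synthetic stand-in; no audio
    is involved.
    """
    if n_components > channels:
        raise ValueError("n_components must not exceed channels")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))

    # smooth positive latents
    a = 1.0 - dt / smoothing_tau
    sig = np.sqrt(2.0 / smoothing_tau) * np.sqrt(dt)
    z = np.empty((n_components, n))
    z[:, 0] = rng.standard_normal(n_components)
    for t in range(n - 1):
        z[:, t + 1] = a * z[:, t] + sig * rng.standard_normal(n_components)
    latents = np.maximum(z, 0.0)

    # localized, band-like non-negative loadings (Gaussian bumps on the
    # channel axis, one per component)
    centers = np.linspace(0, channels - 1, n_components)
    width = max(channels / (2.0 * n_components), 1.0)
    idx = np.arange(channels)
    loadings = np.exp(-0.5 * ((idx[:, None] - centers[None, :]) / width) ** 2)
    loadings *= 0.5 + rng.random(n_components)[None, :]

    x = loadings @ latents
    c = _currents_for(x, dt)
    return SignalBundle(
        c=c,
        x=x,
        dt=dt,
        meta={
            "generator": "structured_bank",
            "channels": channels,
            "n_components": n_components,
            "seed": seed,
        },
    )


def calibrate_gain(
    pilot,
    target_rate: float,
    make_signal,
    seed: int = 0,
    pilot_duration: float = 50.0,
    tol: float = 0.1,
    max_iter: int = 20,
    gain_bounds: tuple[float, float] = (1e-3, 1e3),
) -> float:
    """Bisection on a scalar input gain to hit a target mean firing rate.

    Parameters
    ----------
    pilot : callable(SignalBundle) -> float
        Runs a short simulation on the supplied signal and returns the mean
        population firing rate (spikes per τ).
    target_rate : float
        Desired mean rate in spikes per τ.
    make_signal : callable(duration, seed) -> SignalBundle
        Fresh pilot signal factory.
    tol : float
        Acceptable relative rate error.

    Returns
    -------
    The calibrated gain.  Firing rates increase monotonically with input
    gain in these networks, which is what bisection relies on.
    """
    sig = make_signal(pilot_duration, seed)
    lo, hi = gain_bounds
    # expand/locate a bracket
    rate_lo = pilot(sig.scaled(lo))
    rate_hi = pilot(sig.scaled(hi))
    if rate_lo > target_rate or rate_hi < target_rate:
        # best effort: return whichever endpoint is closer
        return lo if abs(rate_lo - target_rate) < abs(rate_hi - target_rate) else hi
    gain = 1.0
    for _ in range(max_iter):
        gain = np.sqrt(lo * hi)  # geometric bisection: rates scale roughly with log-gain
        rate = pilot(sig.scaled(gain))
        if abs(rate - target_rate) <= tol * target_rate:
            return gain
        if rate < target_rate:
            lo = gain
        else:
            hi = gain
    return gain
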