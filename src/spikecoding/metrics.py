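"""Spike-train statistics and population-coding diagnostics.

Rates are reported in spikes per membrane time constant τ internally; the
conversion to Hz uses the package convention τ = 10 ms (``TAU_SECONDS``),
so 0.05 spikes/τ = 5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .network import EINetwork, Network, SimResult, simulate
from .readout import filter_spikes, fit_decoder, reconstruct
from .signals import SignalBundle, make_constant_angle

__all__ = [
    "TAU_SECONDS",
    "SpikeStats",
    "spike_stats",
    "tuning_curves",
    "coverage_gap",
    "poisson_matched_error",
    "rate_to_hz",
]

TAU_SECONDS = 0.010  # membrane time constant used when converting rates to Hz


def rate_to_hz(rate_per_tau: float | np.ndarray):
    return np.asarray(rate_per_tau) / TAU_SECONDS


@dataclass
class SpikeStats:
    """Per-neuron spike-train statistics.

    mean_rate_hz : firing rates (Hz, τ = 10 ms convention); cv_isi :
    coefficient of variation of inter-spike intervals (NaN for neurons with
    fewer than 3 ISIs); fano_factor : across-trial variance/mean of windowed
    spike counts (NaN without repeated trials); mean_pairwise_correlation :
    average Pearson correlation of binned spike counts over neuron pairs.
    """

    mean_rate_hz: np.ndarray
    cv_isi: np.ndarray
    fano_factor: np.ndarray
    mean_pairwise_correlation: float

    def to_frame(self):
        import pandas as pd

        rows = []
        for stat in ("mean_rate_hz", "cv_isi", "fano_factor"):
            vals = getattr(self, stat)
            for i, v in enumerate(vals):
                rows.append({"neuron": i, "statistic": stat, "value": v})
        rows.append(
            {
                "neuron": -1,
                "statistic": "mean_pairwise_correlation",
                "value": self.mean_pairwise_correlation,
            }
        )
        return pd.DataFrame(rows)


def _binned_counts(spikes: np.ndarray, N: int, n_steps: int, dt: float, bin_width: float):
    steps_per_bin = max(int(round(bin_width / dt)), 1)
    n_bins = n_steps // steps_per_bin
    counts = np.zeros((N, n_bins))
    for t, k in spikes:
        b = t // steps_per_bin
        if b < n_bins:
            counts[k, b] += 1
    return counts


def spike_stats(
    rasters: SimResult | Sequence[SimResult],
    bin_width: float = 1.0,
    ff_window: float = 5.0,
) -> SpikeStats:
    """CV, Fano factor, rates and pairwise correlations of spike trains.

    CV is std/mean of the inter-spike intervals per neuron, excluding
    neurons with fewer than 3 ISIs.  The Fano factor needs at least two
    repeated trials with frozen input: spike counts are taken in windows of
    ``ff_window`` τ, and FF is the across-trial variance/mean averaged over
    windows with nonzero mean count.  The pairwise correlation is the mean
    over neuron pairs of the Pearson correlation of binned counts
    (``bin_width`` τ bins, default 1 τ = 10 ms), averaged over trials;
    zero-variance neurons are excluded.
    """
    if isinstance(rasters, SimResult):
        rasters = [rasters]
    if len(rasters) == 0:
        raise ValueError("at least one raster required")
    N = rasters[0].n_neurons
    dt = rasters[0].dt
    n_steps = rasters[0].n_steps

    # rates (averaged over trials)
    rates = np.mean([res.rates() for res in rasters], axis=0)

    # CV of ISIs, pooled over trials
    cv = np.full(N, np.nan)
    for k in range(N):
        isis = []
        for res in rasters:
            t_k = np.sort(res.spikes[res.spikes[:, 1] == k, 0]) * dt
            if len(t_k) >= 2:
                isis.append(np.diff(t_k))
        if isis:
            isis = np.concatenate(isis)
            if len(isis) >= 3 and isis.mean() > 0:
                cv[k] = isis.std() / isis.mean()

    # Fano factor across trials
    fano = np.full(N, np.nan)
    if len(rasters) >= 2:
        counts = np.stack(
            [_binned_counts(res.spikes, N, n_steps, dt, ff_window) for res in rasters]
        )  # (trials, N, windows)
        mean_c = counts.mean(axis=0)
        var_c = counts.var(axis=0, ddof=1)
        for k in range(N):
            ok = mean_c[k] > 0
            if ok.any():
                fano[k] = float(np.mean(var_c[k, ok] / mean_c[k, ok]))

    # mean pairwise correlation of binned counts
    corrs = []
    for res in rasters:
        counts = _binned_counts(res.spikes, N, n_steps, dt, bin_width)
        sd = counts.std(axis=1)
        active = np.nonzero(sd > 0)[0]
        if len(active) >= 2:
            C = np.corrcoef(counts[active])
            iu = np.triu_indices(len(active), k=1)
            corrs.append(float(np.mean(C[iu])))
    mean_corr = float(np.mean(corrs)) if corrs else float("nan")

    return SpikeStats(
        mean_rate_hz=rate_to_hz(rates),
        cv_isi=cv,
        fano_factor=fano,
        mean_pairwise_correlation=mean_corr,
    )


def tuning_curves(
    net: Network | EINetwork,
    radius: float,
    angles: np.ndarray,
    duration_per_angle: float = 20.0,
    burn_in: float = 5.0,
    dims: tuple[int, int] = (0, 1),
    seed: int = 0,
) -> np.ndarray:
    """Per-neuron firing rate (spikes per τ) vs. angle of a constant-radius
    input in a 2-D slice of signal space (remaining channels clamped to 0).

    Returns a rate matrix of shape (N, n_angles); for EI networks the rows
    cover excitatory then inhibitory neurons.
    """
    angles = np.asarray(angles, dtype=float)
    if duration_per_angle <= burn_in:
        raise ValueError("duration_per_angle must exceed the burn-in")
    M = net.n_channels
    N = net.n_neurons
    out = np.zeros((N, len(angles)))
    skip = int(burn_in / net.dt)
    for a_idx, ang in enumerate(angles):
        probe = make_constant_angle(ang, radius, duration_per_angle, net.dt)
        if M > 2:
            c = np.zeros((M, probe.n_steps))
            x = np.zeros((M, probe.n_steps))
            c[list(dims)] = probe.c
            x[list(dims)] = probe.x
            probe = SignalBundle(c=c, x=x, dt=net.dt, meta=probe.meta)
        res = simulate(net, probe, seed=seed, raise_on_divergence=False)
        late = res.spikes[res.spikes[:, 0] >= skip]
        counts = np.bincount(late[:, 1], minlength=N)
        out[:, a_idx] = counts / ((res.n_steps - skip) * net.dt)
    return out


def coverage_gap(preferred_directions: np.ndarray) -> float:
    """Largest angular gap (degrees) between consecutive preferred
    directions on the circle.  360 for a degenerate (single-direction)
    population; 360/n for n uniformly spaced directions."""
    ang = np.sort(np.asarray(preferred_directions, dtype=float) % 360.0)
    if len(ang) < 2:
        raise ValueError("need at least two preferred directions")
    gaps = np.diff(ang)
    wrap = ang[0] + 360.0 - ang[-1]
    return float(max(gaps.max() if len(gaps) else 0.0, wrap))


def poisson_matched_error(
    trained_result: SimResult,
    x: np.ndarray,
    seed: int = 0,
    ridge_scale: float = 1e-4,
    rates: Optional[np.ndarray] = None,
) -> float:
    """Held-out decoding mse of rate-matched homogeneous Poisson neurons.

    Generates independent Poisson spike trains with each neuron's average
    rate from the trained run (per-step firing probability rate·dt), filters
    them with the readout filter, fits a fresh ridge decoder against x on
    the first half and returns the mse on the second half.  This is the
    baseline a spike-by-spike code is compared against: same neurons, same
    rates, but spikes carrying no coordinated information.
    """
    dt = trained_result.dt
    n = trained_result.n_steps
    N = trained_result.n_neurons
    if rates is None:
        rates = trained_result.rates()
    rng = np.random.default_rng(seed)
    p = np.clip(np.asarray(rates) * dt, 0.0, 1.0)
    spikes_bool = rng.random((N, n)) < p[:, None]
    ev = np.argwhere(spikes_bool)
    events = np.column_stack([ev[:, 1], ev[:, 0]])  # (step, neuron)
    r = filter_spikes(events, N, n, dt)
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    half = n // 2
    # give the baseline its best shrinkage: Poisson trains are sparse and
    # uninformative per regressor, so a single small ridge overfits badly
    # and would understate the baseline
    best = np.inf
    for lam_scale in (ridge_scale, 1e-2, 1.0, 1e2):
        dec = fit_decoder(r[:, :half], x[:, :half], ridge_lambda=lam_scale * half)
        x_hat = reconstruct(dec, r[:, half:])
        best = min(best, float(np.mean(np.sum((x[:, half:] - x_hat) ** 2, axis=0))))
    return best
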