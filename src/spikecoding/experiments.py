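"""Reproducible experiment runners tying the modules together.

Each runner executes one of the protocol families the learning rules are
validated on: two-signal learning in a small single population, EI-network
learning with per-population diagnostics, robustness sweeps (network size,
connection sparsity, injected noise, synaptic delay, against a rate-matched
Poisson baseline), and the lesion/selective-plasticity experiment.  All
runners are deterministic given (config, seed) and have scaled-down presets
suitable for continuous testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .metrics import (
    coverage_gap,
    poisson_matched_error,
    spike_stats,
    tuning_curves,
)
from .network import (
    EINetwork,
    Network,
    lesion,
    make_delay_kernel,
    preferred_directions,
    select_by_preferred_direction,
    simulate,
    sparsify,
)
from .plasticity import LearnConfig, Trajectory, evaluate_coding, train, train_ei
from .readout import fit_decoder, matrix_cosine, reconstruct
from .signals import SignalBundle, make_sinusoid_pair, make_smooth_noise

__all__ = [
    "ExperimentConfig",
    "make_network",
    "make_ei_network",
    "smooth_noise_source",
    "calibrate_input_gain",
    "run_two_signal",
    "run_ei",
    "run_robustness",
    "run_lesion",
    "plateaued",
]


@dataclass
class ExperimentConfig:
    """Declarative description of an experiment run.

    A config plus the code version determines every output given the seed.
    Unused fields are ignored by runners that do not need them.
    """

    name: str = "two_signal"
    # network
    n_neurons: int = 20
    n_exc: int = 60
    n_inh: int = 15
    n_channels: int = 2
    threshold: float = 0.5
    reset: float = -0.5
    gamma: float = 1.0
    dt: float = 1e-3
    # signal
    smoothing_tau: float = 0.5
    gain: float = 1.5
    # learning
    learn: LearnConfig = field(default_factory=LearnConfig)
    t_recurrent: float = 600.0
    t_joint: float = 2000.0
    checkpoint_every: float = 200.0
    # perturbations
    density: float = 1.0
    noise_sigma: float = 0.0
    delay: float = 0.0
    # evaluation (held-out decoder fits need ~100 τ to be stable)
    eval_duration: float = 100.0
    angle_step: float = 15.0
    radius: float = 1.0
    target_rate_e: float = 0.05
    target_rate_i: float = 0.10
    calibrate: bool = False
    # lesion
    lesion_center: float = 180.0
    lesion_width: float = 90.0
    retrain_time: float = 1000.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("learn"), dict):
            d["learn"] = LearnConfig(**d["learn"])
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _unit_rows(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    F = rng.standard_normal((n, m))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    return F


def make_network(
    N: int = 20,
    M: int = 2,
    seed: int = 0,
    lopsided: bool = False,
    gamma: float = 1.0,
    threshold: float = 0.5,
    reset: float = -0.5,
    dt: float = 1e-3,
    v_floor: bool = False,
) -> Network:
    """Fresh single-population network: random unit-norm feedforward rows
    (scaled by ``gamma``), zero recurrent off-diagonal, self-resets on the
    diagonal.  ``lopsided`` flips every neuron's first-channel weight
    negative, leaving half of a 2-D signal space uncovered."""
    rng = np.random.default_rng(seed)
    F = _unit_rows(N, M, rng) * gamma
    if lopsided:
        F[:, 0] = -np.abs(F[:, 0])
    return Network(
        F=F,
        Omega=np.eye(N) * reset,
        T=np.full(N, threshold),
        dt=dt,
        v_floor=v_floor,
    )


def make_ei_network(
    n_exc: int = 60,
    n_inh: int = 15,
    M: int = 2,
    seed: int = 0,
    gamma: float = 1.0,
    w_ie0: float = 0.4,
    threshold: float = 0.5,
    reset: float = -0.5,
    dt: float = 1e-3,
    lopsided: bool = False,
) -> EINetwork:
    """Fresh Dale-partitioned network.

    Input→E weights are random unit rows; E→I weights start as small random
    positive values (so the inhibitory population fires and its plasticity
    can engage); I→E, and the off-diagonals of E→E and I→I start at zero.
    """
    rng = np.random.default_rng(seed)
    F = _unit_rows(n_exc, M, rng) * gamma
    if lopsided:
        F[:, 0] = -np.abs(F[:, 0])
    W_IE = rng.uniform(0.0, w_ie0, size=(n_inh, n_exc))
    return EINetwork(
        F=F,
        W_IE=W_IE,
        W_EI=np.zeros((n_exc, n_inh)),
        W_II=np.eye(n_inh) * reset,
        W_EE=np.eye(n_exc) * reset,
        T_E=np.full(n_exc, threshold),
        T_I=np.full(n_inh, threshold),
        dt=dt,
    )


def smooth_noise_source(
    M: int = 2,
    smoothing_tau: float = 0.5,
    gain: float = 1.5,
    dt: float = 1e-3,
    covariance: Optional[np.ndarray] = None,
) -> Callable[[float, int], SignalBundle]:
    """Factory for the training-signal source: smoothed Gaussian noise with
    identity (or given) covariance, scaled by ``gain``."""

    def source(duration: float, seed: int) -> SignalBundle:
        sig = make_smooth_noise(
            M, duration, dt, covariance=covariance, smoothing_tau=smoothing_tau, seed=seed
        )
        return sig.scaled(gain)

    return source


def calibrate_input_gain(
    make_net: Callable[[], EINetwork],
    source_for_gain: Callable[[float], Callable[[float, int], SignalBundle]],
    cfg: ExperimentConfig,
    pilot_train: float = 150.0,
    tol: float = 0.15,
    max_iter: int = 8,
) -> float:
    """Bisection on the input gain so a briefly trained pilot network hits
    the target excitatory rate.  Rates increase monotonically with input
    gain, which the bisection relies on."""
    lo, hi = cfg.gain / 8.0, cfg.gain * 8.0
    gain = cfg.gain

    def pilot_rate(g: float) -> float:
        traj = train_ei(
            make_net(), source_for_gain(g), pilot_train, cfg.learn,
            checkpoint_every=pilot_train, eval_duration=15.0,
        )
        return traj.rates["E"][-1]

    for _ in range(max_iter):
        gain = np.sqrt(lo * hi)
        rate = pilot_rate(gain)
        if abs(rate - cfg.target_rate_e) <= tol * cfg.target_rate_e:
            break
        if rate < cfg.target_rate_e:
            lo = gain
        else:
            hi = gain
    return gain


def plateaued(traj: Trajectory, key: Optional[str] = None, rel_tol: float = 0.01) -> bool:
    """True when the error curve changed by < ``rel_tol`` (relative) over
    the last three checkpoints."""
    if key is None:
        key = next(iter(traj.errors))
    e = traj.errors[key]
    if len(e) < 3:
        return False
    tail = e[-3:]
    return (max(tail) - min(tail)) <= rel_tol * max(abs(tail[-1]), 1e-12)


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------


def _reconstruction_error(net, sig: SignalBundle, seed: int, ridge_scale: float) -> dict:
    """Fit a decoder on the first half of a test signal, report test mse and
    traces on the second half."""
    res = simulate(net, sig, seed=seed, raise_on_divergence=False)
    r = res.r if not isinstance(net, EINetwork) else res.split_ei()[0].r
    half = sig.n_steps // 2
    dec = fit_decoder(r[:, :half], sig.x[:, :half], ridge_lambda=ridge_scale * half)
    x_hat = reconstruct(dec, r[:, half:])
    mse = float(np.mean(np.sum((sig.x[:, half:] - x_hat) ** 2, axis=0)))
    return {"mse": mse, "x": sig.x[:, half:], "x_hat": x_hat, "decoder": dec, "result": res}


def run_two_signal(cfg: ExperimentConfig) -> dict:
    """Small-population learning experiment.

    A single population with a lopsided initial feedforward map (no neuron
    responds positively to the first signal) and zero recurrent
    off-diagonal is trained in two stages: recurrent plasticity only, then
    joint recurrent + feedforward.  Reports learning curves, sine/cosine
    test reconstructions and tuning/coverage diagnostics at each stage.
    """
    net0 = make_network(
        N=cfg.n_neurons, M=cfg.n_channels, seed=cfg.seed, lopsided=True,
        gamma=cfg.gamma, threshold=cfg.threshold, reset=cfg.reset, dt=cfg.dt,
    )
    source = smooth_noise_source(cfg.n_channels, cfg.smoothing_tau, cfg.gain, cfg.dt)
    angles = np.arange(-180.0, 180.0, cfg.angle_step)
    test_sig = make_sinusoid_pair(cfg.eval_duration, cfg.dt, amplitude=cfg.gain, period=8.0)

    report: dict = {"config": cfg.to_dict(), "stages": {}}

    def _stage_report(net, tag: str) -> None:
        rec = _reconstruction_error(net, test_sig, cfg.seed, cfg.learn.ridge_scale)
        tc = tuning_curves(net, cfg.radius * cfg.gain, angles, duration_per_angle=10.0, seed=cfg.seed)
        pref = angles[np.argmax(tc, axis=1)]
        active = tc.max(axis=1) > 0
        gap = coverage_gap(pref[active]) if active.sum() >= 2 else 360.0
        report["stages"][tag] = {
            "mse": rec["mse"],
            "x": rec["x"],
            "x_hat": rec["x_hat"],
            "tuning": tc,
            "angles": angles,
            "coverage_gap": gap,
            "mean_rate": float(np.mean(rec["result"].rates())),
            "network": net,
        }

    _stage_report(net0, "initial")

    cfg_learn = dataclasses.replace(cfg.learn, seed=cfg.seed)
    traj_rec = train(
        net0, source, cfg.t_recurrent, cfg_learn,
        checkpoint_every=cfg.checkpoint_every, learn_ff=False,
        eval_duration=cfg.eval_duration,
    )
    _stage_report(traj_rec.final_network, "recurrent_only")

    traj_joint = train(
        traj_rec.final_network, source, cfg.t_joint, cfg_learn,
        checkpoint_every=cfg.checkpoint_every, learn_ff=True,
        eval_duration=cfg.eval_duration,
    )
    _stage_report(traj_joint.final_network, "joint")

    report["trajectory_recurrent"] = traj_rec
    report["trajectory_joint"] = traj_joint
    report["plateaued"] = plateaued(traj_joint)
    # alignment of learnt recurrent weights with -F D for the post-hoc
    # optimal decoder
    final = traj_joint.final_network
    ev = evaluate_coding(final, source, cfg.seed + 1, duration=cfg.eval_duration)
    D_opt = ev["decoder_all"].D
    report["omega_cosine"] = matrix_cosine(final.Omega, -final.F @ D_opt)
    report["ff_decoder_discrepancy"] = float(
        np.linalg.norm(final.F - D_opt.T) / np.linalg.norm(final.F)
    )
    return report


def run_ei(cfg: ExperimentConfig, n_trials: int = 3) -> dict:
    """EI-network learning experiment with spike-statistics diagnostics.

    Trains the Dale-partitioned network, then compares pre/post: coding
    error per population, mean rates, CV/Fano/pairwise correlations over
    repeated frozen-input trials, EI current balance in single neurons, and
    tuning curves on a 2-D slice.
    """
    net0 = make_ei_network(
        n_exc=cfg.n_exc, n_inh=cfg.n_inh, M=cfg.n_channels, seed=cfg.seed,
        gamma=cfg.gamma, threshold=cfg.threshold, reset=cfg.reset, dt=cfg.dt,
    )
    source = smooth_noise_source(cfg.n_channels, cfg.smoothing_tau, cfg.gain, cfg.dt)
    cfg_learn = dataclasses.replace(cfg.learn, seed=cfg.seed)

    def _stats(net) -> dict:
        frozen = source(cfg.eval_duration, cfg.seed + 17)
        trials = [
            simulate(net, frozen, seed=cfg.seed + 100 + t, raise_on_divergence=False)
            for t in range(n_trials)
        ]
        # trial-to-trial variability needs a noise source; frozen input with
        # identical everything would be deterministic, so jitter initial V
        if net.noise_sigma == 0:
            rng = np.random.default_rng(cfg.seed + 55)
            trials = [
                simulate(
                    net, frozen, seed=cfg.seed + 100 + t,
                    V0=rng.uniform(-0.1, 0.1, net.n_neurons),
                    raise_on_divergence=False,
                )
                for t in range(n_trials)
            ]
        st = spike_stats(trials, bin_width=1.0)
        bal = ei_balance_correlation(net, frozen, seed=cfg.seed)
        return {"stats": st, "balance_correlation": bal}

    report: dict = {"config": cfg.to_dict()}
    report["pre"] = _stats(net0)
    report["pre"]["eval"] = evaluate_coding(net0, source, cfg.seed + 1, cfg.eval_duration)

    traj = train_ei(
        net0, source, cfg.t_joint, cfg_learn,
        checkpoint_every=cfg.checkpoint_every, eval_duration=cfg.eval_duration,
    )
    final = traj.final_network
    report["post"] = _stats(final)
    report["post"]["eval"] = evaluate_coding(final, source, cfg.seed + 1, cfg.eval_duration)
    report["trajectory"] = traj
    report["plateaued"] = plateaued(traj, "E")

    angles = np.arange(-180.0, 180.0, cfg.angle_step)
    report["tuning"] = tuning_curves(
        final, cfg.radius * cfg.gain, angles, duration_per_angle=10.0, seed=cfg.seed
    )
    report["angles"] = angles
    report["network"] = final
    return report


def ei_balance_correlation(net: EINetwork, sig: SignalBundle, seed: int = 0,
                           filter_tau: float = 0.3) -> float:
    """Mean per-neuron correlation between smoothed excitatory and
    inhibitory input currents into the excitatory cells (negative when
    inhibition tracks excitation)."""
    res = simulate(net, sig, seed=seed, record_currents=True, raise_on_divergence=False)
    ne = net.n_exc
    dtc = net.dt / filter_tau

    def smooth(a):
        out = np.empty_like(a)
        acc = np.zeros(a.shape[0])
        for t in range(a.shape[1]):
            acc += dtc * (a[:, t] / net.dt - acc)
            out[:, t] = acc
        return out

    exc = smooth(res.exc_in[:ne])
    inh = smooth(res.inh_in[:ne])
    cors = []
    for i in range(ne):
        if exc[i].std() > 0 and inh[i].std() > 0:
            cors.append(np.corrcoef(exc[i], inh[i])[0, 1])
    return float(np.mean(cors)) if cors else float("nan")


def _train_fresh_ei(cfg: ExperimentConfig, n_inh: int, density: float = 1.0,
                    noise_sigma: float = 0.0, delay: float = 0.0,
                    gain: Optional[float] = None, seed: Optional[int] = None) -> tuple:
    """Build, optionally perturb, and train an EI network; returns
    (trajectory, source)."""
    seed = cfg.seed if seed is None else seed
    n_exc = 2 * n_inh
    net = make_ei_network(
        n_exc=n_exc, n_inh=n_inh, M=cfg.n_channels, seed=seed,
        gamma=cfg.gamma, threshold=cfg.threshold, reset=cfg.reset, dt=cfg.dt,
    )
    net.noise_sigma = noise_sigma
    if delay > 0:
        net.delay_kernel = make_delay_kernel(delay, cfg.dt)
    if density < 1.0:
        net = sparsify(net, density, seed=seed + 3)
    g = cfg.gain if gain is None else gain
    source = smooth_noise_source(cfg.n_channels, cfg.smoothing_tau, g, cfg.dt)
    cfg_learn = dataclasses.replace(cfg.learn, seed=seed)
    traj = train_ei(
        net, source, cfg.t_joint, cfg_learn,
        checkpoint_every=cfg.checkpoint_every, eval_duration=cfg.eval_duration,
    )
    return traj, source


def _trained_vs_poisson(net: EINetwork, source, seed: int, duration: float,
                        ridge_scale: float) -> tuple[float, float]:
    """Held-out decoding mse of the trained E population and of a
    rate-matched Poisson population of the same size."""
    sig = source(duration, seed + 23)
    res = simulate(net, sig, seed=seed, raise_on_divergence=False)
    res_e, _ = res.split_ei()
    half = sig.n_steps // 2
    dec = fit_decoder(res_e.r[:, :half], sig.x[:, :half], ridge_lambda=ridge_scale * half)
    x_hat = reconstruct(dec, res_e.r[:, half:])
    mse = float(np.mean(np.sum((sig.x[:, half:] - x_hat) ** 2, axis=0)))
    pois = poisson_matched_error(res_e, sig.x, seed=seed + 31, ridge_scale=ridge_scale)
    return mse, pois


def run_robustness(cfg: ExperimentConfig, sweep: dict) -> pd.DataFrame:
    """Robustness sweep over one perturbation axis.

    ``sweep`` holds exactly one of the keys ``sizes`` (inhibitory counts;
    excitatory pool twice as large), ``densities``, ``noise_levels`` or
    ``delays``, plus optionally ``seeds`` (list of seeds, default [cfg.seed]).
    Each point trains a fresh EI network under the perturbation and reports
    the trained decoding mse next to the rate-matched Poisson baseline.
    Failed points are flagged and the sweep continues.
    """
    axes = {k: v for k, v in sweep.items() if k != "seeds"}
    if len(axes) != 1:
        raise ValueError("sweep must name exactly one axis")
    (axis, values), = axes.items()
    seeds = sweep.get("seeds", [cfg.seed])
    rows = []
    for val in values:
        for seed in seeds:
            kw = {"n_inh": cfg.n_inh, "density": 1.0, "noise_sigma": 0.0, "delay": 0.0}
            if axis == "sizes":
                kw["n_inh"] = int(val)
            elif axis == "densities":
                kw["density"] = float(val)
            elif axis == "noise_levels":
                kw["noise_sigma"] = float(val)
            elif axis == "delays":
                kw["delay"] = float(val)
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
            gain = None
            if cfg.calibrate:
                def mk():
                    return make_ei_network(
                        n_exc=2 * kw["n_inh"], n_inh=kw["n_inh"], M=cfg.n_channels,
                        seed=seed, gamma=cfg.gamma, dt=cfg.dt,
                    )
                gain = calibrate_input_gain(
                    mk,
                    lambda g: smooth_noise_source(cfg.n_channels, cfg.smoothing_tau, g, cfg.dt),
                    cfg,
                )
            try:
                traj, source = _train_fresh_ei(cfg, seed=seed, gain=gain, **kw)
                net = traj.final_network
                mse, pois = _trained_vs_poisson(
                    net, source, seed, cfg.eval_duration, cfg.learn.ridge_scale
                )
                rows.append({
                    "axis": axis, "value": val, "seed": seed,
                    "trained_mse": mse, "poisson_mse": pois,
                    "rate_E": traj.rates["E"][-1], "rate_I": traj.rates["I"][-1],
                    "failed": traj.failed,
                })
            except Exception as exc:  # pragma: no cover - defensive
                rows.append({
                    "axis": axis, "value": val, "seed": seed,
                    "trained_mse": np.nan, "poisson_mse": np.nan,
                    "rate_E": np.nan, "rate_I": np.nan,
                    "failed": True, "error": str(exc),
                })
    return pd.DataFrame(rows)


def run_lesion(cfg: ExperimentConfig, retrain_mode: str = "both",
               trained: Optional[EINetwork] = None,
               source: Optional[Callable] = None) -> dict:
    """Lesion/selective-plasticity experiment.

    Trains an EI network (or reuses ``trained``), deletes the excitatory
    neurons whose preferred direction falls in the configured angular
    window, then retrains with ``retrain_mode`` in {"both",
    "recurrent_only", "feedforward_only", "none"}.  Reports coding error,
    mean excitatory rates and tuning summaries for each stage.
    """
    if retrain_mode not in {"both", "recurrent_only", "feedforward_only", "none"}:
        raise ValueError(f"unknown retrain mode {retrain_mode!r}")
    if source is None:
        source = smooth_noise_source(cfg.n_channels, cfg.smoothing_tau, cfg.gain, cfg.dt)
    cfg_learn = dataclasses.replace(cfg.learn, seed=cfg.seed)
    if trained is None:
        net0 = make_ei_network(
            n_exc=cfg.n_exc, n_inh=cfg.n_inh, M=cfg.n_channels, seed=cfg.seed,
            gamma=cfg.gamma, threshold=cfg.threshold, reset=cfg.reset, dt=cfg.dt,
        )
        traj0 = train_ei(net0, source, cfg.t_joint, cfg_learn,
                         checkpoint_every=cfg.checkpoint_every,
                         eval_duration=cfg.eval_duration)
        trained = traj0.final_network

    report: dict = {"config": cfg.to_dict(), "retrain_mode": retrain_mode}

    def _eval(net, tag):
        # held-out error averaged over a few independent test signals; a
        # single short signal makes the stage comparisons noisy
        evs = [
            evaluate_coding(net, source, cfg.seed + 7 + 1000 * j, cfg.eval_duration)
            for j in range(3)
        ]
        report[tag] = {
            "mse": float(np.mean([e["mse_E"] for e in evs])),
            "rate_E": float(np.mean([e["rate_E"] for e in evs])),
            "rate_I": float(np.mean([e["rate_I"] for e in evs])),
            "network": net,
        }
        return evs[0]

    ev_pre = _eval(trained, "pre_lesion")

    # lesion: decoding-vector angles from the post-hoc optimal E decoder
    D_opt = ev_pre["decoder_E"].D
    ids = select_by_preferred_direction(
        trained, cfg.lesion_center, cfg.lesion_width, weights=D_opt.T
    )
    if len(ids) == 0 or len(ids) >= trained.n_exc:
        ids = select_by_preferred_direction(trained, cfg.lesion_center, cfg.lesion_width)
    report["lesioned_ids"] = ids
    lesioned = lesion(trained, ids)
    _eval(lesioned, "post_lesion")

    # per-neuron rates of survivors, for the rate-increase diagnostic
    probe = source(cfg.eval_duration, cfg.seed + 7)
    keep = np.setdiff1d(np.arange(trained.n_exc), ids)
    res_before = simulate(trained, probe, seed=cfg.seed, raise_on_divergence=False)
    res_after = simulate(lesioned, probe, seed=cfg.seed, raise_on_divergence=False)
    report["survivor_rates_pre"] = res_before.split_ei()[0].rates()[keep]
    report["survivor_rates_post"] = res_after.split_ei()[0].rates()
    report["survivor_pref"] = preferred_directions(D_opt.T[keep]) if D_opt.shape[0] == 2 else None

    if retrain_mode == "none":
        report["final"] = report["post_lesion"]
        return report

    learn_rec = retrain_mode in {"both", "recurrent_only"}
    learn_ff = retrain_mode in {"both", "feedforward_only"}
    traj = train_ei(
        lesioned, source, cfg.retrain_time, cfg_learn,
        checkpoint_every=min(cfg.checkpoint_every, cfg.retrain_time),
        learn_rec=learn_rec, learn_ff=learn_ff, eval_duration=cfg.eval_duration,
    )
    _eval(traj.final_network, "final")
    report["trajectory"] = traj
    return report
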