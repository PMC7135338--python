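"""Local plasticity rules and training loops.

Two spike-gated rules drive the network into the efficient regime:

* the **recurrent rule**, applied to a presynaptic neuron k's outgoing
  column each time k spikes,

      ΔΩ_ik = -η_r ( β (V_i + μ r_i) + Ω_ik + μ δ_ik ),

  with V_i the postsynaptic membrane potential *before* the spike arrives.
  Its stationary point is Ω_ik = -β⟨V_i + μ r_i⟩_k - μ δ_ik; with the
  voltage-error identity this is exactly Ω = -F D for the decoder
  D_jk = β⟨x_j - x̂_j⟩_k (β = 2 when μ = 0 recovers the bare rule
  ΔΩ_ik ∝ -(2 V_i + Ω_ik)).

* the **feedforward rule**, applied to neuron i's input row each time i
  spikes,

      ΔF_ij = η_f ( x_j - α F_ij ),

  a Hebbian drift of the weights toward the inputs that make the neuron
  fire.  For correlated inputs the decay term α F_ij is replaced by
  α·Cov(x_j, g_i) with g_i the neuron's total input drive, tracked by a
  running (exponentially weighted) covariance estimator.

Recurrent plasticity must run on a faster time scale than feedforward
plasticity (η_f < η_r) so the network stays balanced while the feedforward
weights drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _kernels
from .network import EINetwork, Network, SimResult, simulate
from .readout import fit_decoder, reconstruct
from .signals import SignalBundle

__all__ = [
    "LearnConfig",
    "Trajectory",
    "recurrent_update",
    "feedforward_update",
    "feedforward_update_cov",
    "RunningCovariance",
    "train",
    "train_ei",
    "evaluate_coding",
    "stationary_decoder",
]


@dataclass
class LearnConfig:
    """Plasticity constants.

    beta, mu : voltage gain and quadratic rate-cost weight of the recurrent
        rule; alpha : decay constant of the feedforward rule; alpha_ie :
        decay for the E→I feedforward rule (defaults to alpha); eta_rec,
        eta_ff : learning rates per presynaptic/postsynaptic spike.  The
        proportionality constants of the continuous-time rules are absorbed
        into the learning rates.  schedule, if given, divides both rates by
        (1 + t / t_decay) at learning time t.
    """

    beta: float = 1.0
    mu: float = 0.05
    alpha: float = 1.9
    alpha_ie: float = 1.0
    eta_rec: float = 0.01
    eta_ff: float = 0.001
    eta_ie: Optional[float] = None
    ridge_scale: float = 1e-4
    cov_tau: float = 50.0
    schedule: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.alpha <= 0:
            raise ValueError("beta and alpha must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.eta_ff < 0 or self.eta_rec < 0:
            raise ValueError("learning rates must be non-negative")
        frozen = self.eta_ff == 0 and self.eta_rec == 0
        if not frozen and not self.eta_ff < self.eta_rec:
            raise ValueError(
                "feedforward plasticity must be slower than recurrent "
                "(eta_ff < eta_rec)"
            )
        if self.alpha_ie is None:
            self.alpha_ie = self.alpha
        if self.eta_ie is None:
            self.eta_ie = self.eta_ff

    def rates_at(self, t: float) -> tuple[float, float, float]:
        if self.schedule is None:
            return self.eta_rec, self.eta_ff, self.eta_ie
        t0 = float(self.schedule.get("t_decay", 1000.0))
        f = 1.0 / (1.0 + t / t0)
        return self.eta_rec * f, self.eta_ff * f, self.eta_ie * f


@dataclass
class Trajectory:
    """Learning curves recorded at checkpoints.

    ``errors`` holds the held-out coding mse per checkpoint; for EI
    training the keys "E" and "I" hold per-population errors (decoding the
    input from each population's spikes).  ``rates`` holds mean population
    rates in spikes per τ.
    """

    times: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    final_network: object = None
    failed: bool = False

    def add(self, t: float, errs: dict, rts: dict) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("learning time must be strictly increasing")
        self.times.append(t)
        for k, v in errs.items():
            self.errors.setdefault(k, []).append(v)
        for k, v in rts.items():
            self.rates.setdefault(k, []).append(v)

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        for k, v in self.errors.items():
            data[f"error_{k}"] = v
        for k, v in self.rates.items():
            data[f"rate_{k}"] = v
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# single-synapse reference operations
# ---------------------------------------------------------------------------


def recurrent_update(
    Omega: np.ndarray,
    V: np.ndarray,
    r: np.ndarray,
    k: int,
    cfg: LearnConfig,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Apply the recurrent rule to column k (presynaptic spike of neuron k).

    V and r are the pre-spike membrane voltages and filtered trains.
    Returns a new matrix; masked entries are untouched.
    """
    Omega = np.array(Omega, dtype=np.float64)
    N = Omega.shape[0]
    if not 0 <= k < N:
        raise ValueError(f"presynaptic index {k} out of range for N={N}")
    V = np.asarray(V, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    delta = np.zeros(N)
    delta[k] = 1.0
    dw = -cfg.eta_rec * (cfg.beta * (V + cfg.mu * r) + Omega[:, k] + cfg.mu * delta)
    if mask is not None:
        dw = np.where(mask[:, k], dw, 0.0)
    Omega[:, k] += dw
    return Omega


def feedforward_update(
    F: np.ndarray, x: np.ndarray, i: int, cfg: LearnConfig
) -> np.ndarray:
    """Apply the feedforward rule to row i (neuron i fired a spike).

    x is the signal vector at the spike time.  Rows of non-firing neurons
    are untouched.
    """
    F = np.array(F, dtype=np.float64)
    if not 0 <= i < F.shape[0]:
        raise ValueError(f"neuron index {i} out of range")
    F[i] += cfg.eta_ff * (np.asarray(x, dtype=np.float64) - cfg.alpha * F[i])
    return F


class RunningCovariance:
    """Exponentially weighted covariance of (input drive, signal) pairs.

    Tracks Cov(g_i, x_j) for each neuron i and channel j with time constant
    ``tau`` (in τ units): means and covariance are EMAs updated once per
    step of size dt.
    """

    def __init__(self, n_neurons: int, n_channels: int, tau: float, dt: float):
        self.mean_x = np.zeros(n_channels)
        self.mean_g = np.zeros(n_neurons)
        self.cov = np.zeros((n_neurons, n_channels))
        self.a = dt / tau

    def update(self, g: np.ndarray, x: np.ndarray) -> None:
        a = self.a
        self.mean_x += a * (x - self.mean_x)
        self.mean_g += a * (g - self.mean_g)
        dev = np.outer(g - self.mean_g, x - self.mean_x)
        self.cov += a * (dev - self.cov)


def feedforward_update_cov(
    F: np.ndarray,
    x: np.ndarray,
    i: int,
    cfg: LearnConfig,
    cov: RunningCovariance,
) -> np.ndarray:
    """Correlated-input variant of the feedforward rule.

    The decay term uses the running covariance of each presynaptic channel
    with the neuron's total input drive in place of the weight itself:
    ΔF_ij = η_f (x_j - α Cov(x_j, g_i)).  For uncorrelated unit-variance
    inputs Cov(x_j, g_i) = F_ij and the rule reduces to the plain one.
    """
    F = np.array(F, dtype=np.float64)
    if not 0 <= i < F.shape[0]:
        raise ValueError(f"neuron index {i} out of range")
    F[i] += cfg.eta_ff * (np.asarray(x, dtype=np.float64) - cfg.alpha * cov.cov[i])
    return F


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_coding(
    net: Network | EINetwork,
    source: Callable[[float, int], SignalBundle],
    seed: int,
    duration: float = 30.0,
    ridge_scale: float = 1e-4,
    burn_in: float = 2.0,
) -> dict:
    """Held-out coding error and mean rates with a freshly fitted decoder.

    Simulates (plasticity off) on a fresh signal, fits a ridge decoder on
    the first half and reports the mse on the second half.  For an EI
    network the input is decoded separately from the excitatory and the
    inhibitory spike trains.
    """
    sig = source(duration, seed)
    res = simulate(net, sig, seed=seed, raise_on_divergence=False)
    skip = int(burn_in / net.dt)
    out = {"stable": res.stable}

    def _score(r: np.ndarray, tag: str) -> None:
        x = sig.x[:, skip:]
        rr = r[:, skip:]
        half = rr.shape[1] // 2
        lam = ridge_scale * half
        dec = fit_decoder(rr[:, :half], x[:, :half], ridge_lambda=lam)
        x_hat = reconstruct(dec, rr[:, half:])
        out[f"mse_{tag}"] = float(np.mean(np.sum((x[:, half:] - x_hat) ** 2, axis=0)))
        out[f"decoder_{tag}"] = dec

    if isinstance(net, EINetwork):
        res_e, res_i = res.split_ei()
        _score(res_e.r, "E")
        _score(res_i.r, "I")
        out["rate_E"] = float(np.mean(res_e.rates()))
        out["rate_I"] = float(np.mean(res_i.rates()))
        out["mse"] = out["mse_E"]
    else:
        _score(res.r, "all")
        out["mse"] = out["mse_all"]
        out["rate"] = float(np.mean(res.rates()))
    return out


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def _train_loop(
    net,
    source: Callable[[float, int], SignalBundle],
    total_time: float,
    cfg: LearnConfig,
    checkpoint_every: float,
    learn_rec: bool,
    learn_f: bool,
    learn_ie: bool,
    ff_cov: bool,
    eval_duration: float,
) -> Trajectory:
    is_ei = isinstance(net, EINetwork)
    work = net.copy()
    if is_ei:
        Fc, Om, Tc = work.combined()
        n_e = work.n_exc
        dale = work.dale_rectify
    else:
        Fc, Om, Tc = work.F, work.Omega, work.T
        n_e = work.n_neurons
        dale = False
    Fc = np.ascontiguousarray(Fc)
    Om = np.ascontiguousarray(Om)
    # latent weights the rules act on; transmitted = rectified latent.
    # Starting latent at the transmitted values means previously clipped
    # synapses re-enter at zero, which a fresh training run re-settles.
    OmL = Om.copy()
    N = Fc.shape[0]
    M = Fc.shape[1]
    mask = work.mask if work.mask is not None else np.ones((N, N), dtype=bool)
    kern = np.ascontiguousarray(work.delay_kernel)
    L = len(kern)
    dt = work.dt

    V = np.zeros(N)
    r = np.zeros(N)
    buf = np.zeros((N, max(L, 1)))
    buf_pos = 0
    covC = np.zeros((N, M))
    mean_x = np.zeros(M)
    mean_g = np.zeros(N)
    dummy = np.zeros((1, 1))
    guard_abs = float(work.guard) * float(np.max(np.abs(Tc)))

    rng = np.random.default_rng(cfg.seed)
    traj = Trajectory()
    n_chunks = max(int(round(total_time / checkpoint_every)), 1)
    t_learn = 0.0
    eval_seed = int(rng.integers(2**31 - 1))

    def _sync_back() -> None:
        if is_ei:
            work.set_combined(Fc, Om)
        else:
            work.F, work.Omega = Fc, Om

    def _checkpoint() -> None:
        _sync_back()
        ev = evaluate_coding(
            work, source, eval_seed, duration=eval_duration, ridge_scale=cfg.ridge_scale
        )
        if is_ei:
            traj.add(
                t_learn,
                {"E": ev["mse_E"], "I": ev["mse_I"]},
                {"E": ev["rate_E"], "I": ev["rate_I"]},
            )
        else:
            traj.add(t_learn, {"all": ev["mse_all"]}, {"all": ev["rate"]})

    for _ in range(n_chunks):
        sig = source(checkpoint_every, int(rng.integers(2**31 - 1)))
        eta_r, eta_f, eta_i = cfg.rates_at(t_learn)
        _, _, _, _, diverged, buf_pos = _kernels.run_network(
            np.ascontiguousarray(sig.c.T),
            np.ascontiguousarray(sig.x.T),
            dt,
            Fc,
            Om,
            OmL,
            np.ascontiguousarray(Tc),
            np.ascontiguousarray(mask),
            n_e,
            float(work.noise_sigma),
            kern,
            V,
            r,
            buf,
            buf_pos,
            int(rng.integers(2**31 - 1)),
            learn_rec,
            learn_f,
            learn_ie,
            dale,
            ff_cov,
            eta_r,
            eta_f,
            eta_i,
            cfg.beta,
            cfg.mu,
            cfg.alpha,
            cfg.alpha_ie,
            covC,
            mean_x,
            mean_g,
            cfg.cov_tau,
            bool(work.v_floor),
            guard_abs,
            dummy,
            False,
            dummy,
            dummy,
            False,
        )
        t_learn += checkpoint_every
        if diverged >= 0:
            traj.failed = True
            _sync_back()
            traj.final_network = work
            return traj
        _checkpoint()

    _sync_back()
    traj.final_network = work
    return traj


def train(
    net: Network,
    source: Callable[[float, int], SignalBundle],
    total_time: float,
    cfg: LearnConfig,
    checkpoint_every: float = 100.0,
    learn_ff: bool = True,
    learn_rec: bool = True,
    ff_cov: bool = False,
    eval_duration: float = 30.0,
) -> Trajectory:
    """Train a single-population network.

    Interleaves simulation with per-spike plasticity (recurrent rule always
    available, feedforward rule optional), checkpointing the held-out coding
    error and mean rate every ``checkpoint_every`` τ.  ``ff_cov`` switches
    the feedforward rule to its correlated-input (running covariance)
    variant.
    """
    if isinstance(net, EINetwork):
        raise TypeError("use train_ei for EI networks")
    return _train_loop(
        net, source, total_time, cfg, checkpoint_every,
        learn_rec, learn_ff, False, ff_cov, eval_duration,
    )


def train_ei(
    net: EINetwork,
    source: Callable[[float, int], SignalBundle],
    total_time: float,
    cfg: LearnConfig,
    checkpoint_every: float = 100.0,
    learn_ff: bool = True,
    learn_rec: bool = True,
    eval_duration: float = 30.0,
) -> Trajectory:
    """Train an EI network.

    Input→E weights and the E→I weights (the I population's feedforward
    input, driven by the filtered excitatory trains) follow the feedforward
    rule; E→E, I→E and I→I follow the recurrent rule with each target
    neuron's voltage.  Dale sign constraints are maintained by rectification
    when ``net.dale_rectify`` is set.  The trajectory records errors and
    rates separately per population.
    """
    if not isinstance(net, EINetwork):
        raise TypeError("train_ei requires an EINetwork")
    # the E→I connections belong to the recurrent balancing loop even
    # though they follow the feedforward-form rule, so they are gated by
    # learn_rec (selective-plasticity experiments freeze them together
    # with the recurrent rule)
    return _train_loop(
        net, source, total_time, cfg, checkpoint_every,
        learn_rec, learn_ff, learn_rec, False, eval_duration,
    )


# ---------------------------------------------------------------------------
# stationary-point analysis
# ---------------------------------------------------------------------------


def spike_triggered_errors(
    result: SimResult, sig: SignalBundle, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coding errors at the pre-spike instants, grouped by firing neuron.

    For a spike event (t, k) the error is e = x[t+1] - D (1-dt) r[t]
    (signal and readout advanced to the spike decision instant, readout
    before the spike's own jump).  Returns (errors, neuron_ids) with errors
    of shape (n_spikes, M).
    """
    x, r, dt = sig.x, result.r, result.dt
    steps = result.spikes[:, 0]
    ids = result.spikes[:, 1]
    e = x[:, steps + 1].T - ((1.0 - dt) * r[:, steps].T) @ np.asarray(D).T
    return e, ids


def stationary_decoder(
    F: np.ndarray,
    source: Callable[[float, int], SignalBundle],
    T: np.ndarray,
    beta: float = 2.0,
    duration: float = 500.0,
    dt: float = 1e-3,
    seed: int = 0,
    n_iter: int = 25,
    damping: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent empirical decoder D_jk = β ⟨x_j - x̂_j⟩_k.

    Iterates: simulate with Ω = -F D, re-estimate D from the spike-triggered
    errors, with damped updates D ← (1-λ)D + λ β⟨e⟩ (the undamped map is
    not a contraction).  At the fixed point the time-averaged recurrent
    update vanishes (Ω = -F D is the stationary point of the recurrent
    rule with μ = 0).

    Returns (D, se) where ``se`` holds the per-entry standard error of the
    final estimate (needed to judge stationarity of the rule against the
    decoder's own estimation noise).
    """
    F = np.asarray(F, dtype=np.float64)
    N = F.shape[0]
    D = F.T.copy()
    se = np.zeros_like(D)
    sig = source(duration, seed)
    for it in range(n_iter):
        net = Network(F=F, Omega=-F @ D - 1e-9 * np.eye(N), T=T, dt=dt)
        res = simulate(net, sig, seed=seed)
        e, ids = spike_triggered_errors(res, sig, D)
        D_new = D.copy()
        for k in range(N):
            sel = ids == k
            nk = int(sel.sum())
            if nk > 1:
                D_new[:, k] = beta * e[sel].mean(axis=0)
                se[:, k] = beta * e[sel].std(axis=0, ddof=1) / np.sqrt(nk)
        D = (1 - damping) * D + damping * D_new
    return D, se
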