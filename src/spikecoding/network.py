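"""Leaky integrate-and-fire network containers and simulation.

Two architectures are provided.  ``Network`` is the simplified population in
which single neurons may both excite and inhibit others (recurrent matrix Ω
with self-resets on the diagonal).  ``EINetwork`` splits the population into
excitatory (E) and inhibitory (I) neurons obeying Dale's law: E cells
receive the analog input through F and send non-negative weights (E→E,
E→I); I cells receive the excitatory spike trains as their "feedforward"
input and send non-positive weights (I→E, I→I).

Both are simulated by the same jitted kernel; the EI network is mapped onto
combined block matrices first.  Robustness perturbations — connection
sparsity masks, injected white-noise currents, and alpha-function synaptic
delay kernels — are fields of the network objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .signals import SignalBundle

__all__ = [
    "Network",
    "EINetwork",
    "SimResult",
    "simulate",
    "make_delay_kernel",
    "sparsify",
    "lesion",
    "select_by_preferred_direction",
]


def _as_f64(a) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=np.float64))


@dataclass
class Network:
    """Single-population LIF network.

    F : (N, M) feedforward weights; Omega : (N, N) recurrent weights with
    self-resets Ω_ii < 0 on the diagonal; T : (N,) firing thresholds.
    Perturbation state: ``noise_sigma`` (std of injected current per τ and
    threshold), ``delay_kernel`` (postsynaptic current profile; empty means
    instantaneous synapses), ``mask`` (allowed connections; None means all).
    ``v_floor`` clips voltages at -T_i, a stabilizer for the
    pre-convergence regime.
    """

    F: np.ndarray
    Omega: np.ndarray
    T: np.ndarray
    dt: float = 1e-3
    noise_sigma: float = 0.0
    delay_kernel: np.ndarray = field(default_factory=lambda: np.empty(0))
    mask: Optional[np.ndarray] = None
    v_floor: bool = False
    guard: float = 100.0

    def __post_init__(self) -> None:
        self.F = _as_f64(self.F)
        self.Omega = _as_f64(self.Omega)
        self.T = _as_f64(np.atleast_1d(self.T))
        self.delay_kernel = _as_f64(self.delay_kernel)
        N = self.F.shape[0]
        if self.Omega.shape != (N, N):
            raise ValueError(f"Omega must be ({N},{N}), got {self.Omega.shape}")
        if self.T.shape != (N,):
            raise ValueError(f"T must have length {N}")
        if not np.all(np.isfinite(self.F)) or not np.all(np.isfinite(self.Omega)):
            raise ValueError("non-finite network weights")
        if np.any(np.diag(self.Omega) >= 0):
            raise ValueError("diagonal of Omega (self-resets) must be negative")
        if self.mask is not None:
            self.mask = np.ascontiguousarray(np.asarray(self.mask, dtype=bool))
            if self.mask.shape != (N, N):
                raise ValueError("mask shape mismatch")
            if np.any(self.Omega[~self.mask] != 0):
                raise ValueError("Omega must be zero on masked-out connections")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_channels(self) -> int:
        return self.F.shape[1]

    def copy(self) -> "Network":
        return replace(
            self,
            F=self.F.copy(),
            Omega=self.Omega.copy(),
            T=self.T.copy(),
            delay_kernel=self.delay_kernel.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )


@dataclass
class EINetwork:
    """Dale-partitioned network of excitatory and inhibitory populations.

    F : (N_E, M) input→E weights.  W_IE : (N_I, N_E) E→I weights (the I
    population's feedforward input).  W_EI : (N_E, N_I) I→E.  W_II and W_EE
    are the within-population recurrences; their diagonals are the
    self-resets and must be negative.  Sign conventions (Dale): E sends
    non-negative weights, I sends non-positive weights.
    """

    F: np.ndarray
    W_IE: np.ndarray
    W_EI: np.ndarray
    W_II: np.ndarray
    W_EE: np.ndarray
    T_E: np.ndarray
    T_I: np.ndarray
    dt: float = 1e-3
    noise_sigma: float = 0.0
    delay_kernel: np.ndarray = field(default_factory=lambda: np.empty(0))
    mask: Optional[np.ndarray] = None  # combined (N_E+N_I)² mask
    v_floor: bool = False
    guard: float = 100.0
    dale_rectify: bool = True

    def __post_init__(self) -> None:
        for name in ("F", "W_IE", "W_EI", "W_II", "W_EE"):
            setattr(self, name, _as_f64(getattr(self, name)))
        self.T_E = _as_f64(np.atleast_1d(self.T_E))
        self.T_I = _as_f64(np.atleast_1d(self.T_I))
        self.delay_kernel = _as_f64(self.delay_kernel)
        ne, ni = self.n_exc, self.n_inh
        if self.W_IE.shape != (ni, ne):
            raise ValueError("W_IE must be (N_I, N_E)")
        if self.W_EI.shape != (ne, ni):
            raise ValueError("W_EI must be (N_E, N_I)")
        if self.W_II.shape != (ni, ni) or self.W_EE.shape != (ne, ne):
            raise ValueError("W_II / W_EE shape mismatch")
        if self.T_E.shape != (ne,) or self.T_I.shape != (ni,):
            raise ValueError("threshold length mismatch")
        if np.any(np.diag(self.W_EE) >= 0) or np.any(np.diag(self.W_II) >= 0):
            raise ValueError("self-resets (diagonals of W_EE, W_II) must be negative")
        if self.dale_rectify:
            off_ee = self.W_EE - np.diag(np.diag(self.W_EE))
            off_ii = self.W_II - np.diag(np.diag(self.W_II))
            if np.any(off_ee < 0) or np.any(self.W_IE < 0):
                raise ValueError("excitatory weights (W_EE off-diag, W_IE) must be >= 0")
            if np.any(off_ii > 0) or np.any(self.W_EI > 0):
                raise ValueError("inhibitory weights (W_EI, W_II off-diag) must be <= 0")
        if self.mask is not None:
            N = ne + ni
            self.mask = np.ascontiguousarray(np.asarray(self.mask, dtype=bool))
            if self.mask.shape != (N, N):
                raise ValueError("mask must cover the combined population")

    @property
    def n_exc(self) -> int:
        return self.F.shape[0]

    @property
    def n_inh(self) -> int:
        return self.W_II.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def n_channels(self) -> int:
        return self.F.shape[1]

    def combined(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Combined (F, Omega, T) block matrices; I rows of F are zero."""
        ne, ni, M = self.n_exc, self.n_inh, self.n_channels
        Fc = np.zeros((ne + ni, M))
        Fc[:ne] = self.F
        Om = np.block([[self.W_EE, self.W_EI], [self.W_IE, self.W_II]])
        Tc = np.concatenate([self.T_E, self.T_I])
        return Fc, Om, Tc

    def set_combined(self, Fc: np.ndarray, Om: np.ndarray) -> None:
        """Write combined matrices back into the blocks (after learning)."""
        ne = self.n_exc
        self.F = _as_f64(Fc[:ne])
        self.W_EE = _as_f64(Om[:ne, :ne])
        self.W_EI = _as_f64(Om[:ne, ne:])
        self.W_IE = _as_f64(Om[ne:, :ne])
        self.W_II = _as_f64(Om[ne:, ne:])

    def copy(self) -> "EINetwork":
        return replace(
            self,
            F=self.F.copy(),
            W_IE=self.W_IE.copy(),
            W_EI=self.W_EI.copy(),
            W_II=self.W_II.copy(),
            W_EE=self.W_EE.copy(),
            T_E=self.T_E.copy(),
            T_I=self.T_I.copy(),
            delay_kernel=self.delay_kernel.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )


@dataclass
class SimResult:
    """Outcome of a simulation run.

    ``spikes`` is an event list of (step, neuron) pairs; the spike at step t
    affects the filtered trains and voltages from step t+1 on.  ``r`` holds
    the exponentially filtered spike trains (unit leak, unit jump).  For an
    EI run, neuron indices [0, n_exc) are excitatory.  ``v_pre`` records the
    firing neuron's pre-spike membrane voltage for each event.
    """

    spikes: np.ndarray
    r: np.ndarray
    dt: float
    seed: int
    V: Optional[np.ndarray] = None
    v_pre: Optional[np.ndarray] = None
    n_exc: Optional[int] = None
    n_multi: int = 0
    diverged_step: int = -1
    exc_in: Optional[np.ndarray] = None
    inh_in: Optional[np.ndarray] = None

    @property
    def n_steps(self) -> int:
        return self.r.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.r.shape[0]

    @property
    def stable(self) -> bool:
        return self.diverged_step < 0

    def rates(self) -> np.ndarray:
        """Per-neuron mean firing rate in spikes per τ."""
        counts = np.bincount(self.spikes[:, 1], minlength=self.n_neurons)
        return counts / (self.n_steps * self.dt)

    def split_ei(self) -> tuple["SimResult", "SimResult"]:
        """Split an EI result into (excitatory, inhibitory) sub-results."""
        if self.n_exc is None:
            raise ValueError("not an EI simulation result")
        ne = self.n_exc
        e_mask = self.spikes[:, 1] < ne
        sp_e = self.spikes[e_mask]
        sp_i = self.spikes[~e_mask].copy()
        sp_i[:, 1] -= ne
        res_e = SimResult(sp_e, self.r[:ne], self.dt, self.seed,
                          V=None if self.V is None else self.V[:ne])
        res_i = SimResult(sp_i, self.r[ne:], self.dt, self.seed,
                          V=None if self.V is None else self.V[ne:])
        return res_e, res_i


class DivergenceError(RuntimeError):
    """Raised when membrane voltages exceed the runaway guard."""


def make_delay_kernel(d: float, dt: float) -> np.ndarray:
    """Alpha-function synaptic current profile with time-to-peak ``d``.

    Returns the per-step current injected after a presynaptic spike,
    normalized to unit total charge, shaped so that the resulting
    postsynaptic *potential* (the current filtered by the unit membrane
    leak) peaks at time d after the spike.  d = 0 returns the empty kernel,
    i.e. instantaneous voltage jumps.

    The current profile is c(s) ∝ s·exp(-s/τ_d); the leaky-integrated PSP
    then peaks at a time set by τ_d, located numerically so that the peak
    lands on d.
    """
    if d < 0:
        raise ValueError("delay must be non-negative")
    if d == 0:
        return np.empty(0)

    def psp_peak(tau_d: float) -> float:
        horizon = max(6.0 * tau_d, 2.0 * d, 20 * dt)
        n = int(round(horizon / dt))
        s = np.arange(n) * dt
        cur = s * np.exp(-s / tau_d)
        tot = cur.sum()
        if tot <= 0:
            return 0.0
        cur = cur / tot
        # PSP: leaky integration of the current (unit membrane leak)
        v = 0.0
        peak_t = 0.0
        peak_v = -np.inf
        for i in range(n):
            v = (1.0 - dt) * v + cur[i]
            if v > peak_v:
                peak_v = v
                peak_t = s[i]
        return peak_t

    lo, hi = dt / 10.0, max(4.0 * d, 10 * dt)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if psp_peak(mid) < d:
            lo = mid
        else:
            hi = mid
    tau_d = 0.5 * (lo + hi)
    horizon = max(6.0 * tau_d, 2.0 * d)
    n = max(int(round(horizon / dt)), 2)
    s = np.arange(n) * dt
    cur = s * np.exp(-s / tau_d)
    return cur / cur.sum()


def simulate(
    net: Network | EINetwork,
    sig: SignalBundle,
    seed: int = 0,
    record_voltage: bool = False,
    record_currents: bool = False,
    V0: Optional[np.ndarray] = None,
    raise_on_divergence: bool = True,
) -> SimResult:
    """Forward-Euler simulation of the spiking dynamics.

    At most one spike is fired per time step network-wide: among all neurons
    at or above threshold, the one with the largest excess V_i - T_i fires,
    and its outgoing recurrent column (including its self-reset) is applied
    within the step.  Reproducible for a fixed seed.
    """
    if abs(sig.dt - net.dt) > 1e-12:
        raise ValueError(f"signal dt {sig.dt} != network dt {net.dt}")
    is_ei = isinstance(net, EINetwork)
    if is_ei:
        Fc, Om, Tc = net.combined()
        n_e = net.n_exc
    else:
        Fc, Om, Tc = net.F, net.Omega, net.T
        n_e = net.n_neurons
    N = Fc.shape[0]
    n = sig.n_steps
    mask = net.mask if net.mask is not None else np.ones((N, N), dtype=bool)
    kern = net.delay_kernel
    L = len(kern)

    V = np.zeros(N) if V0 is None else _as_f64(V0).copy()
    r = np.zeros(N)
    buf = np.zeros((N, max(L, 1)))
    Vtrace = np.zeros((N, n)) if record_voltage else np.zeros((1, 1))
    exc = np.zeros((N, n)) if record_currents else np.zeros((1, 1))
    inh = np.zeros((N, n)) if record_currents else np.zeros((1, 1))
    dummy_cov = np.zeros((1, 1))

    spk_step, spk_id, v_pre, n_multi, diverged, _ = _kernels.run_network(
        np.ascontiguousarray(sig.c.T),
        np.ascontiguousarray(sig.x.T),
        net.dt,
        _as_f64(Fc.copy()),
        _as_f64(Om.copy()),
        _as_f64(Om.copy()),
        _as_f64(Tc),
        np.ascontiguousarray(mask),
        n_e,
        float(net.noise_sigma),
        _as_f64(kern),
        V,
        r,
        buf,
        0,
        int(seed) % (2**31),
        False,
        False,
        False,
        False,
        False,
        0.0,
        0.0,
        0.0,
        0.0,
        0.0,
        0.0,
        0.0,
        dummy_cov,
        np.zeros(1),
        np.zeros(1),
        1.0,
        bool(net.v_floor),
        float(net.guard) * float(np.max(np.abs(Tc))),
        Vtrace,
        record_voltage,
        exc,
        inh,
        record_currents,
    )
    if diverged >= 0 and raise_on_divergence:
        raise DivergenceError(
            f"voltage exceeded guard ({net.guard}x max threshold) at step {diverged}; "
            "dynamics unstable"
        )

    spikes = np.column_stack([spk_step, spk_id]).astype(np.int64)
    r_full = _filtered_trains(spikes, N, n, net.dt)
    return SimResult(
        spikes=spikes,
        r=r_full,
        dt=net.dt,
        seed=seed,
        V=Vtrace if record_voltage else None,
        v_pre=v_pre,
        n_exc=net.n_exc if is_ei else None,
        n_multi=n_multi,
        diverged_step=diverged,
        exc_in=exc if record_currents else None,
        inh_in=inh if record_currents else None,
    )


def _filtered_trains(spikes: np.ndarray, N: int, n: int, dt: float) -> np.ndarray:
    from .readout import filter_spikes

    return filter_spikes(spikes, N, n, dt)


def sparsify(net: Network | EINetwork, density: float, seed: int = 0):
    """Randomly delete off-diagonal recurrent connections.

    Keeps exactly round(density · n_offdiag) off-diagonal connections,
    sampled without replacement; diagonals (self-resets) are always
    retained.  Masked entries are zeroed and frozen: plasticity never
    writes them.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = net.copy()
    N = net.n_neurons
    off = [(i, j) for i in range(N) for j in range(N) if i != j]
    keep_n = int(round(density * len(off)))
    keep_idx = rng.choice(len(off), size=keep_n, replace=False)
    mask = np.eye(N, dtype=bool)
    for idx in keep_idx:
        i, j = off[idx]
        mask[i, j] = True
    out.mask = mask
    if isinstance(out, EINetwork):
        Fc, Om, _ = out.combined()
        Om = Om * mask
        # re-impose negative self-resets untouched by masking
        out.set_combined(Fc, Om)
    else:
        out.Omega = out.Omega * mask
    return out


def preferred_directions(F: np.ndarray) -> np.ndarray:
    """Angles (degrees, in (-180, 180]) of each neuron's weight vector in a
    2-D signal space."""
    F = np.atleast_2d(F)
    if F.shape[1] != 2:
        raise ValueError("preferred directions require a 2-D signal space")
    return np.degrees(np.arctan2(F[:, 1], F[:, 0]))


def select_by_preferred_direction(
    net: EINetwork, center: float, width: float, weights: Optional[np.ndarray] = None
) -> np.ndarray:
    """Excitatory neurons whose preferred direction falls within
    ``width``/2 of ``center`` (degrees, circular).  ``weights`` defaults to
    the decoding-vector proxy Fᵀ (for uncorrelated inputs the decoding and
    feedforward vectors coincide)."""
    W = net.F if weights is None else np.asarray(weights)
    ang = preferred_directions(W)
    diff = (ang - center + 180.0) % 360.0 - 180.0
    return np.nonzero(np.abs(diff) <= width / 2.0)[0]


def lesion(net: EINetwork, neuron_ids) -> EINetwork:
    """Remove the listed excitatory neurons from every block they touch."""
    ids = np.unique(np.asarray(neuron_ids, dtype=int))
    if len(ids) == 0:
        return net.copy()
    ne = net.n_exc
    if np.any(ids < 0) or np.any(ids >= ne):
        raise ValueError("lesion ids must be valid excitatory indices")
    if len(ids) >= ne:
        raise ValueError("cannot delete the entire excitatory population")
    keep = np.setdiff1d(np.arange(ne), ids)
    out = net.copy()
    out.F = net.F[keep]
    out.W_EE = net.W_EE[np.ix_(keep, keep)]
    out.W_EI = net.W_EI[keep]
    out.W_IE = net.W_IE[:, keep]
    out.T_E = net.T_E[keep]
    if net.mask is not None:
        keep_all = np.concatenate([keep, ne + np.arange(net.n_inh)])
        out.mask = net.mask[np.ix_(keep_all, keep_all)]
    return out
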