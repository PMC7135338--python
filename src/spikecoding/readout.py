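"""Linear decoding of spike trains and the coding-efficiency objective.

The readout is x̂(t) = D r(t), where r is the spike train filtered with the
same unit-leak exponential as the membrane (dr/dt = -r, +1 per spike).  The
efficiency of a code is the time-averaged squared reconstruction error plus
a firing cost with a linear (per-spike) and a quadratic (rate) term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Decoder",
    "LossReport",
    "filter_spikes",
    "reconstruct",
    "fit_decoder",
    "coding_loss",
    "optimal_feedforward_check",
    "discretization_limit",
]


@dataclass
class Decoder:
    """Linear readout matrix D (M signals × N neurons) with its filter."""

    D: np.ndarray
    filter_tau: float = 1.0
    ridge_lambda: float = 0.0

    def __post_init__(self) -> None:
        self.D = np.atleast_2d(np.asarray(self.D, dtype=np.float64))


@dataclass
class LossReport:
    """Decomposition of the efficiency objective: total = mse + cost."""

    mse: float
    cost: float
    cost_params: tuple[float, float] = (0.0, 0.0)

    @property
    def total(self) -> float:
        return self.mse + self.cost


def filter_spikes(
    spikes: np.ndarray, N: int, n_steps: int, dt: float
) -> np.ndarray:
    """Exponentially filtered spike trains r_k(t).

    r[t+1] = (1-dt)·r[t] with a unit jump at each spike, matching the leak
    of the voltage and of the signals.  ``spikes`` is an event list of
    (step, neuron) pairs.

    Returns r with shape (N, n_steps); the jump of a spike at step t is
    visible from step t+1 onward (the readout reacts after the spike).
    """
    spikes = np.asarray(spikes, dtype=np.int64).reshape(-1, 2)
    if len(spikes):
        if spikes[:, 0].min() < 0 or spikes[:, 0].max() >= n_steps:
            raise ValueError("spike step index out of range")
        if spikes[:, 1].min() < 0 or spikes[:, 1].max() >= N:
            raise ValueError("spike neuron index out of range")
    jumps = np.zeros((N, n_steps))
    for t, k in spikes:
        jumps[k, t] += 1.0
    r = np.zeros((N, n_steps))
    decay = 1.0 - dt
    for t in range(n_steps - 1):
        r[:, t + 1] = decay * r[:, t] + jumps[:, t]
    return r


def reconstruct(dec: Decoder, r: np.ndarray) -> np.ndarray:
    """Signal estimate x̂ = D r."""
    r = np.atleast_2d(np.asarray(r, dtype=np.float64))
    if dec.D.shape[1] != r.shape[0]:
        raise ValueError(
            f"decoder expects {dec.D.shape[1]} neurons, raster has {r.shape[0]}"
        )
    return dec.D @ r


def fit_decoder(r: np.ndarray, x: np.ndarray, ridge_lambda: float = 0.0) -> Decoder:
    """Optimal linear decoder by (ridge) least squares.

    Minimizes Σ_t ‖x(t) − D r(t)‖² + λ‖D‖²_F.  With λ = 0 and degenerate
    normal equations the pseudo-inverse (minimum-norm) solution is returned
    with a warning.
    """
    r = np.atleast_2d(np.asarray(r, dtype=np.float64))
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if r.shape[1] != x.shape[1]:
        raise ValueError("r and x must cover the same time steps")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    N = r.shape[0]
    G = r @ r.T + ridge_lambda * np.eye(N)
    b = x @ r.T
    if ridge_lambda == 0.0 and np.linalg.matrix_rank(G) < N:
        import warnings

        warnings.warn(
            "degenerate normal equations; falling back to pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        D = b @ np.linalg.pinv(G)
    else:
        D = np.linalg.solve(G, b.T).T
    return Decoder(D=D, ridge_lambda=ridge_lambda)


def coding_loss(
    x: np.ndarray,
    x_hat: np.ndarray,
    r: np.ndarray,
    nu: float = 0.0,
    mu: float = 0.0,
) -> LossReport:
    """Efficiency objective: time-mean ‖x − x̂‖² plus the firing cost.

    cost C(r) = time-mean of ν·Σ_k r_k + μ·Σ_k r_k², penalizing the total
    number of spikes and high individual rates respectively.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=np.float64))
    r = np.atleast_2d(np.asarray(r, dtype=np.float64))
    if x.shape != x_hat.shape or x.shape[1] != r.shape[1]:
        raise ValueError("shape mismatch between x, x_hat and r")
    mse = float(np.mean(np.sum((x - x_hat) ** 2, axis=0)))
    cost = float(np.mean(nu * np.sum(r, axis=0) + mu * np.sum(r**2, axis=0)))
    return LossReport(mse=mse, cost=cost, cost_params=(nu, mu))


def optimal_feedforward_check(F: np.ndarray, D: np.ndarray) -> float:
    """Scale-invariant discrepancy between F and Dᵀ.

    Returns the relative Frobenius distance min_s ‖F − s·Dᵀ‖ / ‖F‖ after the
    optimal global rescaling s; 0 iff F ∝ Dᵀ.  For uncorrelated inputs the
    optimal feedforward weights equal the decoding weights, so this score
    measures how close a network is to that optimum.
    """
    F = np.atleast_2d(np.asarray(F, dtype=np.float64))
    Dt = np.atleast_2d(np.asarray(D, dtype=np.float64)).T
    if F.shape != Dt.shape:
        raise ValueError("F and D^T must have the same shape")
    nF = np.linalg.norm(F)
    nD = np.linalg.norm(Dt)
    if nF == 0 and nD == 0:
        return 0.0
    if nF == 0 or nD == 0:
        return 1.0
    s = float(np.sum(F * Dt)) / nD**2
    return float(np.linalg.norm(F - s * Dt) / nF)


def matrix_cosine(A: np.ndarray, B: np.ndarray) -> float:
    """Cosine similarity between two matrices viewed as flat vectors."""
    a = np.asarray(A, dtype=np.float64).ravel()
    b = np.asarray(B, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def discretization_limit(x: np.ndarray, D: np.ndarray, dt: float) -> float:
    """Error floor of a greedy offline encoder with the same decoder.

    At each step the encoder may fire at most one spike: it picks the neuron
    whose decoding column most reduces the instantaneous squared error
    ‖x − D r‖², firing only if the reduction is positive.  The returned mse
    estimates the floor imposed by the finite jump each spike causes in the
    readout; a well-trained network should come within a small factor of it.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    D = np.atleast_2d(np.asarray(D, dtype=np.float64))
    M, n = x.shape
    N = D.shape[1]
    col_sq = np.sum(D**2, axis=0)  # ‖D_k‖²
    r = np.zeros(N)
    err_acc = 0.0
    decay = 1.0 - dt
    x_hat = np.zeros(M)
    for t in range(n):
        e = x[:, t] - x_hat
        # firing neuron k changes error by -2 D_k·e + ‖D_k‖²
        gain = 2.0 * (D.T @ e) - col_sq
        k = int(np.argmax(gain))
        if gain[k] > 0:
            r[k] += 1.0
        err_acc += float(e @ e)
        r *= decay
        x_hat = D @ r
    return err_acc / n
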