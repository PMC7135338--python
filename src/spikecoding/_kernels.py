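"""Numba-jitted simulation/learning inner loop.

One kernel integrates the leaky integrate-and-fire dynamics

    dV/dt = -V + F c(t) + Ω o(t)   (+ noise, + delayed synaptic currents)

with at most one spike per time step network-wide (largest threshold excess
fires first and its recurrent column is applied within the step), and
optionally applies the local plasticity rules at each spike:

    recurrent (presynaptic-spike gated):
        ΔΩ_ik = -η_r (β (V_i + μ r_i) + Ω_ik + μ δ_ik)
    feedforward (postsynaptic-spike gated):
        ΔF_ij = η_f (x_j - α F_ij)

The Dale-partitioned EI network is run through the same kernel on combined
block matrices: neurons [0, n_e) are excitatory, [n_e, N) inhibitory; the
inhibitory population's "feedforward" input is the excitatory spike train
(its weights live in the Ω block and are trained with the feedforward rule
driven by the filtered excitatory trains r_E in place of x).

Discrete-time conventions (step t -> t+1):
    1. V <- (1-dt) V + dt (F c_t + noise) + delayed currents
    2. r <- (1-dt) r
    3. spike decision on this pre-spike V; plasticity uses pre-spike V and
       pre-jump r
    4. V <- V + Ω[:,k] (self-reset instantaneous even with a delay kernel);
       r_k <- r_k + 1
With Ω = -F D this makes V_t = F (x_t - D r_t) an exact invariant of the
discrete dynamics (the voltage-error identity), not merely an O(dt) one.
"""

import numpy as np
from numba import njit

__all__ = ["run_network"]


@njit(cache=True)
def run_network(
    cT,  # (n_steps, M) input currents, time-major
    xT,  # (n_steps, M) leaky-integrated signals, time-major
    dt,
    F,  # (N, M) feedforward weights; zero rows for inhibitory neurons
    Omega,  # (N, N) transmitted recurrent weights, diagonal = self-resets
    OmL,  # (N, N) latent (unrectified) weights the plasticity acts on;
    #       transmitted = sign-rectified latent under Dale's law, so that
    #       clipping does not ratchet near-zero weights upward
    T,  # (N,) thresholds
    mask,  # (N, N) boolean, allowed connections (diagonal always True)
    n_e,  # excitatory split; == N for a single population
    noise_sigma,
    kernel,  # (L,) delay current profile; L == 0 -> instantaneous synapses
    V,  # (N,) state, in/out
    r,  # (N,) filtered trains, in/out
    buf,  # (N, max(L,1)) delay ring buffer, in/out
    buf_pos,
    seed,
    learn_rec,  # recurrent rule on EE/EI/II columns (full Ω for single pop)
    learn_f,  # feedforward rule on input rows F
    learn_ie,  # feedforward-form rule on E→I rows (part of the recurrent loop)
    dale,
    ff_cov,
    eta_rec,
    eta_ff,
    eta_ie,
    beta,
    mu,
    alpha,
    alpha_ie,
    covC,  # (N, M) running covariance state for the correlated-input rule
    mean_x,  # (M,)
    mean_g,  # (N,)
    cov_tau,
    use_floor,
    guard_abs,
    Vtrace,  # (N, n_steps) if record_v else (1, 1)
    record_v,
    exc_in,  # (N, n_steps) if record_i else (1, 1)
    inh_in,
    record_i,
):
    N = F.shape[0]
    M = F.shape[1]
    n = cT.shape[0]
    L = kernel.shape[0]
    np.random.seed(seed)
    decay = 1.0 - dt
    sqrt_dt = np.sqrt(dt)

    spk_step = np.empty(n, np.int64)
    spk_id = np.empty(n, np.int64)
    v_pre = np.empty(n, np.float64)
    ns = 0
    n_multi = 0
    diverged = -1

    if record_v:
        for i in range(N):
            Vtrace[i, 0] = V[i]

    for t in range(n - 1):
        # --- integrate membrane, leak filtered trains ---
        for i in range(N):
            drive = 0.0
            for j in range(M):
                drive += F[i, j] * cT[t, j]
            V[i] = decay * V[i] + dt * drive
            if record_i:
                if drive > 0.0:
                    exc_in[i, t + 1] += dt * drive
                else:
                    inh_in[i, t + 1] += dt * drive
        if noise_sigma > 0.0:
            for i in range(N):
                V[i] += noise_sigma * T[i] * sqrt_dt * np.random.normal()
        if L > 0:
            for i in range(N):
                inc = buf[i, buf_pos]
                V[i] += inc
                buf[i, buf_pos] = 0.0
                if record_i:
                    if inc > 0.0:
                        exc_in[i, t + 1] += inc
                    else:
                        inh_in[i, t + 1] += inc
        for k in range(N):
            r[k] *= decay

        # --- running covariance of (x_j, total input drive g_i) ---
        if ff_cov:
            a = dt / cov_tau
            for j in range(M):
                mean_x[j] += a * (xT[t + 1, j] - mean_x[j])
            for i in range(n_e):
                g = 0.0
                for j in range(M):
                    g += F[i, j] * xT[t + 1, j]
                mean_g[i] += a * (g - mean_g[i])
                for j in range(M):
                    covC[i, j] += a * (
                        (g - mean_g[i]) * (xT[t + 1, j] - mean_x[j]) - covC[i, j]
                    )

        # --- spike decision: largest threshold excess fires ---
        best = -1
        best_ex = 0.0
        crossing = 0
        for i in range(N):
            ex = V[i] - T[i]
            if ex >= 0.0:
                crossing += 1
                if best < 0 or ex > best_ex:
                    best = i
                    best_ex = ex
        if crossing > 1:
            n_multi += 1

        if best >= 0:
            k = best
            spk_step[ns] = t
            spk_id[ns] = k
            v_pre[ns] = V[k]
            ns += 1

            # --- plasticity at the spike, using pre-spike V and pre-jump r ---
            if learn_rec:
                # recurrent rule on column k: all E rows for an E spike
                # (EE block / full column for a single population), full
                # column for an I spike (EI and II blocks).
                rows_hi = n_e if k < n_e else N
                for i in range(rows_hi):
                    if mask[i, k]:
                        delta = 1.0 if i == k else 0.0
                        w = OmL[i, k] - eta_rec * (
                            beta * (V[i] + mu * r[i]) + OmL[i, k] + mu * delta
                        )
                        OmL[i, k] = w
                        if dale:
                            if i == k:
                                if w > 0.0:
                                    w = 0.0
                            elif k < n_e:  # excitatory presynapse
                                if w < 0.0:
                                    w = 0.0
                            else:  # inhibitory presynapse
                                if w > 0.0:
                                    w = 0.0
                        Omega[i, k] = w
            if learn_f and k < n_e:
                for j in range(M):
                    if ff_cov:
                        decay_term = covC[k, j]
                    else:
                        decay_term = F[k, j]
                    F[k, j] += eta_ff * (xT[t + 1, j] - alpha * decay_term)
            if learn_ie and k >= n_e:
                # inhibitory neuron: its "feedforward" input is the
                # excitatory spike train; same rule with r_E for x.
                for j in range(n_e):
                    if mask[k, j]:
                        w = OmL[k, j] + eta_ie * (r[j] - alpha_ie * OmL[k, j])
                        OmL[k, j] = w
                        if dale and w < 0.0:
                            w = 0.0
                        Omega[k, j] = w

            # --- apply the recurrent column (self-reset instantaneous) ---
            if L == 0:
                for i in range(N):
                    if mask[i, k]:
                        V[i] += Omega[i, k]
                        if record_i:
                            if Omega[i, k] > 0.0:
                                exc_in[i, t + 1] += Omega[i, k]
                            else:
                                inh_in[i, t + 1] += Omega[i, k]
            else:
                V[k] += Omega[k, k]
                for l in range(L):
                    q = (buf_pos + l) % L
                    for i in range(N):
                        if i != k and mask[i, k]:
                            buf[i, q] += Omega[i, k] * kernel[l]
            r[k] += 1.0

        if use_floor:
            for i in range(N):
                if V[i] < -T[i]:
                    V[i] = -T[i]

        if L > 0:
            buf_pos = (buf_pos + 1) % L

        if record_v:
            for i in range(N):
                Vtrace[i, t + 1] = V[i]

        for i in range(N):
            if np.abs(V[i]) > guard_abs:
                diverged = t
                break
        if diverged >= 0:
            break

    return spk_step[:ns].copy(), spk_id[:ns].copy(), v_pre[:ns].copy(), n_multi, diverged, buf_pos
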