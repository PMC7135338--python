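import numpy as np
import pytest

from spikecoding import (
    EINetwork,
    Network,
    filter_spikes,
    lesion,
    make_delay_kernel,
    make_smooth_noise,
    select_by_preferred_direction,
    simulate,
    sparsify,
)
from spikecoding.network import DivergenceError
from spikecoding.signals import SignalBundle


def _const_signal(value, duration, dt, M=1):
    n = int(duration / dt)
    c = np.full((M, n), float(value))
    from spikecoding.signals import leaky_integrate

    x = leaky_integrate(c, dt, x0=np.zeros(M))
    return SignalBundle(c=c, x=x, dt=dt)


def _make_ei(seed=0, ne=6, ni=3, M=2):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((ne, M))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    return EINetwork(
        F=F,
        W_IE=rng.uniform(0, 0.3, (ni, ne)),
        W_EI=-rng.uniform(0, 0.3, (ne, ni)),
        W_II=np.eye(ni) * -0.5 - rng.uniform(0, 0.1, (ni, ni)) * (1 - np.eye(ni)),
        W_EE=np.eye(ne) * -0.5,
        T_E=np.full(ne, 0.5),
        T_I=np.full(ni, 0.5),
        dt=1e-3,
    )


class TestSimulate:
    def test_first_spike_time_single_neuron(self):
        """One neuron, F=1, T=0.5, constant current c=1: V(t)=1-e^{-t}
        crosses threshold at t* = ln 2."""
        dt = 1e-3
        net = Network(F=[[1.0]], Omega=[[-1.0]], T=[0.5], dt=dt)
        sig = _const_signal(1.0, 2.0, dt)
        res = simulate(net, sig, seed=0)
        t_star = res.spikes[0, 0] * dt
        assert abs(t_star - np.log(2.0)) <= 2 * dt

    def test_rest_stays_at_rest(self):
        dt = 1e-3
        net = Network(F=[[1.0]], Omega=[[-1.0]], T=[0.5], dt=dt)
        sig = _const_signal(0.0, 1.0, dt)
        res = simulate(net, sig, seed=0, record_voltage=True)
        assert len(res.spikes) == 0
        assert not res.V.any()

    def test_mutual_inhibition_never_two_spikes_per_step(self):
        """Two identical neurons with mutual inhibition and shared drive:
        spikes must serialize, never two in one step, and the firing
        alternation follows the largest-excess rule (verified against an
        explicit step-through)."""
        dt = 1e-3
        net = Network(
            F=[[1.0], [1.0]],
            Omega=[[-1.0, -1.0], [-1.0, -1.0]],
            T=[0.5, 0.5],
            dt=dt,
        )
        sig = _const_signal(1.5, 3.0, dt)
        res = simulate(net, sig, seed=0)
        steps = res.spikes[:, 0]
        assert len(steps) == len(np.unique(steps))
        # explicit forward step-through with the same semantics
        V = np.zeros(2)
        expected = []
        for t in range(sig.n_steps - 1):
            V = (1 - dt) * V + dt * 1.5
            k = int(np.argmax(V - 0.5))
            if V[k] >= 0.5:
                expected.append((t, k))
                V += net.Omega[:, k]
        assert np.array_equal(res.spikes, np.array(expected))

    def test_pre_spike_voltage_at_or_above_threshold(self, small_balanced_net, noise_signal):
        res = simulate(small_balanced_net, noise_signal, seed=3)
        T = small_balanced_net.T[res.spikes[:, 1]]
        assert np.all(res.v_pre >= T)

    def test_filtered_train_recurrence(self, small_balanced_net, noise_signal):
        """r must satisfy the same unit-leak recurrence as the readout filter."""
        res = simulate(small_balanced_net, noise_signal, seed=3)
        r_ref = filter_spikes(res.spikes, res.n_neurons, res.n_steps, res.dt)
        assert np.allclose(res.r, r_ref)

    def test_determinism(self, small_balanced_net, noise_signal):
        a = simulate(small_balanced_net, noise_signal, seed=11, record_voltage=True)
        b = simulate(small_balanced_net, noise_signal, seed=11, record_voltage=True)
        assert np.array_equal(a.spikes, b.spikes)
        assert np.array_equal(a.V, b.V)

    def test_noise_changes_with_seed(self, small_balanced_net, noise_signal):
        noisy = small_balanced_net.copy()
        noisy.noise_sigma = 0.2
        a = simulate(noisy, noise_signal, seed=1)
        b = simulate(noisy, noise_signal, seed=2)
        assert not np.array_equal(a.spikes, b.spikes)

    def test_divergence_guard_trips(self):
        dt = 1e-3
        # positive self-feedback: each spike depolarizes the neuron further
        net = Network(F=[[1.0]], Omega=[[-0.1]], T=[0.5], dt=dt, guard=2.0)
        huge = _const_signal(500.0, 1.0, dt)
        with pytest.raises(DivergenceError):
            simulate(net, huge, seed=0)

    def test_dt_mismatch_rejected(self, small_balanced_net):
        sig = make_smooth_noise(2, 1.0, 5e-4, seed=0)
        with pytest.raises(ValueError, match="dt"):
            simulate(small_balanced_net, sig, seed=0)


class TestVoltageErrorIdentity:
    def test_voltage_equals_projected_coding_error(self, small_balanced_net, noise_signal):
        """With Ω = -F D the membrane voltage must equal F(x - x̂) at every
        step, where x̂ = D r is integrated independently from the spike
        list."""
        net = small_balanced_net
        D = net.F.T
        res = simulate(net, noise_signal, seed=5, record_voltage=True)
        r = filter_spikes(res.spikes, net.n_neurons, noise_signal.n_steps, net.dt)
        V_pred = net.F @ (noise_signal.x - D @ r)
        assert np.max(np.abs(res.V - V_pred)) <= 10 * net.dt

    def test_identity_with_rate_cost(self, noise_signal):
        """With Ω = -F D - μI and μ > 0 the identity generalizes to
        V = F(x - x̂) - μ r."""
        rng = np.random.default_rng(8)
        N, M, mu = 15, 2, 0.1
        F = rng.standard_normal((N, M))
        F /= np.linalg.norm(F, axis=1, keepdims=True)
        D = F.T
        net = Network(F=F, Omega=-F @ D - mu * np.eye(N), T=0.5 * np.sum(F**2, 1) + mu, dt=1e-3)
        res = simulate(net, noise_signal, seed=5, record_voltage=True)
        r = filter_spikes(res.spikes, N, noise_signal.n_steps, net.dt)
        V_pred = F @ (noise_signal.x - D @ r) - mu * r
        assert np.max(np.abs(res.V - V_pred)) <= 10 * net.dt


class TestDelayKernel:
    def test_zero_delay_is_instantaneous(self, small_balanced_net, noise_signal):
        k = make_delay_kernel(0.0, 1e-3)
        assert k.size == 0
        delayed = small_balanced_net.copy()
        delayed.delay_kernel = k
        a = simulate(small_balanced_net, noise_signal, seed=1)
        b = simulate(delayed, noise_signal, seed=1)
        assert np.array_equal(a.spikes, b.spikes)

    @pytest.mark.parametrize("d", [0.05, 0.1, 0.5])
    def test_unit_charge_and_peak_position(self, d):
        dt = 1e-3
        k = make_delay_kernel(d, dt)
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        # PSP = leaky integral of the current profile peaks at d
        v, peak_t, peak_v = 0.0, 0.0, -np.inf
        for i, ki in enumerate(k):
            v = (1 - dt) * v + ki
            if v > peak_v:
                peak_v, peak_t = v, i * dt
        assert abs(peak_t - d) <= 2 * dt

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            make_delay_kernel(-0.1, 1e-3)


class TestSparsify:
    def test_density_one_is_identity(self, small_balanced_net):
        out = sparsify(small_balanced_net, 1.0, seed=0)
        assert out.mask.all()
        assert np.array_equal(out.Omega, small_balanced_net.Omega)

    def test_exact_offdiagonal_count(self, small_balanced_net):
        N = small_balanced_net.n_neurons
        out = sparsify(small_balanced_net, 0.5, seed=1)
        off = out.mask.sum() - N  # diagonal always retained
        assert off == round(0.5 * N * (N - 1))
        assert np.all(out.Omega[~out.mask] == 0)

    def test_deterministic_mask(self, small_balanced_net):
        a = sparsify(small_balanced_net, 0.3, seed=4)
        b = sparsify(small_balanced_net, 0.3, seed=4)
        assert np.array_equal(a.mask, b.mask)

    def test_invalid_density(self, small_balanced_net):
        with pytest.raises(ValueError):
            sparsify(small_balanced_net, 0.0)


class TestEINetwork:
    def test_dale_sign_validation(self):
        net = _make_ei()
        with pytest.raises(ValueError, match=">= 0"):
            EINetwork(
                F=net.F, W_IE=net.W_IE - 1.0, W_EI=net.W_EI, W_II=net.W_II,
                W_EE=net.W_EE, T_E=net.T_E, T_I=net.T_I,
            )

    def test_combined_roundtrip(self):
        net = _make_ei()
        Fc, Om, Tc = net.combined()
        other = net.copy()
        other.set_combined(Fc, Om)
        for f in ("F", "W_IE", "W_EI", "W_II", "W_EE"):
            assert np.array_equal(getattr(net, f), getattr(other, f))

    def test_simulation_runs_and_splits(self):
        net = _make_ei()
        sig = make_smooth_noise(2, 10.0, 1e-3, seed=0)
        res = simulate(net, sig, seed=0)
        res_e, res_i = res.split_ei()
        assert res_e.n_neurons == net.n_exc
        assert res_i.n_neurons == net.n_inh
        assert len(res_e.spikes) + len(res_i.spikes) == len(res.spikes)


class TestLesion:
    def test_empty_lesion_is_identity(self):
        net = _make_ei()
        out = lesion(net, [])
        assert np.array_equal(out.F, net.F)
        assert np.array_equal(out.W_EI, net.W_EI)

    def test_shapes_consistent_after_lesion(self):
        net = _make_ei(ne=8, ni=3)
        out = lesion(net, [1, 5])
        assert out.n_exc == 6
        assert out.W_EE.shape == (6, 6)
        assert out.W_IE.shape == (3, 6)
        assert out.W_EI.shape == (6, 3)
        assert out.T_E.shape == (6,)

    def test_cannot_delete_everyone(self):
        net = _make_ei(ne=4)
        with pytest.raises(ValueError):
            lesion(net, [0, 1, 2, 3])

    def test_select_by_preferred_direction_matches_bruteforce(self):
        net = _make_ei(ne=40)
        ids = select_by_preferred_direction(net, 180.0, 90.0)
        ang = np.degrees(np.arctan2(net.F[:, 1], net.F[:, 0]))
        expected = [
            i for i in range(40)
            if abs((ang[i] - 180.0 + 180.0) % 360.0 - 180.0) <= 45.0
        ]
        assert list(ids) == expected


def test_network_validation():
    with pytest.raises(ValueError, match="negative"):
        Network(F=[[1.0]], Omega=[[0.1]], T=[0.5])
    with pytest.raises(ValueError, match="masked"):
        Network(
            F=[[1.0], [1.0]],
            Omega=[[-1.0, 0.5], [0.0, -1.0]],
            T=[0.5, 0.5],
            mask=np.eye(2, dtype=bool),
        )
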