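import numpy as np
import pytest

from spikecoding import (
    LearnConfig,
    RunningCovariance,
    feedforward_update,
    feedforward_update_cov,
    recurrent_update,
    train,
    train_ei,
)
from spikecoding.experiments import make_ei_network, make_network, smooth_noise_source


class TestRecurrentRule:
    def test_fixed_point_is_exactly_zero_update(self):
        """V_i = -(Ω_ik + μ δ_ik)/β - μ r_i zeroes the update to float
        precision."""
        cfg = LearnConfig(beta=1.7, mu=0.3, eta_rec=0.05, eta_ff=0.01)
        rng = np.random.default_rng(0)
        N, k = 6, 2
        Omega = -rng.random((N, N)) - np.eye(N)
        r = rng.random(N)
        delta = np.zeros(N)
        delta[k] = 1.0
        V = -(Omega[:, k] + cfg.mu * delta) / cfg.beta - cfg.mu * r
        out = recurrent_update(Omega, V, r, k, cfg)
        assert np.array_equal(out, Omega)

    def test_direct_substitution(self):
        """β=1, μ=0, V_i=0.2, Ω_ik=-0.4, η=0.01 → ΔΩ_ik = +0.002."""
        cfg = LearnConfig(beta=1.0, mu=0.0, eta_rec=0.01, eta_ff=0.001)
        Omega = np.array([[-0.4]])
        out = recurrent_update(Omega, np.array([0.2]), np.array([0.0]), 0, cfg)
        assert out[0, 0] - Omega[0, 0] == pytest.approx(0.002, abs=1e-15)

    def test_bare_rule_reduction(self):
        """β=2, μ=0 reduces the update to -η(2V_i + Ω_ik)."""
        cfg = LearnConfig(beta=2.0, mu=0.0, eta_rec=0.01, eta_ff=0.001)
        rng = np.random.default_rng(1)
        Omega = -np.eye(4) - rng.random((4, 4))
        V, r = rng.random(4), rng.random(4)
        out = recurrent_update(Omega, V, r, 1, cfg)
        expected = Omega[:, 1] - 0.01 * (2 * V + Omega[:, 1])
        assert np.allclose(out[:, 1], expected)

    def test_only_target_column_touched_and_mask_respected(self):
        cfg = LearnConfig()
        rng = np.random.default_rng(2)
        Omega = -np.eye(5) - rng.random((5, 5))
        mask = np.ones((5, 5), dtype=bool)
        mask[3, 2] = False
        out = recurrent_update(Omega, rng.random(5), rng.random(5), 2, cfg, mask=mask)
        untouched = np.delete(np.arange(5), 2)
        assert np.array_equal(out[:, untouched], Omega[:, untouched])
        assert out[3, 2] == Omega[3, 2]

    def test_bad_index_rejected(self):
        with pytest.raises(ValueError):
            recurrent_update(-np.eye(3), np.zeros(3), np.zeros(3), 5, LearnConfig())


class TestFeedforwardRule:
    def test_fixed_point_exact(self):
        cfg = LearnConfig(alpha=2.0)
        F = np.array([[0.3, -0.1], [0.5, 0.2]])
        x = cfg.alpha * F[1]
        out = feedforward_update(F, x, 1, cfg)
        assert np.array_equal(out, F)

    def test_geometric_convergence_to_x_over_alpha(self):
        """Repeated spiking at constant x drives F_i → x/α geometrically
        with ratio (1 - η α)."""
        cfg = LearnConfig(alpha=2.0, eta_ff=0.05, eta_rec=0.1)
        F = np.zeros((1, 2))
        x = np.array([1.0, -0.6])
        target = x / cfg.alpha
        gaps = []
        for _ in range(200):
            F = feedforward_update(F, x, 0, cfg)
            gaps.append(np.linalg.norm(F[0] - target))
        assert gaps[-1] < 1e-8
        ratios = np.array(gaps[1:50]) / np.array(gaps[:49])
        assert np.allclose(ratios, 1 - cfg.eta_ff * cfg.alpha, atol=1e-10)

    def test_non_firing_rows_untouched(self):
        cfg = LearnConfig()
        rng = np.random.default_rng(3)
        F = rng.random((4, 3))
        out = feedforward_update(F, rng.random(3), 2, cfg)
        assert np.array_equal(out[[0, 1, 3]], F[[0, 1, 3]])


class TestCovarianceRule:
    def test_running_covariance_converges_to_batch(self):
        """The EMA covariance over a long stationary signal must land
        within 5% of the batch estimate."""
        rng = np.random.default_rng(4)
        dt = 1e-3
        n = 200_000
        L = np.array([[1.0, 0.0], [0.6, 0.8]])
        x = L @ rng.standard_normal((2, n))
        F = np.array([[0.7, -0.3]])
        g = F @ x
        cov = RunningCovariance(1, 2, tau=20.0, dt=dt)
        for t in range(n):
            cov.update(g[:, t], x[:, t])
        batch = (F @ (L @ L.T)).ravel()
        assert np.allclose(cov.cov[0], batch, rtol=0.05)

    def test_reduces_to_plain_rule_for_uncorrelated_inputs(self):
        """For unit-variance uncorrelated x, Cov(x_j, F_i·x) = F_ij, so the
        covariance rule's fixed point coincides with the plain rule's."""
        cfg = LearnConfig(alpha=1.5)
        F = np.array([[0.4, -0.2]])
        cov = RunningCovariance(1, 2, tau=1.0, dt=1e-3)
        cov.cov = F.copy()  # analytic covariance for unit-variance inputs
        x = cfg.alpha * F[0]
        out = feedforward_update_cov(F, x, 0, cfg, cov)
        assert np.allclose(out, F)

    def test_zero_variance_channel_contributes_nothing(self):
        """A centered zero-variance channel has x_j = 0 and zero covariance:
        its weight never moves and its drive contribution stays 0."""
        cfg = LearnConfig(alpha=1.5)
        F = np.array([[0.4, 0.7]])
        cov = RunningCovariance(1, 2, tau=1.0, dt=1e-3)
        x = np.array([0.8, 0.0])  # channel 1 silent
        for _ in range(50):
            cov.update(F @ x, x)
            F = feedforward_update_cov(F, x, 0, cfg, cov)
        assert cov.cov[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert F[0, 1] == pytest.approx(0.7)  # untouched: no signal, no decay


class TestLearnConfig:
    def test_timescale_separation_enforced(self):
        with pytest.raises(ValueError):
            LearnConfig(eta_rec=0.001, eta_ff=0.01)
        with pytest.raises(ValueError):
            LearnConfig(eta_rec=0.01, eta_ff=0.01)

    def test_frozen_config_allowed(self):
        cfg = LearnConfig(eta_rec=0.0, eta_ff=0.0)
        assert cfg.rates_at(0.0) == (0.0, 0.0, 0.0)

    def test_schedule_decays_rates(self):
        cfg = LearnConfig(schedule={"t_decay": 100.0})
        r0, f0, i0 = cfg.rates_at(0.0)
        r1, f1, _ = cfg.rates_at(100.0)
        assert r1 == pytest.approx(r0 / 2) and f1 == pytest.approx(f0 / 2)


class TestTraining:
    def test_frozen_learning_is_identity(self):
        net = make_network(N=8, M=2, seed=0)
        src = smooth_noise_source()
        cfg = LearnConfig(eta_rec=0.0, eta_ff=0.0)
        traj = train(net, src, 20.0, cfg, checkpoint_every=20.0, eval_duration=5.0)
        assert np.array_equal(traj.final_network.Omega, net.Omega)
        assert np.array_equal(traj.final_network.F, net.F)

    def test_frozen_ei_learning_is_identity(self):
        net = make_ei_network(n_exc=10, n_inh=4, M=2, seed=0)
        src = smooth_noise_source()
        cfg = LearnConfig(eta_rec=0.0, eta_ff=0.0)
        traj = train_ei(net, src, 20.0, cfg, checkpoint_every=20.0, eval_duration=5.0)
        for f in ("F", "W_IE", "W_EI", "W_II", "W_EE"):
            assert np.array_equal(getattr(traj.final_network, f), getattr(net, f))

    def test_training_is_deterministic(self):
        src = smooth_noise_source()
        runs = []
        for _ in range(2):
            net = make_network(N=10, M=2, seed=3)
            traj = train(net, src, 50.0, LearnConfig(seed=7), checkpoint_every=50.0,
                         eval_duration=10.0)
            runs.append(traj.final_network.Omega.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_trajectory_times_strictly_increasing(self):
        net = make_network(N=10, M=2, seed=1)
        src = smooth_noise_source()
        traj = train(net, src, 60.0, LearnConfig(seed=1), checkpoint_every=20.0,
                     eval_duration=10.0)
        assert np.all(np.diff(traj.times) > 0)
        assert len(traj.errors["all"]) == len(traj.times)

    def test_mask_is_respected_during_training(self):
        """Masked-out synapses stay exactly zero through learning."""
        from spikecoding import sparsify

        net = make_network(N=12, M=2, seed=2)
        net = sparsify(net, 0.5, seed=5)
        src = smooth_noise_source()
        traj = train(net, src, 100.0, LearnConfig(seed=2), checkpoint_every=100.0,
                     eval_duration=10.0)
        out = traj.final_network
        assert np.all(out.Omega[~net.mask] == 0)

    def test_dale_signs_preserved_through_training(self):
        net = make_ei_network(n_exc=16, n_inh=8, M=2, seed=4)
        src = smooth_noise_source()
        traj = train_ei(net, src, 150.0, LearnConfig(seed=4), checkpoint_every=150.0,
                        eval_duration=10.0)
        fin = traj.final_network
        ne = fin.n_exc
        assert np.all(fin.W_IE >= 0)
        assert np.all(fin.W_EI <= 0)
        assert np.all(fin.W_EE[~np.eye(ne, dtype=bool)] >= 0)
        assert np.all(np.diag(fin.W_EE) <= 0)
        assert np.all(fin.W_II[~np.eye(fin.n_inh, dtype=bool)] <= 0)

    def test_wrong_network_type_rejected(self):
        src = smooth_noise_source()
        with pytest.raises(TypeError):
            train(make_ei_network(n_exc=4, n_inh=2, seed=0), src, 1.0, LearnConfig())
        with pytest.raises(TypeError):
            train_ei(make_network(N=4, seed=0), src, 1.0, LearnConfig())
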