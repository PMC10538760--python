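"""Gaussian heads, stochastic recurrence, prior, and the chain-density
oracle."""

import numpy as np
import pytest
from scipy import stats

from wakesleep import autodiff as ad
from wakesleep.model_core import (GaussianHead, HierarchyConfig,
                                  NetworkState, StochasticRecurrentNet,
                                  chain_log_density, gaussian_head_forward,
                                  load_net, sample_prior, save_net,
                                  stochastic_forward)


def _zero_head(in_dim, hidden, out_dim):
    head = GaussianHead(in_dim, hidden, out_dim)
    for p in head.parameters():
        p.data[...] = 0.0
    return head


class TestGaussianHead:
    def test_zero_parameters_give_standard_normal_parameters(self, rng):
        head = _zero_head(3, 8, 2)
        mean, std = gaussian_head_forward(head, rng.standard_normal((5, 3)))
        np.testing.assert_array_equal(mean, np.zeros((5, 2)))
        np.testing.assert_array_equal(std, np.ones((5, 2)))

    def test_matches_hand_rolled_dense_arithmetic(self, rng):
        head = GaussianHead(3, 4, 2, rng=7)
        x = rng.standard_normal((6, 3))
        h_pre = x @ head.W1.data + head.b1.data
        h = np.where(h_pre > 0, h_pre, np.exp(np.minimum(h_pre, 0)) - 1)
        out = h @ head.W2.data + head.b2.data
        raw_ls = out[:, 2:]
        expected_std = np.exp(4.0 * np.tanh(raw_ls / 4.0))
        mean, std = gaussian_head_forward(head, x)
        np.testing.assert_allclose(mean, out[:, :2], rtol=1e-12)
        np.testing.assert_allclose(std, expected_std, rtol=1e-12)

    def test_std_strictly_positive_and_finite(self, rng):
        head = GaussianHead(4, 8, 3, rng=0)
        _, std = gaussian_head_forward(head, 100 * rng.standard_normal((10, 4)))
        assert np.all(std > 0) and np.all(np.isfinite(std))

    def test_dimension_mismatch_raises(self):
        head = GaussianHead(3, 4, 2)
        with pytest.raises(ValueError, match="units"):
            head.forward(ad.tensor(np.zeros((2, 5))))


class TestStochasticForward:
    def test_noise_free_identity_recurrence_returns_head_sample(self):
        """With noise silenced and the recurrence acting as the identity
        on positive samples, (s + r)/2 = s."""
        net = StochasticRecurrentNet(2, 4, 2, rng=0)
        # head: mean = const positive vector, std irrelevant (no noise)
        for p in net.head.parameters():
            p.data[...] = 0.0
        net.head.b2.data[:2] = [2.0, 1.5]
        # recurrence: identity map on the mean half (ELU(x)=x for x>0)
        for p in net.recurrence.parameters():
            p.data[...] = 0.0
        net.recurrence.W1.data[:, :2] = np.eye(2)
        net.recurrence.W2.data[:2, :2] = np.eye(2)
        out = stochastic_forward(net, np.zeros((3, 2)), seed=0, noise_scale=0.0)
        np.testing.assert_allclose(out, np.tile([2.0, 1.5], (3, 1)), rtol=1e-12)

    def test_zero_recurrence_weights_match_manual_reparameterization(self):
        """With an all-zero recurrence net the output is
        (s + eps')/2 with both draws reproducible from the seed."""
        net = StochasticRecurrentNet(2, 4, 2, rng=3)
        for p in net.recurrence.parameters():
            p.data[...] = 0.0
        x = np.array([[0.3, -0.7]])
        out = stochastic_forward(net, x, seed=11)
        mean, std = gaussian_head_forward(net.head, x)
        r = np.random.default_rng(11)
        eps = r.standard_normal((1, 2))
        eps_rec = r.standard_normal((1, 2))
        s = mean + std * eps
        np.testing.assert_allclose(out, (s + eps_rec) / 2.0, rtol=1e-12)

    def test_same_seed_is_bit_identical(self, rng):
        net = StochasticRecurrentNet(3, 8, 2, rng=1)
        x = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(stochastic_forward(net, x, seed=5),
                                      stochastic_forward(net, x, seed=5))

    def test_recurrence_disabled_sampling_converges_to_head_moments(self):
        net = StochasticRecurrentNet(2, 8, 2, recurrence_steps=0, rng=2)
        n = 40000
        x = np.zeros((n, 2))
        mean, std = gaussian_head_forward(net.head, x[:1])
        samples = stochastic_forward(net, x, seed=9)
        tol = 4.0 / np.sqrt(n)
        assert np.all(np.abs(samples.mean(0) - mean[0]) < tol * std[0])
        assert np.all(np.abs(samples.std(0) - std[0]) < 4 * tol * std[0])


class TestSamplePrior:
    def test_moments_and_determinism(self):
        z = sample_prior(10000, 2, seed=0)
        assert np.all(np.abs(z.mean(0)) < 4 / np.sqrt(10000))
        assert np.all(np.abs(z.var(0) - 1.0) < 0.06)
        np.testing.assert_array_equal(z, sample_prior(10000, 2, seed=0))

    def test_invalid_count_raises(self):
        with pytest.raises(ValueError):
            sample_prior(0, 2, seed=0)


class TestNetworkState:
    def test_batch_length_and_phase_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            NetworkState(np.zeros((3, 2)), np.zeros((2, 2)), "wake")
        with pytest.raises(ValueError, match="phase"):
            NetworkState(np.zeros((2, 2)), np.zeros((2, 2)), "dusk")
        st = NetworkState(np.zeros((2, 3)), np.ones((2, 2)), "sleep")
        assert st.joint.shape == (2, 5)


class TestChainLogDensity:
    def test_independent_standard_normals_at_origin(self):
        d = 4
        cfg = HierarchyConfig(dims=[d], root_mean=np.zeros(d),
                              root_std=np.ones(d))
        assert chain_log_density(cfg, [np.zeros(d)]) == pytest.approx(
            -(d / 2) * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_factorized_density_equals_full_covariance_normal(self, seed):
        """Sum of conditional log densities == joint MVN log density for
        random linear-Gaussian chains (<=5 layers, <=4 units/layer)."""
        rng = np.random.default_rng(seed)
        n_layers = int(rng.integers(1, 6))
        dims = [int(rng.integers(1, 5)) for _ in range(n_layers)]
        cfg = HierarchyConfig.random(dims, rng)
        mean, cov = cfg.joint_moments()
        mvn = stats.multivariate_normal(mean=mean, cov=cov)
        states = cfg.sample(20, rng)
        for k in range(20):
            state = [s[k] for s in states]
            expected = mvn.logpdf(np.concatenate(state))
            assert chain_log_density(cfg, state) == pytest.approx(
                expected, abs=1e-10)

    def test_doubling_one_conditional_std_shifts_by_log_two(self):
        rng = np.random.default_rng(0)
        cfg = HierarchyConfig.random([2, 3], rng)
        # evaluate at that layer's conditional mean so only the
        # normalizer changes
        root = rng.standard_normal(2)
        mean1 = np.asarray(cfg.weights[0]) @ root + cfg.biases[0]
        base = chain_log_density(cfg, [root, mean1])
        cfg.stds[0] = np.asarray(cfg.stds[0]) * 2.0
        doubled = chain_log_density(cfg, [root, mean1])
        assert doubled - base == pytest.approx(-3 * np.log(2), abs=1e-12)

    def test_non_chain_structure_rejected(self):
        with pytest.raises(ValueError, match="chain"):
            HierarchyConfig(dims=[2, 3], root_mean=np.zeros(2),
                            root_std=np.ones(2),
                            weights=[np.zeros((3, 3))], biases=[np.zeros(3)],
                            stds=[np.ones(3)])


def test_serialization_roundtrip(tmp_path, rng):
    net = StochasticRecurrentNet(3, 8, 2, direction="theta", rng=4)
    save_net(net, str(tmp_path / "net"))
    loaded = load_net(str(tmp_path / "net"))
    assert loaded.direction == "theta"
    x = rng.standard_normal((5, 3))
    np.testing.assert_array_equal(stochastic_forward(net, x, seed=1),
                                  stochastic_forward(loaded, x, seed=1))
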