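"""PV-RNN core computations: dynamics, heads, KL, free energy, gradients."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from pvrnn_dyad import network as net
from pvrnn_dyad.network import (GaussianLatent, LayerSpec, compute_posterior,
                                compute_prior, deterministic_update,
                                desk_specs, forward_sequence, free_energy,
                                free_energy_and_grads, init_params, kl_unit,
                                output_map, prior_generate, sample_latent,
                                table1_specs)


class TestDeterministicUpdate:
    def test_tau_one_has_no_leak(self):
        specs = [LayerSpec(4, 2, 1.0)]
        p = init_params(specs, seed=0)
        h_prev = [np.full((1, 4), 100.0)]  # would dominate if leaked
        d_prev = [np.zeros((1, 4))]
        z = [np.ones((1, 2))]
        h, d = deterministic_update(h_prev, d_prev, z, p)
        expected = z[0] @ p["Wzd0"].T + p["bh0"]
        np.testing.assert_allclose(h[0], expected, atol=1e-12)

    def test_zero_weight_fixed_point_is_bias(self):
        """With all weights and z zero, h_t = (1-1/tau) h_{t-1} + b/tau,
        whose fixed point is h* = b (solved analytically)."""
        specs = [LayerSpec(3, 1, 4.0)]
        p = init_params(specs, seed=0)
        for k in p.data:
            p.data[k][:] = 0.0
        p.data["bh0"][:] = np.array([0.5, -1.0, 2.0])
        h = [np.zeros((1, 3))]
        d = [np.zeros((1, 3))]
        z = [np.zeros((1, 1))]
        for _ in range(200):
            h, _d = deterministic_update(h, d, z, p)
            d = [np.zeros((1, 3))]  # isolate the scalar recursion in h
        np.testing.assert_allclose(h[0][0], [0.5, -1.0, 2.0], atol=1e-8)

    def test_timescale_hierarchy_slows_higher_layers(self):
        """With the (2, 4, 8) time constants, the lag-1 autocorrelation of
        d~ increases with the layer index."""
        specs = table1_specs()
        assert [s.tau for s in specs] == [2.0, 4.0, 8.0]
        p = init_params(specs, seed=1)
        rng = np.random.default_rng(0)
        h = [np.zeros((1, s.d_dim)) for s in specs]
        d = [np.zeros((1, s.d_dim)) for s in specs]
        traj = [[] for _ in specs]
        for _ in range(300):
            z = [rng.standard_normal((1, s.z_dim)) for s in specs]
            h, d = deterministic_update(h, d, z, p)
            for l in range(3):
                traj[l].append(d[l][0].copy())
        def ac1(x):
            x = np.asarray(x)[50:]
            x = x - x.mean(axis=0)
            num = (x[1:] * x[:-1]).sum()
            return num / (x * x).sum()
        acs = [ac1(traj[l]) for l in range(3)]
        assert acs[0] < acs[1] < acs[2]


class TestLatentHeads:
    def test_prior_is_standard_normal_at_t1(self, tiny_params):
        d_prev = np.full((1, 3), 0.9)
        g = compute_prior(d_prev, tiny_params, 0, t=1)
        np.testing.assert_array_equal(g.mu, 0.0)
        np.testing.assert_array_equal(g.sigma, 1.0)

    def test_zero_weights_give_unit_gaussian(self, tiny_specs):
        p = init_params(tiny_specs, seed=0)
        for k in p.data:
            p.data[k][:] = 0.0
        g = compute_prior(np.ones((1, 3)), p, 0, t=5)
        np.testing.assert_allclose(g.mu, 0.0)
        np.testing.assert_allclose(g.sigma, 1.0)

    def test_sigma_strictly_positive(self, tiny_params):
        d_prev = np.array([[-50.0, 30.0, -4.0]])
        g = compute_prior(d_prev, tiny_params, 0, t=2)
        assert np.all(g.sigma > 0)
        q = compute_posterior(d_prev, np.array([[0.0, -40.0]]),
                              np.array([[-60.0, 0.0]]), tiny_params, 0)
        assert np.all(q.sigma > 0)

    def test_posterior_equals_prior_with_zero_adaptation(self, tiny_specs):
        """Shared heads, equal biases, A = 0 -> q == p."""
        p = init_params(tiny_specs, seed=2, shared_heads=True)
        d_prev = np.random.default_rng(0).uniform(-0.5, 0.5, (1, 3))
        zdim = tiny_specs[0].z_dim
        pri = compute_prior(d_prev, p, 0, t=3)
        post = compute_posterior(d_prev, np.zeros((1, zdim)),
                                 np.zeros((1, zdim)), p, 0)
        np.testing.assert_allclose(pri.mu, post.mu)
        np.testing.assert_allclose(pri.sigma, post.sigma)


class TestSampling:
    def test_tiny_sigma_collapses_to_mean(self):
        g = GaussianLatent(np.array([[1.5, -2.0]]), np.full((1, 2), 1e-12))
        z = sample_latent(g, np.random.default_rng(0))
        np.testing.assert_allclose(z, g.mu, atol=1e-9)

    def test_monte_carlo_mean(self):
        g = GaussianLatent(np.array([[0.7]]), np.array([[2.0]]))
        rng = np.random.default_rng(1)
        draws = np.array([sample_latent(g, rng)[0, 0] for _ in range(100_000)])
        se = 2.0 / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.7) < 4 * se

    def test_reproducible_with_fixed_stream(self):
        g = GaussianLatent(np.zeros((2, 3)), np.ones((2, 3)))
        z1 = sample_latent(g, np.random.default_rng(5))
        z2 = sample_latent(g, np.random.default_rng(5))
        np.testing.assert_array_equal(z1, z2)


class TestKL:
    def test_zero_at_equality(self):
        assert kl_unit(0.3, 1.2, 0.3, 1.2) == pytest.approx(0.0, abs=1e-14)

    def test_unit_shift_closed_form(self):
        # KL(N(1,1) || N(0,1)) = 1/2
        assert kl_unit(0.0, 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_matches_numerical_quadrature(self):
        """Closed form vs quadrature of q log(q/p) on 20 random draws."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            mp, mq = rng.uniform(-2, 2, 2)
            sp, sq = rng.uniform(0.3, 2.5, 2)
            def integrand(x):
                return norm.pdf(x, mq, sq) * (norm.logpdf(x, mq, sq)
                                              - norm.logpdf(x, mp, sp))
            ref, _ = quad(integrand, mq - 12 * sq, mq + 12 * sq, limit=200)
            assert kl_unit(mp, sp, mq, sq) == pytest.approx(ref, abs=1e-6)

    def test_nonnegative_random_draws(self):
        rng = np.random.default_rng(3)
        mp, mq = rng.uniform(-3, 3, (2, 100))
        sp, sq = rng.uniform(0.05, 5, (2, 100))
        assert np.all(kl_unit(mp, sp, mq, sq) >= 0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kl_unit(0.0, 0.0, 0.0, 1.0)


class TestOutputMap:
    def test_zero_weights_yield_bias_activation(self, tiny_params):
        p = tiny_params.copy()
        p.data["Wout"][:] = 0.0
        d1 = np.ones((1, 3))
        np.testing.assert_allclose(output_map(d1, p)[0],
                                   np.tanh(p["bout"]))

    def test_output_dimension_and_bounds(self, tiny_params):
        out = output_map(np.random.default_rng(0).uniform(-1, 1, (5, 3)),
                         tiny_params)
        assert out.shape == (5, 10)
        assert np.all(np.abs(out) < 1.0)


class TestFreeEnergy:
    def test_zero_when_posterior_matches_prior_and_data(self, tiny_specs):
        p = init_params(tiny_specs, seed=0, shared_heads=True)
        a_mu = [np.zeros((1, 4, s.z_dim)) for s in tiny_specs]
        a_sig = [np.zeros((1, 4, s.z_dim)) for s in tiny_specs]
        cache = forward_sequence(p, a_mu, a_sig, use_mean=True)
        targets = np.stack([np.stack(cache.xbar, axis=1)[0]])[..., :]
        terms = free_energy(cache, targets, p,
                            np.array([1.0, 1.0]), np.ones(10))
        assert terms["F"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights_leave_pure_error_term(self, tiny_params, tiny_specs):
        rng = np.random.default_rng(4)
        a_mu = [0.1 * rng.standard_normal((1, 3, s.z_dim)) for s in tiny_specs]
        a_sig = [0.1 * rng.standard_normal((1, 3, s.z_dim)) for s in tiny_specs]
        cache = forward_sequence(tiny_params, a_mu, a_sig, use_mean=True)
        targets = rng.standard_normal((1, 3, 10)) * 0.3
        terms = free_energy(cache, targets, tiny_params,
                            np.zeros(2), np.ones(10), w_at_t1=0.0)
        manual = sum(float(((targets[0, i] - cache.xbar[i][0]) ** 2).sum())
                     for i in range(3)) / 10
        assert terms["complexity"] == 0.0
        assert terms["F"] == pytest.approx(manual, rel=1e-12)

    def test_hand_computed_toy_case(self):
        """1 layer, 1 d unit, 1 z unit, 2 steps: F computed by hand."""
        specs = [LayerSpec(1, 1, 2.0, 1.0, 1.0)]
        p = init_params(specs, seed=0, out_dim=10)
        p.data["Wdd0"][:] = 0.5
        p.data["Wzd0"][:] = 1.0
        p.data["bh0"][:] = 0.1
        p.data["Wmu0"][:] = 0.3
        p.data["Wsig0"][:] = -0.2
        for k in ("bmup0", "bsigp0", "bmuq0", "bsigq0"):
            p.data[k][:] = 0.0
        p.data["Wout"][:] = 0.0
        p.data["Wout"][0, 0] = 1.0
        p.data["bout"][:] = 0.0
        a_mu = [np.array([[[0.4], [0.2]]])]
        a_sig = [np.array([[[-0.1], [0.3]]])]
        eps = [[np.array([[0.5]])], [np.array([[-1.0]])]]
        cache = forward_sequence(p, a_mu, a_sig, eps=eps)
        targets = np.zeros((1, 2, 10))
        targets[0, :, 0] = [0.3, -0.2]
        terms = free_energy(cache, targets, p, np.array([2.0]),
                            np.ones(10), w_at_t1=1.0)

        # hand-stepped forward
        import math
        muq1 = math.tanh(0.4); sigq1 = math.exp(-0.1)
        z1 = muq1 + sigq1 * 0.5
        h1 = 0.5 * (1.0 * z1 + 0.1); d1 = math.tanh(h1)
        x1 = math.tanh(d1)
        kl1 = (math.log(1.0 / sigq1)
               + (muq1 ** 2 + sigq1 ** 2) / 2.0 - 0.5)
        mup2 = math.tanh(0.3 * d1); sigp2 = math.exp(-0.2 * d1)
        muq2 = math.tanh(0.3 * d1 + 0.2); sigq2 = math.exp(-0.2 * d1 + 0.3)
        z2 = muq2 + sigq2 * (-1.0)
        h2 = 0.5 * h1 + 0.5 * (0.5 * d1 + z2 + 0.1); d2 = math.tanh(h2)
        x2 = math.tanh(d2)
        kl2 = (math.log(sigp2 / sigq2)
               + ((muq2 - mup2) ** 2 + sigq2 ** 2) / (2 * sigp2 ** 2) - 0.5)
        err = ((0.3 - x1) ** 2 + (-0.2 - x2) ** 2) / 10.0
        f_hand = 1.0 * kl1 + 2.0 * kl2 + err
        assert terms["F"] == pytest.approx(f_hand, abs=1e-10)

    def test_empty_mask_rejected(self, tiny_params, tiny_specs):
        a_mu = [np.zeros((1, 2, s.z_dim)) for s in tiny_specs]
        a_sig = [np.zeros((1, 2, s.z_dim)) for s in tiny_specs]
        cache = forward_sequence(tiny_params, a_mu, a_sig, use_mean=True)
        with pytest.raises(ValueError):
            free_energy(cache, np.zeros((1, 2, 10)), tiny_params,
                        np.ones(2), np.zeros(10))


@pytest.mark.parametrize("shared", [True, False])
def test_gradients_match_finite_differences(tiny_specs, shared):
    """Analytic BPTT gradients of the free energy agree with central
    finite differences for every parameter group and the adaptive
    variables (relative error < 1e-4)."""
    p = init_params(tiny_specs, seed=3, shared_heads=shared)
    rng = np.random.default_rng(7)
    for k in p.data:
        p.data[k] = p.data[k] + 0.1 * rng.standard_normal(p.data[k].shape)
    B, T = 2, 5
    a_mu = [0.3 * rng.standard_normal((B, T, s.z_dim)) for s in tiny_specs]
    a_sig = [0.2 * rng.standard_normal((B, T, s.z_dim)) for s in tiny_specs]
    eps = [[rng.standard_normal((B, s.z_dim)) for s in tiny_specs]
           for _ in range(T)]
    targets = 0.5 * rng.standard_normal((B, T, 10))
    w = np.array([1.3, 0.7])
    mask = np.ones(10); mask[:3] = 0.0

    def value(params, am, asg):
        cache = forward_sequence(params, am, asg, eps=eps)
        return free_energy(cache, targets, params, w, mask, w_at_t1=1.0)["F"]

    cache = forward_sequence(p, a_mu, a_sig, eps=eps)
    _, g, gm, gs = free_energy_and_grads(p, a_mu, a_sig, cache, targets, w,
                                         mask, w_at_t1=1.0)
    h = 1e-6
    for key in p.data:
        gnum = np.zeros_like(p.data[key])
        it = np.nditer(gnum, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            p2 = p.copy(); p2.data[key][idx] += h
            f1 = value(p2, a_mu, a_sig)
            p2 = p.copy(); p2.data[key][idx] -= h
            f0 = value(p2, a_mu, a_sig)
            gnum[idx] = (f1 - f0) / (2 * h)
        scale = max(np.abs(gnum).max(), 1e-8)
        assert np.abs(g[key] - gnum).max() / scale < 1e-4, key
    for l in range(2):
        for which, arrs, ga in (("mu", a_mu, gm), ("sig", a_sig, gs)):
            gnum = np.zeros_like(arrs[l])
            it = np.nditer(gnum, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                pert = [x.copy() for x in arrs]
                pert[l][idx] += h
                f1 = value(p, pert if which == "mu" else a_mu,
                           pert if which == "sig" else a_sig)
                pert = [x.copy() for x in arrs]
                pert[l][idx] -= h
                f0 = value(p, pert if which == "mu" else a_mu,
                           pert if which == "sig" else a_sig)
                gnum[idx] = (f1 - f0) / (2 * h)
            scale = max(np.abs(gnum).max(), 1e-8)
            assert np.abs(ga[l] - gnum).max() / scale < 1e-4, (which, l)


class TestPriorGenerate:
    def test_untrained_rollout_bounded_and_finite(self, tiny_params):
        traj = prior_generate(tiny_params, 80, seed=0)
        assert np.all(np.isfinite(traj.observations))
        assert np.abs(traj.observations).max() < 1.0

    def test_fixed_seed_reproducible(self, tiny_params):
        t1 = prior_generate(tiny_params, 40, seed=11)
        t2 = prior_generate(tiny_params, 40, seed=11)
        np.testing.assert_array_equal(t1.observations, t2.observations)

    def test_mean_propagation_is_deterministic_without_seed(self, tiny_params):
        t1 = prior_generate(tiny_params, 30, seed=1, use_mean=True)
        t2 = prior_generate(tiny_params, 30, seed=2, use_mean=True)
        np.testing.assert_array_equal(t1.observations, t2.observations)


def test_checkpoint_round_trip(tmp_path, tiny_params):
    path = tmp_path / "ckpt"
    tiny_params.save(str(path))
    back = net.NetworkParams.load(str(path))
    assert [s.d_dim for s in back.specs] == [3, 2]
    for k in tiny_params.data:
        np.testing.assert_array_equal(back.data[k], tiny_params.data[k])


def test_table1_configuration():
    specs = table1_specs()
    assert [s.d_dim for s in specs] == [40, 20, 10]
    assert [s.z_dim for s in specs] == [4, 2, 1]
    assert [s.tau for s in specs] == [2.0, 4.0, 8.0]
    assert [s.w_train for s in specs] == [3.5, 35.0, 350.0]
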