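"""Diploid sigmoid GRN model: dynamics, sampling, and the Monte-Carlo path."""

import numpy as np
import pytest

from gpmono.gpmap import GPMap
from gpmono.grn import (
    Discard,
    DiploidNetworkParams,
    SimConfig,
    hill,
    monte_carlo_study,
    regulation_function,
    rhs,
    sample_genotype_parameters,
    simulate_gpmap,
    steady_state,
)
from gpmono.monotonicity import degree_of_monotonicity

CASCADE = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]])  # X1 -> X2 -> X3
FAST_CFG = SimConfig(n_reps=1, seed=0)


def _uniform_params(A, alpha=150.0, theta=25.0, p=4.0):
    return DiploidNetworkParams(
        A=np.asarray(A, int),
        alpha=np.full((3, 2), alpha),
        theta=np.full((3, 3, 2), theta),
        p=np.full((3, 3, 2), p),
    )


class TestHill:
    def test_half_maximal_at_threshold(self):
        for p in (1.0, 3.7, 10.0):
            assert hill(25.0, 25.0, p) == pytest.approx(0.5)

    def test_limits(self):
        assert hill(0.0, 25.0, 2.0) == 0.0
        assert hill(0.0, 25.0, 2.0, "repressor") == 1.0
        assert hill(1e6, 25.0, 4.0) == pytest.approx(1.0, abs=1e-6)

    def test_activator_repressor_complementary(self):
        for y in (0.1, 25.0, 300.0):
            total = hill(y, 25.0, 3.0) + hill(y, 25.0, 3.0, "repressor")
            assert total == pytest.approx(1.0)

    def test_extreme_steepness_no_overflow(self):
        assert hill(1e-200, 30.0, 10.0) == 0.0
        assert hill(1e200, 30.0, 10.0) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill(-1.0, 25.0, 2.0)
        with pytest.raises(ValueError):
            hill(1.0, 0.0, 2.0)


class TestRegulation:
    def test_unregulated_gene_always_on(self):
        params = _uniform_params(np.zeros((3, 3)))
        assert regulation_function(params.A, 0, 0, (0.0, 0.0, 0.0), params) == 1.0

    def test_two_activators_at_threshold_product(self):
        A = np.zeros((3, 3), int)
        A[2, 0] = A[2, 1] = 1
        params = _uniform_params(A)
        r = regulation_function(A, 2, 0, (25.0, 25.0, 0.0), params)
        assert r == pytest.approx(0.25)

    def test_single_repressor_vanishes_at_high_dose(self):
        A = np.zeros((3, 3), int)
        A[2, 1] = -1
        params = _uniform_params(A)
        assert regulation_function(A, 2, 0, (0.0, 1e9, 0.0), params) < 1e-10


class TestRHS:
    def test_unregulated_fixed_point(self):
        params = _uniform_params(np.zeros((3, 3)), alpha=150.0)
        x = np.full(6, 15.0)  # alpha / gamma per allele copy
        np.testing.assert_allclose(rhs(x, params.A, params), 0.0, atol=1e-12)

    def test_zero_state_production_only(self):
        params = _uniform_params(np.zeros((3, 3)), alpha=120.0)
        np.testing.assert_allclose(rhs(np.zeros(6), params.A, params), 120.0)

    def test_decoupled_when_unwired(self):
        params = _uniform_params(np.zeros((3, 3)))
        a = rhs(np.array([1.0, 2.0, 0.0, 0.0, 0.0, 0.0]), params.A, params)
        b = rhs(np.array([1.0, 2.0, 9.0, 9.0, 9.0, 9.0]), params.A, params)
        np.testing.assert_allclose(a[:2], b[:2])


class TestSteadyState:
    def test_unregulated_closed_form(self):
        params = _uniform_params(np.zeros((3, 3)))
        alpha = params.alpha.copy()
        alpha[0] = [140.0, 160.0]
        params = DiploidNetworkParams(
            A=params.A, alpha=alpha, theta=params.theta, p=params.p
        )
        out = steady_state(params.A, params, FAST_CFG, counts=(1, 1, 1))
        assert out is not None
        _, y = out
        assert y[0] == pytest.approx((140.0 + 160.0) / 10.0, rel=1e-6)
        assert y[1] == pytest.approx(30.0, rel=1e-6)

    def test_activator_cascade_converges(self):
        params = _uniform_params(CASCADE)
        out = steady_state(CASCADE, params, FAST_CFG)
        assert out is not None
        x, y = out
        assert np.all(x >= 0) and np.all(np.isfinite(y))

    def test_oscillating_negative_loop_flagged(self):
        # X3 -| X1 -> X2 -> X3 with a low-amplitude X1 stage: stable limit
        # cycle, so no stable point is ever reached
        A = np.array([[0, 0, -1], [1, 0, 0], [0, 1, 0]])
        theta = np.full((3, 3, 2), 1.0)
        p = np.full((3, 3, 2), 1.0)
        theta[2, 0, :] = 15.0
        p[2, 0, :] = 6.0
        theta[0, 1, :] = 0.3
        p[0, 1, :] = 6.0
        theta[1, 2, :] = 15.0
        p[1, 2, :] = 6.0
        params = DiploidNetworkParams(
            A=A,
            alpha=np.array([[5.0, 5.0], [150.0, 150.0], [150.0, 150.0]]),
            theta=theta,
            p=p,
        )
        assert steady_state(A, params, SimConfig(t_max=300.0)) is None


class TestParameterSampling:
    def test_ranges(self, rng):
        params = sample_genotype_parameters(CASCADE, True, rng)
        assert np.all((params.alpha >= 100) & (params.alpha <= 200))
        assert np.all((params.theta >= 20) & (params.theta <= 40))
        assert np.all((params.p >= 1) & (params.p <= 10))
        assert params.gamma == 10.0

    def test_no_pleiotropy_shares_regulation_parameters(self, rng):
        params = sample_genotype_parameters(CASCADE, False, rng)
        np.testing.assert_array_equal(params.theta[..., 0], params.theta[..., 1])
        np.testing.assert_array_equal(params.p[..., 0], params.p[..., 1])
        assert not np.array_equal(params.alpha[:, 0], params.alpha[:, 1])

    def test_pleiotropy_allele_specific(self, rng):
        params = sample_genotype_parameters(CASCADE, True, rng)
        assert not np.array_equal(params.theta[..., 0], params.theta[..., 1])

    def test_same_seed_same_table(self):
        a = sample_genotype_parameters(CASCADE, True, np.random.default_rng(3))
        b = sample_genotype_parameters(CASCADE, True, np.random.default_rng(3))
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.theta, b.theta)


class TestSimulateGPMap:
    def test_downstream_alpha_variation_additive(self):
        """With variation only in alpha_3 and constant upstream regulation,
        the phenotype is (alpha_31 + alpha_32) * R / gamma, additive in the
        allelic production rates."""
        A = np.zeros((3, 3), int)
        A[2, 0] = 1  # X3 activated by (invariant) X1
        params = _uniform_params(A)
        alpha = params.alpha.copy()
        alpha[2] = [110.0, 190.0]
        params = DiploidNetworkParams(A=A, alpha=alpha, theta=params.theta, p=params.p)
        out = simulate_gpmap(A, params, FAST_CFG)
        assert isinstance(out, GPMap)
        y1 = 30.0
        R = 1.0 / (1.0 + (25.0 / y1) ** 4.0)
        shaped = out.values.reshape(3, 3, 3)
        for c3, total in enumerate((220.0, 300.0, 380.0)):
            np.testing.assert_allclose(shaped[:, :, c3], total * R / 10.0, rtol=1e-9)

    def test_equal_alleles_give_flat_discard(self):
        params = _uniform_params(CASCADE)  # identical allele variants
        out = simulate_gpmap(CASCADE, params, FAST_CFG)
        assert isinstance(out, Discard) and out.reason == "flat"

    def test_cascade_no_pleiotropy_monotone(self, rng):
        params = sample_genotype_parameters(CASCADE, False, rng)
        out = simulate_gpmap(CASCADE, params, FAST_CFG)
        assert isinstance(out, GPMap)
        m, report = degree_of_monotonicity(out)
        assert m == pytest.approx(1.0, abs=1e-9)
        assert report.order_breaking_count == 0

    def test_homozygote_allele_swap_symmetry(self, rng):
        """Swapping the allelic variants of a locus permutes genotype values."""
        params = sample_genotype_parameters(CASCADE, True, rng)
        out = simulate_gpmap(CASCADE, params, FAST_CFG)
        swapped = simulate_gpmap(CASCADE, params.swap_alleles(0), FAST_CFG)
        assert isinstance(out, GPMap) and isinstance(swapped, GPMap)
        a = out.values.reshape(3, 3, 3)
        b = swapped.values.reshape(3, 3, 3)
        np.testing.assert_allclose(a, b[::-1, :, :], rtol=1e-8)


class TestMonteCarlo:
    def test_fixed_seed_reproducible_and_counts_reconcile(self):
        cfg = SimConfig(pleiotropy=False, n_reps=4, seed=11)
        motifs = [CASCADE, np.array([[0, 0, 0], [0, 0, 0], [1, 1, 0]])]
        r1 = monte_carlo_study(motifs, cfg)
        r2 = monte_carlo_study(motifs, cfg)
        for a, b in zip(r1, r2):
            assert a.usable == b.usable
            np.testing.assert_array_equal(a.order_breaking_hist, b.order_breaking_hist)
            np.testing.assert_allclose(a.m_values, b.m_values)
            assert a.usable + a.discarded_nonconv + a.discarded_flat == cfg.n_reps

    def test_scaled_inclusion_threshold(self):
        assert SimConfig(n_reps=50).min_usable == 5
        assert SimConfig(n_reps=1000).min_usable == 100
        assert SimConfig(n_reps=5).min_usable == 1
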