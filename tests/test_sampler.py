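import numpy as np
import pytest

from mmsdina import (
    ChainConfig,
    ItemParameters,
    ModelValidationError,
    MultiStrategyQMatrix,
    PriorSpec,
    ResponseMatrix,
    run_chain,
    run_chains,
    sample_attribute_mean,
    sample_item_params,
    sample_memberships,
    sample_pi,
    sample_profiles,
)
from mmsdina.model_core import all_profiles, compute_eta
from mmsdina.sampler import four_beta_mean, membership_log_weights


class TestMixingProportions:
    def test_posterior_moments_match_dirichlet(self, rng):
        """Long-run mean of Step-1 draws equals (beta_m + n_m) / sum."""
        c = np.repeat([0, 1], [432, 96])
        draws = np.stack([sample_pi(c, 2, 0.01, rng) for _ in range(4000)])
        expected = np.array([432.01, 96.01]) / 528.02
        assert np.allclose(draws.mean(axis=0), expected, atol=0.002)

    def test_empty_data_gives_prior(self, rng):
        draws = np.stack([sample_pi(np.array([], dtype=int), 3, 2.0, rng)
                          for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), 1 / 3, atol=0.01)

    def test_simplex(self, rng):
        pi = sample_pi(np.array([0, 1, 1]), 2, 0.01, rng)
        assert pi.sum() == pytest.approx(1.0) and (pi >= 0).all()


class TestMemberships:
    def test_symmetric_likelihoods_give_half(self, rng):
        """Identical Q-blocks, mu and item parameters make both strategies
        equally likely."""
        q = np.array([[1, 0], [0, 1]])
        with pytest.warns(UserWarning):
            qmat = MultiStrategyQMatrix.from_strategies([q, q.copy()])
        params = ItemParameters(np.full((2, 2), 0.3), np.full((2, 2), 0.1))
        resp = ResponseMatrix(rng.integers(0, 2, size=(200, 2)))
        alpha = rng.integers(0, 2, size=(200, 2))
        logw = membership_log_weights(resp, alpha, params, (0.5, 0.5),
                                      (0.5, 0.5), qmat)
        assert np.allclose(logw[:, 0], logw[:, 1])
        c = sample_memberships(resp, alpha, params, (0.5, 0.5), (0.5, 0.5),
                               qmat, rng)
        assert abs(c.mean() - 0.5) < 0.12

    def test_degenerate_pi_forces_membership(self, small_qmatrix, small_params, rng):
        resp = ResponseMatrix(rng.integers(0, 2, size=(50, 4)))
        alpha = rng.integers(0, 2, size=(50, 2))
        c = sample_memberships(resp, alpha, small_params, (1.0, 0.0),
                               (0.5, 0.5), small_qmatrix, rng)
        assert (c == 0).all()

    def test_weights_match_brute_force(self, small_qmatrix, small_params):
        """Tiny case: membership probabilities equal the directly multiplied
        product of response terms, profile prior and mixing weight."""
        u = np.array([[1, 0, 1, 1]])
        alpha = np.array([[1, 0]])
        pi, mu = np.array([0.3, 0.7]), np.array([0.4, 0.8])
        logw = membership_log_weights(ResponseMatrix(u), alpha, small_params,
                                      pi, mu, small_qmatrix)
        for m in range(2):
            expected = np.log(pi[m])
            for j in range(4):
                eta = compute_eta(alpha[0], small_qmatrix.q[m, j])
                p1 = (1 - small_params.s[j, m]) if eta else small_params.g[j, m]
                expected += np.log(p1 if u[0, j] else 1 - p1)
            for k in range(2):
                expected += np.log(mu[m] if alpha[0, k] else 1 - mu[m])
            assert logw[0, m] == pytest.approx(expected, abs=1e-12)


class TestAttributeMean:
    def test_counting_case_moments(self, rng):
        """One member with alpha = (1, 0): the update is Beta(1.5, 1.5)."""
        alpha = np.array([[1, 0]])
        c = np.array([0])
        draws = np.array([
            sample_attribute_mean(alpha, c, 0, 0.5, 0.5, rng)
            for _ in range(6000)
        ])
        assert draws.mean() == pytest.approx(0.5, abs=0.01)
        assert draws.var() == pytest.approx(1.5 * 1.5 / (9 * 4), abs=0.01)

    def test_empty_strategy_gives_prior(self, rng):
        alpha = np.array([[1, 0]])
        draws = np.array([
            sample_attribute_mean(alpha, np.array([0]), 1, 0.5, 0.5, rng)
            for _ in range(6000)
        ])
        # Beta(0.5, 0.5): mean 1/2, variance 1/8
        assert draws.mean() == pytest.approx(0.5, abs=0.02)
        assert draws.var() == pytest.approx(0.125, abs=0.01)

    def test_literal_full_sample_variant(self, rng):
        """The literal reading uses N*K in the second shape parameter."""
        alpha = np.array([[1, 1], [0, 0]])
        c = np.array([0, 1])
        draws = np.array([
            sample_attribute_mean(alpha, c, 0, 0.5, 0.5, rng, literal_N=2)
            for _ in range(6000)
        ])
        # Beta(2.5, 4 - 2 + 0.5) = Beta(2.5, 2.5)
        assert draws.mean() == pytest.approx(0.5, abs=0.01)


class TestProfiles:
    def test_exact_enumeration_oracle_k3(self, rng):
        """Empirical profile frequencies match the hand-enumerated 8-point
        posterior for a single examinee."""
        q = MultiStrategyQMatrix.from_strategies(
            [np.array([[1, 0, 0], [0, 1, 1], [1, 1, 0]])]
        )
        params = ItemParameters(np.array([[0.2], [0.3], [0.25]]),
                                np.array([[0.15], [0.1], [0.2]]))
        u = np.array([[1, 0, 1]])
        mu = np.array([0.6])
        # brute-force posterior over the 8 profiles
        weights = []
        for prof in all_profiles(3):
            w = 1.0
            for j in range(3):
                eta = compute_eta(prof, q.q[0, j])
                p1 = (1 - params.s[j, 0]) if eta else params.g[j, 0]
                w *= p1 if u[0, j] else 1 - p1
            w *= np.prod([mu[0] if a else 1 - mu[0] for a in prof])
            weights.append(w)
        expected = np.array(weights) / np.sum(weights)
        n = 40_000
        resp = ResponseMatrix(np.repeat(u, n, axis=0))
        c = np.zeros(n, dtype=int)
        alpha = sample_profiles(resp, c, params, mu, q, rng)
        idx = alpha @ (1 << np.arange(3))
        freq = np.bincount(idx, minlength=8) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(freq - expected) < 4 * se + 1e-3).all()

    def test_no_items_gives_prior(self, rng):
        q = MultiStrategyQMatrix(np.zeros((1, 0, 3), dtype=int))
        params = ItemParameters(np.zeros((0, 1)), np.zeros((0, 1)))
        resp = ResponseMatrix(np.zeros((3000, 0), dtype=int))
        alpha = sample_profiles(resp, np.zeros(3000, dtype=int), params,
                                np.array([0.7]), q, rng)
        assert abs(alpha.mean() - 0.7) < 0.02

    def test_flat_likelihood_gives_prior(self, rng):
        """With 1 - s = g the item response law is the same whether or not
        the requirement is met, so the data carry no information and the
        posterior over mastery equals the prior."""
        q = MultiStrategyQMatrix.from_strategies([np.array([[1]])])
        params = ItemParameters(np.array([[0.5]]), np.array([[0.5]]))
        resp = ResponseMatrix(np.ones((4000, 1), dtype=int))
        alpha = sample_profiles(resp, np.zeros(4000, dtype=int), params,
                                np.array([0.35]), q, rng)
        assert abs(alpha.mean() - 0.35) < 0.025

    def test_enumeration_cap(self, rng):
        q = MultiStrategyQMatrix(np.ones((1, 2, 4), dtype=int))
        params = ItemParameters(np.full((2, 1), 0.3), np.full((2, 1), 0.1))
        resp = ResponseMatrix(np.ones((5, 2), dtype=int))
        with pytest.raises(ModelValidationError):
            sample_profiles(resp, np.zeros(5, dtype=int), params,
                            np.array([0.5]), q, rng, max_enum_K=3)
        alpha = sample_profiles(resp, np.zeros(5, dtype=int), params,
                                np.array([0.5]), q, rng, max_enum_K=3,
                                fallback=True)
        assert alpha.shape == (5, 4) and np.isin(alpha, (0, 1)).all()


class TestItemParameters:
    def test_no_relevant_examinees_gives_prior(self, rng):
        """Nobody uses strategy 2, so its parameters are prior draws from
        4-Beta(1, 2, 0.1, 0.5) with mean 0.1 + 0.4/3."""
        q = MultiStrategyQMatrix.from_strategies(
            [np.array([[1, 0]]), np.array([[0, 1]])]
        )
        resp = ResponseMatrix(np.ones((30, 1), dtype=int))
        alpha = np.ones((30, 2), dtype=int)
        c = np.zeros(30, dtype=int)
        prior = PriorSpec()
        s2 = np.array([
            sample_item_params(resp, c, alpha, q, prior, rng)[0].s[0, 1]
            for _ in range(3000)
        ])
        assert (s2 > 0.1).all() and (s2 < 0.5).all()
        assert s2.mean() == pytest.approx(four_beta_mean((1, 2), (0.1, 0.5)),
                                          abs=0.01)

    def test_posterior_mean_matches_quadrature(self, rng):
        """Grid-sampler draws reproduce the trapezoid-integrated mean of the
        unnormalized truncated density."""
        q = MultiStrategyQMatrix.from_strategies([np.array([[1]])])
        n, n_correct = 40, 30
        u = np.zeros((n, 1), dtype=int)
        u[:n_correct] = 1
        alpha = np.ones((n, 1), dtype=int)  # everyone satisfies the item
        prior = PriorSpec()
        draws = np.array([
            sample_item_params(ResponseMatrix(u), np.zeros(n, dtype=int),
                               alpha, q, prior, rng)[0].s[0, 0]
            for _ in range(4000)
        ])
        x = np.linspace(0.1 + 1e-9, 0.5 - 1e-9, 10_000)
        dens = (x ** (n - n_correct) * (1 - x) ** n_correct
                * (0.5 - x))  # 4-Beta(1,2,a,b) kernel on (a, b)
        expected = np.trapezoid(x * dens, x) / np.trapezoid(dens, x)
        assert draws.mean() == pytest.approx(expected, abs=0.005)

    def test_mh_variant_stays_in_support(self, rng, small_qmatrix):
        resp = ResponseMatrix(rng.integers(0, 2, size=(40, 4)))
        alpha = rng.integers(0, 2, size=(40, 2))
        c = rng.integers(0, 2, size=40)
        params, accepted, total = sample_item_params(
            resp, c, alpha, small_qmatrix, PriorSpec(), rng, method="mh")
        assert (params.s > 0.1).all() and (params.s < 0.5).all()
        assert 0 <= accepted <= total


class TestRunChain:
    def test_dina_is_bitwise_m1_mixture(self, rng):
        q1 = np.array([[1, 0], [0, 1], [1, 1]])
        qmat = MultiStrategyQMatrix.from_strategies([q1])
        design_u = (np.random.default_rng(0).random((25, 3)) < 0.5).astype(int)
        resp = ResponseMatrix(design_u)
        cfg = ChainConfig(iterations=120, burn_in=60, rng_seed=5)
        d1 = run_chain(resp, qmat, config=cfg, model="dina")
        d2 = run_chain(resp, qmat, config=cfg, model="mmsdina")
        assert np.array_equal(d1.s, d2.s)
        assert np.array_equal(d1.g, d2.g)
        assert np.array_equal(d1.alpha, d2.alpha)
        assert np.array_equal(d1.loglik, d2.loglik)

    def test_prior_recovery_with_no_examinees(self):
        """With zero examinees every retained slipping draw follows the
        4-Beta(1, 2, 0.1, 0.5) prior; its mean is 0.1 + 0.4/3 = 0.2333."""
        qmat = MultiStrategyQMatrix.from_strategies(
            [np.array([[1, 0], [0, 1]]), np.array([[0, 1], [1, 0]])]
        )
        resp = ResponseMatrix(np.zeros((0, 2), dtype=int))
        cfg = ChainConfig(iterations=1500, burn_in=200, rng_seed=11,
                          store_cell_logp=False)
        draws = run_chain(resp, qmat, config=cfg)
        assert draws.s.mean() == pytest.approx(0.2333, abs=0.01)
        assert draws.g.mean() == pytest.approx(0.2333, abs=0.01)

    def test_seed_determinism(self, tiny_dataset):
        cfg = ChainConfig(iterations=150, burn_in=50, rng_seed=77)
        qmat = tiny_dataset.design.resolve_qmatrix()
        a = run_chain(tiny_dataset.responses, qmat, config=cfg)
        b = run_chain(tiny_dataset.responses, qmat, config=cfg)
        assert np.array_equal(a.s, b.s)
        assert np.array_equal(a.c, b.c)
        assert np.array_equal(a.loglik, b.loglik)

    def test_retained_draws_satisfy_invariants(self, tiny_dataset):
        cfg = ChainConfig(iterations=200, burn_in=100, rng_seed=3)
        qmat = tiny_dataset.design.resolve_qmatrix()
        draws = run_chain(tiny_dataset.responses, qmat, config=cfg)
        draws.validate()
        assert draws.R == 100
        assert draws.pi.shape == (100, 2)

    def test_msdina_shapes(self, tiny_dataset):
        cfg = ChainConfig(iterations=120, burn_in=60, rng_seed=3)
        qmat = tiny_dataset.design.resolve_qmatrix()
        draws = run_chain(tiny_dataset.responses, qmat, config=cfg,
                          model="msdina")
        assert draws.pi is None and draws.c is None
        assert draws.s.shape == (60, 4, 1)
        assert draws.mu.shape == (60, 1)
        draws.validate()

    def test_unknown_model_rejected(self, tiny_dataset):
        with pytest.raises(ModelValidationError):
            run_chain(tiny_dataset.responses,
                      tiny_dataset.design.resolve_qmatrix(), model="rasch")

    def test_multichain_dispersed_and_reproducible(self, tiny_dataset):
        cfg = ChainConfig(iterations=150, burn_in=50, rng_seed=9, n_chains=2)
        qmat = tiny_dataset.design.resolve_qmatrix()
        first = run_chains(tiny_dataset.responses, qmat, config=cfg)
        second = run_chains(tiny_dataset.responses, qmat, config=cfg)
        assert len(first) == 2
        assert not np.array_equal(first[0].s, first[1].s)
        assert np.array_equal(first[0].s, second[0].s)

    def test_defaults_match_protocol(self):
        cfg = ChainConfig()
        assert cfg.iterations == 10_000 and cfg.burn_in == 5_000
        assert cfg.thinning == 1


class TestEquilibrium:
    def test_membership_profile_updates_reach_exact_posterior(self, rng):
        """Alternating the membership and profile full conditionals with the
        other parameters frozen must equilibrate to the exact joint law of
        (c_i, alpha_i), computed here by enumerating all M x 2^K states."""
        q = MultiStrategyQMatrix.from_strategies(
            [np.array([[1, 0], [0, 1], [1, 1]]),
             np.array([[0, 1], [1, 0], [1, 0]])]
        )
        params = ItemParameters(np.array([[0.2, 0.35], [0.3, 0.15], [0.25, 0.3]]),
                                np.array([[0.12, 0.2], [0.1, 0.25], [0.18, 0.11]]))
        pi = np.array([0.45, 0.55])
        mu = np.array([0.35, 0.7])
        u_row = np.array([1, 0, 1])
        # exact joint posterior over (m, profile)
        exact = np.zeros((2, 4))
        for m in range(2):
            for p, prof in enumerate(all_profiles(2)):
                w = pi[m]
                for j in range(3):
                    eta = compute_eta(prof, q.q[m, j])
                    p1 = (1 - params.s[j, m]) if eta else params.g[j, m]
                    w *= p1 if u_row[j] else 1 - p1
                w *= np.prod([mu[m] if a else 1 - mu[m] for a in prof])
                exact[m, p] = w
        exact /= exact.sum()
        # run the two updates jointly on many iid copies of the examinee
        n = 6000
        resp = ResponseMatrix(np.tile(u_row, (n, 1)))
        alpha = rng.integers(0, 2, size=(n, 2))
        c = rng.integers(0, 2, size=n)
        for _ in range(60):
            c = sample_memberships(resp, alpha, params, pi, mu, q, rng)
            alpha = sample_profiles(resp, c, params, mu, q, rng)
        idx = alpha @ np.array([1, 2])
        freq = np.zeros((2, 4))
        for m in range(2):
            freq[m] = np.bincount(idx[c == m], minlength=4) / n
        se = np.sqrt(exact * (1 - exact) / n)
        assert (np.abs(freq - exact) < 4 * se + 2e-3).all()
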