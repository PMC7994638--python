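import numpy as np
import pytest
from scipy import optimize, stats

from helpers_oracles import (
    oracle_forward_loglik,
    oracle_transition,
    oracle_viterbi,
    random_instance,
)
from pigmove import synthetic
from pigmove.distributions import ZeroStepError
from pigmove.hmm import (
    HMMParams,
    HMMResults,
    MovementHMM,
    select_states,
    transition_matrix,
)
from pigmove.tracks import StepSeries


def _series(steps, turns, hours):
    return StepSeries(
        animal_id="t", burst_id=0, t=np.arange(len(steps)),
        steps=np.asarray(steps, dtype=float),
        turns=np.asarray(turns, dtype=float),
        hours=np.asarray(hours, dtype=float),
        season="low_forage",
    )


def _params_k1(mean=50.0, sd=30.0, turn_mean=0.5, rho=0.4):
    return HMMParams(
        means=[mean], sds=[sd], turn_means=[turn_mean], rhos=[rho],
        beta=np.zeros((0, 3)), delta=[1.0], covariate_form="cosinor",
    )


class TestTransitionMatrix:
    def test_zero_coefficients_uniform(self):
        K = 3
        p = HMMParams(
            means=[1, 2, 3], sds=[1, 2, 3], turn_means=[0, 0, 0],
            rhos=[0.1, 0.1, 0.1], beta=np.zeros((6, 3)),
            delta=np.full(3, 1 / 3),
        )
        G = transition_matrix(p, 13.7)
        np.testing.assert_allclose(G, np.full((3, 3), 1 / 3), atol=1e-12)

    def test_two_state_logit_arithmetic(self):
        beta = np.zeros((2, 1))
        beta[0, 0] = np.log(2.0)  # eta_12 = ln 2 -> row 1 = (1/3, 2/3)
        p = HMMParams(
            means=[1, 2], sds=[1, 2], turn_means=[0, 0], rhos=[0.1, 0.1],
            beta=beta, delta=[0.5, 0.5], covariate_form="none",
        )
        G = transition_matrix(p, 0.0)
        np.testing.assert_allclose(G[0], [1 / 3, 2 / 3], atol=1e-12)
        np.testing.assert_allclose(G[1], [0.5, 0.5], atol=1e-12)

    def test_24h_periodicity_and_row_sums(self, rng):
        for _ in range(50):
            params, _ = random_instance(rng, K=3, T=2)
            h = float(rng.uniform(0, 24))
            G = transition_matrix(params, h)
            G2 = transition_matrix(params, h + 24.0)
            np.testing.assert_allclose(G, G2, atol=1e-12)
            np.testing.assert_allclose(G.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(G > 0) and np.all(G < 1)

    def test_matches_naive_construction(self, rng):
        params, _ = random_instance(rng, K=3, T=2)
        for h in (0.0, 7.3, 23.9):
            np.testing.assert_allclose(
                transition_matrix(params, h), oracle_transition(params, h),
                atol=1e-12,
            )


class TestForwardLoglik:
    def test_single_state_collapses_to_independent_sums(self, rng):
        p = _params_k1()
        T = 40
        steps = rng.gamma(2.0, 30.0, T) + 1.0
        turns = rng.uniform(-np.pi, np.pi, T)
        turns[0] = np.nan
        hours = rng.uniform(0, 24, T)
        series = _series(steps, turns, hours)
        model = MovementHMM([series], n_states=1)
        shape, scale = (50.0 / 30.0) ** 2, 30.0**2 / 50.0
        expected = stats.gamma.logpdf(steps, shape, scale=scale).sum()
        expected += stats.wrapcauchy.logpdf(
            np.mod(turns[1:] - 0.5, 2 * np.pi), 0.4
        ).sum()
        assert model.loglike(p) == pytest.approx(expected, abs=1e-8)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            params, series = random_instance(rng)
            model = MovementHMM(
                [series], n_states=params.n_states,
                transition_covariate=params.covariate_form,
            )
            assert model.loglike(params) == pytest.approx(
                oracle_forward_loglik(params, series), abs=1e-10
            )

    def test_invariant_to_state_relabeling(self, rng):
        params, series = random_instance(rng, K=3, T=7)
        model = MovementHMM([series], n_states=3)
        base = model.loglike(params)
        for perm in ([2, 0, 1], [1, 0, 2], [2, 1, 0]):
            relabeled = params.relabel(np.array(perm))
            assert model.loglike(relabeled) == pytest.approx(base, abs=1e-9)

    def test_invariant_to_burst_order(self, rng):
        params, s1 = random_instance(rng, K=2, T=6)
        _, s2 = random_instance(rng, K=2, T=5)
        s2.steps *= 0.5
        a = MovementHMM([s1, s2], n_states=2).loglike(params)
        b = MovementHMM([s2, s1], n_states=2).loglike(params)
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_steps_rejected_without_zero_mass(self):
        s = _series([10.0, 0.0, 5.0], [np.nan, 0.1, -0.2], [0, 1, 2])
        with pytest.raises(ZeroStepError):
            MovementHMM([s], n_states=2)
        MovementHMM([s], n_states=2, zero_mass=True)  # accepted


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        from pigmove._kernels import forward_nll, forward_nll_grad

        for covariate in ("none", "hour", "cosinor"):
            params, series = random_instance(rng, K=3, T=8,
                                             covariate_form=covariate)
            m = MovementHMM([series], n_states=3,
                            transition_covariate=covariate)
            theta = params.to_working()
            C = m.tcov.shape[1]
            nll, grad = forward_nll_grad(
                theta, 3, C, False, m.steps, m.turns, m.tcov, m.burst_starts
            )
            assert nll == pytest.approx(-m.loglike(params), abs=1e-9)
            for i in range(len(theta)):
                e = np.zeros_like(theta)
                e[i] = 1e-6
                fd = (
                    forward_nll(theta + e, 3, C, False, m.steps, m.turns,
                                m.tcov, m.burst_starts)
                    - forward_nll(theta - e, 3, C, False, m.steps, m.turns,
                                  m.tcov, m.burst_starts)
                ) / 2e-6
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestViterbi:
    def test_single_state_path(self, rng):
        p = _params_k1()
        series = _series(
            rng.gamma(2, 30, 10) + 1, np.r_[np.nan, rng.uniform(-3, 3, 9)],
            np.arange(10) % 24,
        )
        model = MovementHMM([series], n_states=1)
        res = HMMResults(model, p, 0.0, 1, [])
        assert np.all(res.decode() == 1)

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(30):
            params, series = random_instance(rng, K=2)
            model = MovementHMM(
                [series], n_states=2,
                transition_covariate=params.covariate_form,
            )
            res = HMMResults(model, params, 0.0, 1, [])
            np.testing.assert_array_equal(
                res.decode(), oracle_viterbi(params, series)
            )

    def test_well_separated_states_decoded_accurately(self):
        means = np.array([10.0, 400.0])
        p = HMMParams.constant_transitions(
            means=means, sds=[8.0, 300.0], turn_means=[np.pi * 0.99, 0.0],
            rhos=[0.7, 0.8], tpm=np.array([[0.95, 0.05], [0.05, 0.95]]),
        )
        rng = np.random.default_rng(12)
        _, true_states, series = synthetic.simulate_track(p, 3000, rng=rng)
        model = MovementHMM([series], n_states=2, transition_covariate="none")
        res = HMMResults(model, p, 0.0, 1, [])
        agree = np.mean(res.decode() == true_states)
        assert agree >= 0.95


class TestFit:
    def test_seeded_fit_is_deterministic(self, short_series):
        model = MovementHMM(short_series[:2], n_states=2,
                            transition_covariate="none")
        r1 = model.fit(n_starts=3, seed=42)
        r2 = model.fit(n_starts=3, seed=42)
        assert r1.loglik == r2.loglik
        np.testing.assert_array_equal(r1.params.to_working(),
                                      r2.params.to_working())

    def test_states_labeled_by_ascending_mean(self, short_series):
        res = MovementHMM(short_series, n_states=3,
                          transition_covariate="none").fit(n_starts=4, seed=3)
        assert np.all(np.diff(res.params.means) > 0)

    def test_single_state_fit_matches_direct_mle(self, rng):
        steps = rng.gamma(2.5, 40.0, 600) + 0.1
        from pigmove.distributions import wcauchy_rvs

        turns = np.r_[np.nan, wcauchy_rvs(1.0, 0.5, 599, rng)]
        series = _series(steps, turns, np.arange(600) % 24)
        res = MovementHMM([series], n_states=1,
                          transition_covariate="none").fit(n_starts=3, seed=0)

        # independent route: separate MLEs of the two 2-parameter densities
        def gam_nll(par):
            mu, sig = np.exp(par)
            a, sc = (mu / sig) ** 2, sig**2 / mu
            return -stats.gamma.logpdf(steps, a, scale=sc).sum()

        def wc_nll(par):
            mu = 2 * np.arctan(par[0])
            rho = 1 / (1 + np.exp(-par[1]))
            d = 1 + rho**2 - 2 * rho * np.cos(turns[1:] - mu)
            return -np.sum(np.log((1 - rho**2) / (2 * np.pi * d)))

        g = optimize.minimize(gam_nll, [np.log(80), np.log(50)], method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12})
        w = optimize.minimize(wc_nll, [0.5, 0.0], method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12})
        mu, sig = np.exp(g.x)
        assert res.params.means[0] == pytest.approx(mu, rel=1e-5)
        assert res.params.sds[0] == pytest.approx(sig, rel=1e-5)
        assert res.params.turn_means[0] == pytest.approx(
            2 * np.arctan(w.x[0]), abs=1e-4
        )
        assert res.loglik == pytest.approx(-(g.fun + w.fun), abs=1e-5)

    def test_recovers_simulated_parameters(self, female_low_params):
        rng = np.random.default_rng(31)
        series = [
            synthetic.simulate_track(female_low_params, 800, rng=rng)[2]
            for _ in range(8)
        ]
        res = MovementHMM(series, n_states=3,
                          transition_covariate="none").fit(n_starts=8, seed=2)
        np.testing.assert_allclose(
            res.params.means, female_low_params.means, rtol=0.10
        )
        G = res.params.transition_matrix(0.0)
        np.testing.assert_allclose(
            G, female_low_params.transition_matrix(0.0), atol=0.05
        )


class TestAICSelection:
    def _stub(self, loglik, K, n_cov=1):
        p = HMMParams(
            means=np.arange(1, K + 1, dtype=float),
            sds=np.ones(K), turn_means=np.zeros(K), rhos=np.full(K, 0.1),
            beta=np.zeros((K * (K - 1), n_cov)), delta=np.full(K, 1 / K),
            covariate_form="none",
        )
        return HMMResults(model=None, params=p, loglik=loglik, n_starts=1,
                          diagnostics=[])

    def test_aic_formula(self):
        fit = self._stub(-100.0, 2)
        # K=2, constant transitions: 4*2 emission + 2 transition + 1 delta = 11
        assert fit.n_params == 11
        assert fit.aic == pytest.approx(-2 * -100.0 + 2 * 11)

    def test_parsimony_tiebreak(self):
        two = self._stub(-500.0, 2)
        three = self._stub(-500.0, 3)
        assert select_states([three, two]).params.n_states == 2

    def test_extra_inert_parameter_costs_two(self):
        base = self._stub(-500.0, 2, n_cov=1)
        wider = self._stub(-500.0, 2, n_cov=2)
        assert wider.aic - base.aic == pytest.approx(2.0 * 2)  # 2 pairs x 1 col

    def test_separated_three_state_data_prefers_three_states(self, short_series):
        fits = [
            MovementHMM(short_series, n_states=K,
                        transition_covariate="none").fit(n_starts=4, seed=9)
            for K in (2, 3)
        ]
        assert fits[1].aic < fits[0].aic
        assert select_states(fits).params.n_states == 3
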