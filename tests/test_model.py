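import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from alcmeta.gammadist import interval_log_probability
from alcmeta.model import (R_SHAPE, RS_SHAPE, Model, ModelConfig, ModelInputs,
                           ModelParameters, apc_constraint_logdensity,
                           apc_litres_to_grams_per_day, consumption_loglik,
                           joint_logposterior, prevalence_loglik,
                           shape_prior_logdensity, softcap_logdensity)

from conftest import SMALL_MODEL_CONFIG


def _tiny_inputs(w=0.2):
    """A printed-in-test fixture: 2 surveys x 2 cells x 3 intervals."""
    years = np.array([2000, 2001, 2002])
    ages = np.array([25.0, 50.0])
    cons = pd.DataFrame([
        # survey A (year 2000), male, age 1: three intervals
        ("A", 1, 1, 1, 0.0, 5.0, 0.5, 120.0),
        ("A", 1, 1, 2, 5.0, 20.0, 0.3, 120.0),
        ("A", 1, 1, 3, 20.0, np.inf, 0.2, 120.0),
        # survey A, female, age 2
        ("A", 2, 2, 1, 0.0, 3.0, 0.6, 80.0),
        ("A", 2, 2, 2, 3.0, 12.0, 0.3, 80.0),
        ("A", 2, 2, 3, 12.0, np.inf, 0.1, 80.0),
        # survey B (year 2002), male, age 1: includes a degenerate point
        ("B", 1, 1, 1, 0.0, 10.0, 0.7, 150.0),
        ("B", 1, 1, 2, 12.0, 12.0, 0.2, 150.0),
        ("B", 1, 1, 3, 24.0, np.inf, 0.1, 150.0),
        # survey B, female, age 1
        ("B", 2, 1, 1, 0.0, 6.0, 0.8, 90.0),
        ("B", 2, 1, 2, 6.0, 18.0, 0.15, 90.0),
        ("B", 2, 1, 3, 18.0, np.inf, 0.05, 90.0),
    ], columns=["survey_id", "sex", "age_group", "k", "lc", "uc", "pc", "ne"])
    prev = pd.DataFrame([
        ("A", 1, 1, 0.52, 0.02), ("A", 2, 2, 0.18, 0.015),
        ("B", 1, 1, 0.49, 0.025), ("B", 2, 1, 0.21, 0.02),
    ], columns=["survey_id", "sex", "age_group", "pp", "pse"])
    pop = np.tile(np.array([[0.3, 0.2], [0.28, 0.22]])[:, None, :], (1, 3, 1))
    return ModelInputs(
        years=years, ages=ages, prevalence=prev, consumption=cons,
        pop=pop, apc=np.array([6.0, 5.8, 5.6]),
        apcse=np.array([0.3, 0.3, 0.3]),
        survey_year={"A": 2000, "B": 2002},
    )


@pytest.fixture(scope="module")
def tiny_model():
    return Model(_tiny_inputs(), ModelConfig(dc1=2, dc2=2, dp1=2, dp2=2))


@pytest.fixture(scope="module")
def tiny_params(tiny_model):
    rng = np.random.default_rng(10)
    theta = tiny_model.initial_point(rng)
    return theta, tiny_model.unpack(theta)


class TestComponents:
    def test_unbounded_tuple_contributes_nothing(self):
        inp = _tiny_inputs()
        cons = pd.DataFrame([("A", 1, 1, 1, 0.0, np.inf, 1.0, 100.0)],
                            columns=["survey_id", "sex", "age_group", "k",
                                     "lc", "uc", "pc", "ne"])
        inp2 = ModelInputs(years=inp.years, ages=inp.ages,
                           prevalence=inp.prevalence, consumption=cons,
                           pop=inp.pop, apc=inp.apc, apcse=inp.apcse,
                           survey_year=inp.survey_year)
        m = Model(inp2, ModelConfig(dc1=2, dc2=2, dp1=2, dp2=2))
        params = m.unpack(m.initial_point(np.random.default_rng(0)))
        assert consumption_loglik(m, params) == pytest.approx(0.0, abs=1e-12)

    def test_consumption_matches_hand_sum(self, tiny_model, tiny_params):
        _, params = tiny_params
        m = tiny_model
        inp = m.inputs
        yr_index = {2000: 0, 2001: 1, 2002: 2}
        sid_index = {s: i for i, s in enumerate(inp.survey_ids)}
        mu = np.exp(np.einsum("yi,gij,aj->gya", m._By_c, params.sC, m._Ba_c))
        total = 0.0
        for r in inp.consumption.itertuples(index=False):
            g, a = r.sex - 1, r.age_group - 1
            y = yr_index[inp.survey_year[r.survey_id]]
            alpha = params.alpha[g, y, a]
            beta = alpha / mu[g, y, a]
            c = params.cprime[sid_index[r.survey_id]] * params.cdev[g, a]
            total += r.ne * r.pc * interval_log_probability(
                r.lc, r.uc, (alpha, beta), c)
        assert consumption_loglik(m, params) == pytest.approx(total, abs=1e-10)

    def test_degenerate_tuple_is_log_density(self, tiny_model, tiny_params):
        _, params = tiny_params
        m = tiny_model
        # the single degenerate tuple (survey B, male, x = 12)
        mu = np.exp(np.einsum("yi,gij,aj->gya", m._By_c, params.sC, m._Ba_c))
        alpha = params.alpha[0, 2, 0]
        beta = alpha / mu[0, 2, 0]
        c = params.cprime[m.inputs.survey_ids.index("B")] * params.cdev[0, 0]
        direct = stats.gamma.logpdf(12.0, a=alpha, scale=c / beta)
        assert interval_log_probability(12.0, 12.0, (alpha, beta), c) == \
            pytest.approx(direct, rel=1e-12)

    def test_prevalence_matches_normal_oracle(self, tiny_model, tiny_params):
        _, params = tiny_params
        m = tiny_model
        p = 1 / (1 + np.exp(-np.einsum("yi,gij,aj->gya", m._By_p, params.sP,
                                       m._Ba_p)))
        yr_index = {2000: 0, 2001: 1, 2002: 2}
        total = 0.0
        for r in m.inputs.prevalence.itertuples(index=False):
            y = yr_index[m.inputs.survey_year[r.survey_id]]
            total += stats.norm.logpdf(r.pp, p[r.sex - 1, y, r.age_group - 1],
                                       r.pse)
        assert prevalence_loglik(m, params) == pytest.approx(total, abs=1e-10)

    def test_prevalence_maximised_when_exact(self, tiny_model, tiny_params):
        _, params = tiny_params
        m = tiny_model
        best = sum(-math.log(pse * math.sqrt(2 * math.pi))
                   for pse in m.inputs.prevalence.pse)
        assert prevalence_loglik(m, params) <= best + 1e-12

    def test_apc_wastage_shift(self, tiny_model, tiny_params):
        _, params = tiny_params
        inp = _tiny_inputs()
        m0 = Model(inp, ModelConfig(w=0.0, dc1=2, dc2=2, dp1=2, dp2=2))
        m2 = Model(inp, ModelConfig(w=0.2, dc1=2, dc2=2, dp1=2, dp2=2))
        # identical parameters, only the normal mean (1-w) apc moves
        mu = np.exp(np.einsum("yi,gij,aj->gya", m0._By_c, params.sC, m0._Ba_c))
        p = 1 / (1 + np.exp(-np.einsum("yi,gij,aj->gya", m0._By_p, params.sP,
                                       m0._Ba_p)))
        T = np.einsum("gya,gya->y", mu * p, inp.pop)
        expected_diff = sum(
            stats.norm.logpdf(t, 0.8 * a, s) - stats.norm.logpdf(t, a, s)
            for t, a, s in zip(T, inp.apc, inp.apcse))
        diff = (apc_constraint_logdensity(m2, params)
                - apc_constraint_logdensity(m0, params))
        assert diff == pytest.approx(expected_diff, abs=1e-10)

    def test_apc_toy_total(self, tiny_model):
        # 3-cell toy: hand-computed population total
        mu = np.array([10.0, 40.0, 25.0])
        p = np.array([0.2, 0.5, 0.3])
        pop = np.array([0.5, 0.3, 0.2])
        assert np.dot(mu * p, pop) == pytest.approx(1.0 + 6.0 + 1.5)

    def test_shape_prior_constants(self):
        assert round(R_SHAPE[0], 2) == 0.73
        assert round(R_SHAPE[1], 2) == 0.63
        assert RS_SHAPE == (0.028, 0.036)

    def test_shape_prior_maximised_at_location(self, tiny_model, tiny_params):
        _, params = tiny_params
        at_loc = ModelParameters(
            sC=params.sC, sP=params.sP, cprime=params.cprime,
            cdev=params.cdev,
            alpha=np.broadcast_to(np.array(R_SHAPE)[:, None, None],
                                  params.alpha.shape).copy())
        perturbed = ModelParameters(
            sC=params.sC, sP=params.sP, cprime=params.cprime,
            cdev=params.cdev, alpha=at_loc.alpha * 1.1)
        assert shape_prior_logdensity(tiny_model, at_loc) > \
            shape_prior_logdensity(tiny_model, perturbed)

    def test_softcap_inactive_below_cap(self, tiny_model, tiny_params):
        _, params = tiny_params
        small = ModelParameters(
            sC=np.full_like(params.sC, 0.0), sP=params.sP,
            cprime=params.cprime, cdev=params.cdev, alpha=params.alpha)
        small.sC[:, 0, 0] = np.log(10.0)  # q95 well under 150 g/day
        assert softcap_logdensity(tiny_model, small) == pytest.approx(0.0)

    def test_softcap_monotone_and_closed_form(self, tiny_model, tiny_params):
        _, params = tiny_params
        cfg = tiny_model.config

        def cap_pen(mu_const):
            p2 = ModelParameters(
                sC=np.zeros_like(params.sC), sP=params.sP,
                cprime=params.cprime, cdev=params.cdev, alpha=params.alpha)
            p2.sC[:, 0, 0] = np.log(mu_const)
            return softcap_logdensity(tiny_model, p2)

        pens = [cap_pen(m) for m in (50.0, 70.0, 90.0)]
        assert pens[0] >= pens[1] >= pens[2]
        # at q95 = cap + 2 * scale the one-sided normal form gives -2
        alpha0 = params.alpha[0, 0, 0]
        from scipy.special import gammaincinv
        ratio = gammaincinv(alpha0, 0.95) / alpha0  # q95 / mu
        mu_target = (cfg.cap + 2 * cfg.cap_scale) / ratio
        p2 = ModelParameters(
            sC=np.zeros_like(params.sC), sP=params.sP, cprime=params.cprime,
            cdev=params.cdev,
            alpha=np.full_like(params.alpha, alpha0))
        p2.sC[:, 0, 0] = np.log(mu_target)
        n_cells = params.alpha.size
        assert softcap_logdensity(tiny_model, p2) == pytest.approx(
            -0.5 * 2.0**2 * n_cells, rel=1e-6)


class TestJointPosterior:
    def test_additivity(self, tiny_model, tiny_params):
        theta, params = tiny_params
        ll, _ = tiny_model.logpost_and_grad(theta)
        assert joint_logposterior(tiny_model, params) == pytest.approx(
            ll, abs=1e-9)

    def test_tuple_order_invariance(self, tiny_params):
        theta, _ = tiny_params
        inp = _tiny_inputs()
        shuffled = ModelInputs(
            years=inp.years, ages=inp.ages, prevalence=inp.prevalence,
            consumption=inp.consumption.sample(frac=1, random_state=4),
            pop=inp.pop, apc=inp.apc, apcse=inp.apcse,
            survey_year=inp.survey_year)
        m1 = Model(_tiny_inputs(), ModelConfig(dc1=2, dc2=2, dp1=2, dp2=2))
        m2 = Model(shuffled, ModelConfig(dc1=2, dc2=2, dp1=2, dp2=2))
        assert m1.logpost(theta) == pytest.approx(m2.logpost(theta), abs=1e-9)

    def test_gradient_matches_finite_differences(self, tiny_model, tiny_params):
        theta, _ = tiny_params
        _, grad = tiny_model.logpost_and_grad(theta)
        rng = np.random.default_rng(2)
        idx = rng.choice(tiny_model.n_params, 25, replace=False)
        for i in idx:
            e = np.zeros_like(theta)
            e[i] = 1e-5
            num = (tiny_model.logpost(theta + e)
                   - tiny_model.logpost(theta - e)) / 2e-5
            assert grad[i] == pytest.approx(num, rel=1e-5, abs=1e-7)

    def test_finite_at_random_valid_points(self, tiny_model):
        rng = np.random.default_rng(6)
        for _ in range(50):
            theta = tiny_model.initial_point(rng, jitter=0.3)
            ll, grad = tiny_model.logpost_and_grad(theta)
            assert np.isfinite(ll)
            assert np.all(np.isfinite(grad))

    def test_coverage_normalisation_breaks_rescaling_invariance(
            self, tiny_model, tiny_params):
        # multiplying c' by a factor and dividing c'' by it leaves every
        # likelihood term unchanged, so only the c'' normalisation (and its
        # prior) can pin the decomposition: the joint must change
        theta, params = tiny_params
        lam = 1.1
        rescaled = ModelParameters(
            sC=params.sC, sP=params.sP,
            cprime=np.clip(params.cprime * lam, 1e-6, 1 - 1e-9),
            cdev=params.cdev / lam, alpha=params.alpha)
        base = consumption_loglik(tiny_model, params)
        resc = consumption_loglik(tiny_model, rescaled)
        assert base == pytest.approx(resc, abs=1e-8)  # likelihood is flat...
        with pytest.raises(ValueError, match="geometric mean"):
            tiny_model.pack(rescaled)  # ...but the constraint rejects it

    def test_nonfinite_component_is_named(self, tiny_model, tiny_params):
        _, params = tiny_params
        bad = ModelParameters(sC=params.sC.copy(), sP=params.sP,
                              cprime=params.cprime, cdev=params.cdev,
                              alpha=params.alpha)
        bad.sC[0, 0, 0] = 500.0  # exp overflow in mu
        with pytest.raises(ValueError, match="component"):
            joint_logposterior(tiny_model, bad)


class TestLikelihoodConsistency:
    def test_mle_recovers_gamma_parameters(self):
        # with coverage 1 and a single cell, maximising the weighted
        # interval-censored likelihood over (mu, sd) recovers the truth
        rng = np.random.default_rng(123)
        mu_true, alpha_true = 30.0, 0.73
        n = 10_000
        x = rng.gamma(alpha_true, mu_true / alpha_true, size=n)
        edges = np.array([0, 2, 5, 10, 20, 40, 80, np.inf])
        counts, _ = np.histogram(x, bins=edges)
        pc = counts / n

        def nll(z):
            log_mu, log_alpha = z
            alpha = np.exp(log_alpha)
            beta = alpha / np.exp(log_mu)
            lp = interval_log_probability(edges[:-1], edges[1:],
                                          (alpha, beta))
            return -n * float((pc * lp).sum())

        res = optimize.minimize(nll, [np.log(20.0), 0.0], method="Nelder-Mead")
        mu_hat = math.exp(res.x[0])
        alpha_hat = math.exp(res.x[1])
        assert mu_hat == pytest.approx(mu_true, rel=0.05)
        assert alpha_hat == pytest.approx(alpha_true, rel=0.05)


def test_apc_unit_conversion():
    # 1 litre of ethanol per year is 789.24 g spread over 365.25 days
    assert apc_litres_to_grams_per_day(1.0) == pytest.approx(789.24 / 365.25)
    assert apc_litres_to_grams_per_day(10.0) == pytest.approx(21.608, abs=1e-3)


def test_input_validation():
    inp = _tiny_inputs()
    with pytest.raises(ValueError, match="sum to 1"):
        ModelInputs(years=inp.years, ages=inp.ages, prevalence=inp.prevalence,
                    consumption=inp.consumption, pop=inp.pop * 0.5,
                    apc=inp.apc, apcse=inp.apcse, survey_year=inp.survey_year)
    with pytest.raises(ValueError, match="outside"):
        ModelInputs(years=inp.years, ages=inp.ages, prevalence=inp.prevalence,
                    consumption=inp.consumption, pop=inp.pop, apc=inp.apc,
                    apcse=inp.apcse, survey_year={"A": 1990, "B": 2002})
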