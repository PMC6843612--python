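import math

import numpy as np
import pytest
from scipy import optimize

import hazglm as hg
from hazglm.glm_core import (
    DesignSpec,
    FamilySpec,
    binomial_loglik,
    fit_binomial_glm,
    fit_parametric_hazard,
    poisson_loglik,
    standard_spec,
)
from hazglm.synthetic import Scenario, simulate_tte


class TestLogLikelihoods:
    def test_poisson_worked_values(self):
        assert poisson_loglik([0], [0.01], [100]) == pytest.approx(-1.0)
        assert poisson_loglik([1], [0.01], [100]) == pytest.approx(-1.0)

    def test_poisson_matches_termwise_sum(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(3, 20)
        lam = rng.uniform(0.01, 0.2, 20)
        tau = rng.uniform(10, 200, 20)
        brute = sum(
            yi * math.log(li * ti) - li * ti - math.log(math.factorial(yi))
            for yi, li, ti in zip(y, lam, tau)
        )
        assert poisson_loglik(y, lam, tau) == pytest.approx(brute, rel=1e-12)

    def test_poisson_domain_error(self):
        with pytest.raises(ValueError):
            poisson_loglik([1], [0.0], [100])

    def test_binomial_closed_form(self):
        # y=1, n=2, pi=0.5: 2 * 0.5 * 0.5 -> log(0.5)
        assert binomial_loglik([1], [0.5], [2]) == pytest.approx(math.log(0.5))

    def test_binomial_matches_brute_force(self):
        rng = np.random.default_rng(6)
        n = rng.integers(2, 40, 15)
        y = rng.integers(0, n)
        pi = rng.uniform(0.05, 0.95, 15)
        brute = sum(
            yi * math.log(pii / (1 - pii))
            + ni * math.log(1 - pii)
            + math.log(math.comb(int(ni), int(yi)))
            for yi, pii, ni in zip(y, pi, n)
        )
        assert binomial_loglik(y, pi, n) == pytest.approx(brute, rel=1e-12)

    def test_binomial_boundary_limit(self):
        # y = n with pi -> 1: log-likelihood approaches 0 from below
        vals = [binomial_loglik([3], [p], [3]) for p in (0.9, 0.99, 0.999)]
        assert all(v < 0 for v in vals)
        assert vals == sorted(vals)


class TestStandardSpecs:
    @pytest.mark.parametrize(
        "name,dist,resp,transform",
        [
            ("exponential", "poisson", "exponential", "none"),
            ("gompertz", "poisson", "exponential", "t"),
            ("weibull", "poisson", "exponential", "log_t"),
            ("log-logistic", "binomial", "logistic", "log_t"),
            ("lognormal", "binomial", "inverse-probit", "log_t"),
        ],
    )
    def test_model_mapping(self, name, dist, resp, transform):
        family, design = standard_spec(name)
        assert (family.distribution, family.response, design.transform) == (dist, resp, transform)

    def test_unknown_name_lists_valid(self):
        with pytest.raises(KeyError, match="weibull"):
            standard_spec("cauchy")


class TestPoissonGLMFit:
    def test_intercept_only_closed_form(self, gbsg_lifetable):
        """Constant-rate MLE is total events over total exposure, exactly."""
        lt = gbsg_lifetable
        family, design = standard_spec("exponential")
        m = hg.fit_glm(lt, family, design)
        assert np.exp(m.beta[0]) == pytest.approx(lt.events.sum() / lt.at_risk.sum(), abs=1e-10)
        # score equation: fitted total events reproduce observed total
        assert np.sum(m.predict(lt.midpoints) * lt.at_risk) == pytest.approx(
            lt.events.sum(), rel=1e-8
        )

    def test_fit_agrees_with_direct_likelihood_maximization(self, gbsg_lifetable):
        """IRLS solution matches brute-force maximization of the written likelihood."""
        lt = gbsg_lifetable
        family, design = standard_spec("weibull")
        m = hg.fit_glm(lt, family, design)
        keep = lt.at_risk > 0
        y, tau, mid = lt.events[keep], lt.at_risk[keep], lt.midpoints[keep]
        X = design.matrix(mid)

        def negll(beta):
            return -poisson_loglik(y, np.exp(X @ beta), tau)

        res = optimize.minimize(negll, m.beta + 0.5, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 5000})
        assert m.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_nesting_never_decreases_loglik(self, gbsg_lifetable):
        fam = FamilySpec("poisson", "exponential")
        null = hg.fit_glm(gbsg_lifetable, fam, DesignSpec("none"))
        for transform in ("t", "log_t"):
            bigger = hg.fit_glm(gbsg_lifetable, fam, DesignSpec(transform))
            assert bigger.loglik >= null.loglik - 1e-9

    def test_aic_identity(self, gbsg_lifetable):
        family, design = standard_spec("weibull")
        m = hg.fit_glm(gbsg_lifetable, family, design)
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * m.k)
        assert hg.aic(-100.0, 2) == 204.0
        assert hg.aic(0.0, 0) == 0.0

    def test_weibull_slope_recovers_shape(self):
        """Weibull log hazard is linear in log t with slope shape - 1."""
        shape = 1.4
        recs = simulate_tte(
            Scenario("weibull", {"shape": shape, "scale": 3.0}, n=10_000, admin_censor=6.0),
            seed=11,
        )
        lt = hg.build_lifetable(recs)
        family, design = standard_spec("weibull")
        m = hg.fit_glm(lt, family, design)
        assert m.beta[1] == pytest.approx(shape - 1, abs=3 * m.extra["beta_se"][1])

    def test_rank_deficient_design_rejected(self, gbsg_lifetable):
        bad = DesignSpec("basis", basis=lambda t: np.column_stack([t, 2 * t]))
        with pytest.raises(np.linalg.LinAlgError):
            hg.fit_glm(gbsg_lifetable, FamilySpec("poisson", "exponential"), bad)


class TestPredictHazard:
    def test_exponential_constant(self, gbsg_lifetable):
        family, design = standard_spec("exponential")
        m = hg.fit_glm(gbsg_lifetable, family, design)
        vals = hg.predict_hazard(m, [0.5, 1.0, 5.0])
        assert np.ptp(vals) == 0.0

    def test_gompertz_log_linear_in_time(self, gbsg_lifetable):
        family, design = standard_spec("gompertz")
        m = hg.fit_glm(gbsg_lifetable, family, design)
        t = np.linspace(0.5, 6.0, 30)
        second_diff = np.diff(np.log(hg.predict_hazard(m, t)), 2)
        assert np.max(np.abs(second_diff)) < 1e-10

    def test_log_time_design_rejects_zero(self, gbsg_lifetable):
        family, design = standard_spec("weibull")
        m = hg.fit_glm(gbsg_lifetable, family, design)
        with pytest.raises(ValueError):
            hg.predict_hazard(m, [0.0, 1.0])


class TestBinomialPathway:
    def test_cumulative_models_fit(self, gbsg_lifetable):
        for name in ("log-logistic", "lognormal"):
            family, design = standard_spec(name)
            m = fit_binomial_glm(gbsg_lifetable, family, design, name=name)
            assert np.isfinite(m.loglik)
            lam = m.predict(gbsg_lifetable.midpoints)
            assert np.all((lam >= 0) & (lam <= 1))

    def test_binomial_fit_matches_direct_maximization(self, gbsg_lifetable):
        from hazglm.glm_core import _cumulative_data

        family, design = standard_spec("log-logistic")
        m = fit_binomial_glm(gbsg_lifetable, family, design)
        y, n, mid = _cumulative_data(gbsg_lifetable)
        X = design.matrix(mid)

        def negll(beta):
            return -binomial_loglik(y, np.clip(family.h(X @ beta), 1e-12, 1 - 1e-12), n)

        res = optimize.minimize(negll, m.beta, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-12})
        assert m.loglik == pytest.approx(-res.fun, abs=1e-4)


class TestParametricHazards:
    def test_gengamma_pinned_to_weibull_matches_glm(self, gbsg_lifetable):
        """Generalized gamma with its extra shape fixed reduces to Weibull."""
        family, design = standard_spec("weibull")
        w = hg.fit_glm(gbsg_lifetable, family, design)
        gg = fit_parametric_hazard(gbsg_lifetable, "generalized-gamma", fixed={0: 0.0})
        assert gg.loglik == pytest.approx(w.loglik, abs=1e-3)

    def test_generalized_f_nests_generalized_gamma(self, gbsg_lifetable):
        gg = fit_parametric_hazard(gbsg_lifetable, "generalized-gamma")
        gf = fit_parametric_hazard(gbsg_lifetable, "generalized-F")
        assert gf.loglik >= gg.loglik - 0.05
        assert gf.k == 4 and gg.k == 3

    def test_lognormal_parameter_recovery(self):
        recs = simulate_tte(
            Scenario("lognormal", {"mu": 1.2, "sigma": 0.8}, n=10_000, admin_censor=8.0),
            seed=21,
        )
        lt = hg.build_lifetable(recs)
        m = fit_parametric_hazard(lt, "lognormal-hazard")
        mu_hat, sigma_hat = m.beta[0], math.exp(m.beta[1])
        assert mu_hat == pytest.approx(1.2, abs=0.05)
        assert sigma_hat == pytest.approx(0.8, abs=0.05)

    def test_unknown_family(self, gbsg_lifetable):
        with pytest.raises(KeyError):
            fit_parametric_hazard(gbsg_lifetable, "pareto")
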