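import numpy as np
import pytest

import hazglm as hg
from hazglm.flexible import (
    FP_POWERS,
    _bspline_design,
    _penalized_poisson,
    _second_derivative_penalty,
    event_time_knots,
    fit_fp,
    fp_design,
    rcs_basis,
)
from hazglm.glm_core import DesignSpec, FamilySpec
from hazglm.synthetic import Scenario, simulate_tte


class TestFPDesign:
    def test_power_conventions(self):
        t = np.array([1.0, 2.0])
        assert np.allclose(fp_design(t, (1.0,))[:, 0], t)
        assert fp_design(np.array([np.e]), (0.0,))[0, 0] == pytest.approx(1.0)
        rep = fp_design(np.array([2.0, 3.0]), (2.0, 2.0))
        assert np.allclose(rep[:, 0], [4.0, 9.0])
        assert np.allclose(rep[:, 1], [4.0 * np.log(2.0), 9.0 * np.log(3.0)])

    def test_domain_and_power_set_guards(self):
        with pytest.raises(ValueError):
            fp_design(np.array([0.0, 1.0]), (1.0,))
        with pytest.raises(ValueError):
            fp_design(np.array([1.0]), (1.5,))

    def test_fp_power_one_is_gompertz_and_log_is_weibull(self, gbsg_lifetable):
        """FP designs reproduce the standard GLMs they nest, to 1e-8."""
        fam = FamilySpec("poisson", "exponential")
        gom = hg.fit_glm(gbsg_lifetable, fam, DesignSpec("t"))
        assert fit_fp(gbsg_lifetable, (1.0,)).loglik == pytest.approx(gom.loglik, abs=1e-8)
        wei = hg.fit_glm(gbsg_lifetable, fam, DesignSpec("log_t"))
        assert fit_fp(gbsg_lifetable, (0.0,)).loglik == pytest.approx(wei.loglik, abs=1e-8)


class TestClosedTest:
    def test_constant_hazard_retains_simple_model(self):
        """Under a flat hazard the closed test usually stops at the null stage."""
        stops = 0
        for seed in range(30):
            recs = simulate_tte(
                Scenario("constant", {"rate": 0.15}, n=686, admin_censor=7.0), seed=200 + seed
            )
            fp = hg.select_fp(hg.build_lifetable(recs))
            stops += fp.extra["closed_test_stage"] in ("null", "linear")
        assert stops >= 26  # ~alpha-level escape rate

    def test_weibull_hazard_recovered(self):
        shape, scale = 1.6, 3.0
        recs = simulate_tte(
            Scenario("weibull", {"shape": shape, "scale": scale}, n=20_000, admin_censor=6.0),
            seed=31,
        )
        lt = hg.build_lifetable(recs)
        chosen = hg.select_fp(lt)
        t = np.linspace(0.5, 5.0, 40)
        truth = (shape / scale) * (t / scale) ** (shape - 1) * lt.width
        assert np.allclose(chosen.predict(t), truth, rtol=0.15)

    def test_fp2_has_three_coefficients(self, gbsg_lifetable):
        m = fit_fp(gbsg_lifetable, (-0.5, 3.0))
        assert m.k == 3  # intercept + two power terms


class TestRCS:
    def test_single_knot_at_median(self, gbsg_records):
        ev = sorted(r.time for r in gbsg_records if r.event == 1)
        knots = event_time_knots(gbsg_records, 1)
        assert knots[1] == pytest.approx(np.percentile(ev, 50))
        assert knots[0] == min(ev) and knots[-1] == max(ev)

    def test_three_knots_at_quartiles(self, gbsg_records):
        ev = [r.time for r in gbsg_records if r.event == 1]
        knots = event_time_knots(gbsg_records, 3)
        assert np.allclose(knots[1:-1], np.percentile(ev, [25, 50, 75]))

    def test_too_few_event_times_rejected(self):
        recs = [hg.SubjectRecord(1.0, 1), hg.SubjectRecord(2.0, 0)]
        with pytest.raises(ValueError):
            event_time_knots(recs, 2)

    def test_basis_linear_beyond_boundary_knots(self):
        knots = np.array([0.5, 1.2, 2.5, 4.0])
        h = 1e-3
        for x0 in (0.05, 0.3, 4.5, 6.0):
            pts = np.array([x0 - h, x0, x0 + h])
            B = rcs_basis(pts, knots)
            d2 = B[0] - 2 * B[1] + B[2]
            assert np.max(np.abs(d2)) < 1e-6 * max(1.0, np.max(np.abs(B)))

    def test_basis_dimension(self):
        knots = np.linspace(0.5, 4.0, 5)  # 3 internal + 2 boundary
        B = rcs_basis(np.linspace(0.1, 5, 20), knots)
        assert B.shape[1] == 4  # n_internal + 1 columns (plus the model intercept)

    def test_constant_hazard_gives_flat_selected_fit(self, constant_lifetable):
        recs = simulate_tte(Scenario("constant", {"rate": 0.2}, n=4000, admin_censor=6.0), seed=3)
        m = hg.select_rcs(constant_lifetable, recs)
        lam = m.predict(np.linspace(0.5, 5.0, 50))
        assert np.ptp(np.log(lam)) < 0.35  # near-flat on the observed range

    def test_case_style_selection_has_recorded_knots(self, gbsg_lifetable, gbsg_records):
        m = hg.select_rcs(gbsg_lifetable, gbsg_records)
        assert "knots" in m.extra and len(m.extra["knots"]) >= 3
        assert m.aic <= fit_fp(gbsg_lifetable, (1.0,)).aic + 50  # sanity: comparable scale


class TestGAM:
    def test_zero_penalty_matches_unpenalized_glm(self, gbsg_lifetable):
        import statsmodels.api as sm

        lt = gbsg_lifetable
        keep = lt.at_risk > 0
        y, tau, mid = lt.events[keep], lt.at_risk[keep], lt.midpoints[keep]
        g0 = hg.fit_gam(lt, q=8, penalty=0.0)
        B, _ = _bspline_design(mid, 8, mid.min(), mid.max())
        res = sm.GLM(y, B, family=sm.families.Poisson(), offset=np.log(tau)).fit()
        assert g0.loglik == pytest.approx(res.llf, abs=1e-6)
        assert g0.k == pytest.approx(8.0, abs=1e-6)

    def test_infinite_penalty_matches_linear_log_hazard_glm(self, gbsg_lifetable):
        """The penalty null space is a straight line in log hazard."""
        gom = hg.fit_glm(
            gbsg_lifetable, FamilySpec("poisson", "exponential"), DesignSpec("t")
        )
        big = hg.fit_gam(gbsg_lifetable, q=11, penalty=1e9)
        assert big.loglik == pytest.approx(gom.loglik, abs=1e-4)
        assert big.k == pytest.approx(2.0, abs=1e-4)

    def test_edf_monotone_in_penalty(self, gbsg_lifetable):
        lt = gbsg_lifetable
        keep = lt.at_risk > 0
        y, tau, mid = lt.events[keep], lt.at_risk[keep], lt.midpoints[keep]
        B, knots = _bspline_design(mid, 9, mid.min(), mid.max())
        S = _second_derivative_penalty(knots, 9, mid.min(), mid.max())
        edfs = [_penalized_poisson(y, tau, B, S, rho)[2] for rho in 10.0 ** np.arange(-3, 7)]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))
        assert all(2.0 - 1e-6 <= e <= 9.0 + 1e-9 for e in edfs)

    def test_selected_fit_reports_fractional_edf(self, gbsg_lifetable):
        m = hg.fit_gam(gbsg_lifetable, q=11)
        assert 1.0 <= m.k <= 11.0
        assert m.gam.penalty >= 0
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * m.k)

    def test_invalid_arguments(self, gbsg_lifetable):
        with pytest.raises(ValueError):
            hg.fit_gam(gbsg_lifetable, q=2)
        with pytest.raises(ValueError):
            hg.fit_gam(gbsg_lifetable, selection="gcv")
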