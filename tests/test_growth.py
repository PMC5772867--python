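import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from patchsde import (
    ModelError,
    TwoPatchSpec,
    equilibrium_proportion,
    fixture_spec,
    generate_fixture,
    make_two_patch,
    r_closedform_equal_sigma,
    r_large_dispersal_approx,
    r_mc_timeaverage,
    r_quadrature_2p,
    r_single_patch,
    stationary_density_2p,
    stochastic_growth_rate,
    two_patch_sigma,
)


class TestSinglePatch:
    @pytest.mark.parametrize(
        "a, s2, expected",
        [(3.0, 7.0, -0.5), (2.0, 0.0, 2.0), (3.5, 7.0, 0.0)],
    )
    def test_gbm_exponent(self, a, s2, expected):
        res = r_single_patch(a, s2)
        assert res.r == pytest.approx(expected)
        assert res.se == 0.0


class TestEquilibriumProportion:
    def test_equal_growth_rates_give_half(self):
        spec = TwoPatchSpec(a1=3.0, a2=3.0, d12=2.0, d21=2.0,
                            sigma1=1.0, sigma2=1.0, rho=1.0)
        assert equilibrium_proportion(spec) == 0.5

    def test_asymmetric_dispersal_balance(self):
        spec = TwoPatchSpec(a1=2.0, a2=2.0, d12=1.0, d21=3.0,
                            sigma1=1.0, sigma2=1.0, rho=1.0)
        assert equilibrium_proportion(spec) == pytest.approx(0.75)

    def test_matches_root_finder_oracle(self):
        spec = TwoPatchSpec(a1=3.0, a2=4.0, d12=1.0, d21=1.0,
                            sigma1=1.0, sigma2=1.0, rho=1.0)
        oracle = brentq(lambda y: -(1 - y) * y + 1 - 2 * y, 0, 1, xtol=1e-14)
        assert equilibrium_proportion(spec) == pytest.approx(oracle, abs=1e-12)
        assert equilibrium_proportion(spec) == pytest.approx((3 - math.sqrt(5)) / 2)


class TestClosedFormEqualSigma:
    def test_symmetric_dispersal_closed_form(self):
        # a1=3, a2=4, alpha=1, sigma^2=7: r = (5 + sqrt 5)/2 - 7/2
        spec = fixture_spec("two_patch_sweep", rho=1.0, alpha=1.0)
        res = r_closedform_equal_sigma(spec)
        assert res.r == pytest.approx((5 + math.sqrt(5)) / 2 - 3.5, abs=1e-12)
        assert res.diagnostics["ystar"] == pytest.approx((3 - math.sqrt(5)) / 2)

    def test_synchronized_slice_value(self):
        # on the slice 2(d21-d12) = a2-a1: r = a1 - d12 + d21 - sigma^2/2
        spec = TwoPatchSpec(a1=2.0, a2=3.0, d12=1.0, d21=1.5,
                            sigma1=2.0, sigma2=2.0, rho=1.0)
        assert r_closedform_equal_sigma(spec).r == pytest.approx(0.5, abs=1e-12)

    def test_rejects_nonzero_diffusion(self, sweep_rho0):
        with pytest.raises(ModelError):
            r_closedform_equal_sigma(sweep_rho0)

    def test_sinks_cannot_be_rescued(self):
        # equal growth rates: r = a - sigma^2/2 regardless of dispersal
        for alpha in (0.5, 2.0, 8.0):
            spec = TwoPatchSpec(a1=3.0, a2=3.0, d12=alpha, d21=alpha,
                                sigma1=math.sqrt(7), sigma2=math.sqrt(7), rho=1.0)
            assert r_closedform_equal_sigma(spec).r == pytest.approx(-0.5)


class TestLargeDispersalApprox:
    def test_printed_value(self):
        spec = fixture_spec("two_patch_sweep", rho=1.0, alpha=100.0)
        assert r_large_dispersal_approx(spec).r == pytest.approx(0.00125)

    def test_limit_is_average_patch_rate(self):
        spec = fixture_spec("two_patch_sweep", rho=1.0, alpha=1e9)
        limit = (3.0 + 4.0) / 2 - 3.5
        assert r_large_dispersal_approx(spec).r == pytest.approx(limit, abs=1e-8)

    def test_error_shrinks_at_least_quadratically(self):
        errs = []
        for alpha in (10.0, 20.0, 40.0, 80.0):
            spec = fixture_spec("two_patch_sweep", rho=1.0, alpha=alpha)
            errs.append(abs(r_large_dispersal_approx(spec).r
                            - r_closedform_equal_sigma(spec).r))
        ratios = [e1 / e2 for e1, e2 in zip(errs, errs[1:])]
        assert all(r >= 4.0 for r in ratios)


class TestStationaryDensity:
    def test_normalization(self, sweep_rho0, degenerate_unequal):
        for spec in (sweep_rho0, degenerate_unequal,
                     fixture_spec("two_patch_sweep", rho=0.5)):
            d = stationary_density_2p(spec)
            total, _ = quad(d.pdf, 0, 1, limit=200)
            assert total == pytest.approx(1.0, abs=1e-8)
            assert 0.0 <= d.m2 <= d.m1 <= 1.0

    def test_symmetric_spec_density_symmetric(self):
        spec = TwoPatchSpec(a1=2.0, a2=2.0, d12=1.0, d21=1.0,
                            sigma1=1.5, sigma2=1.5, rho=0.0)
        d = stationary_density_2p(spec)
        assert d.m1 == pytest.approx(0.5, abs=1e-9)
        ys = np.linspace(0.05, 0.45, 9)
        np.testing.assert_allclose(d.pdf(ys), d.pdf(1 - ys), rtol=1e-9)

    def test_matches_printed_independent_noise_form(self, sweep_rho0):
        # diagonal covariance: the density is C x^(b-a1)(1-x)^(-b-a2)
        # exp(-2/(s1^2+s2^2) (d21/x + d12/(1-x))) with a_i = 2 s_i^2/scale,
        # b = 2(a1-a2+d21-d12)/scale
        spec = sweep_rho0
        d = stationary_density_2p(spec)
        s1sq, s2sq = spec.sigma1**2, spec.sigma2**2
        scale = s1sq + s2sq
        al1, al2 = 2 * s1sq / scale, 2 * s2sq / scale
        be = 2 * (spec.a1 - spec.a2 + spec.d21 - spec.d12) / scale
        xs = np.linspace(0.01, 0.99, 197)
        printed = ((be - al1) * np.log(xs) + (-be - al2) * np.log(1 - xs)
                   - (2 / scale) * (spec.d21 / xs + spec.d12 / (1 - xs)))
        constructed = d.log_density_unnormalized(xs)
        diff = constructed - printed
        assert np.max(np.abs(diff - diff.mean())) <= 1e-8
        assert d.alpha1 == pytest.approx(al1)
        assert d.alpha2 == pytest.approx(al2)
        assert d.beta_exp == pytest.approx(be)

    def test_matches_rank_one_closed_form(self, degenerate_unequal):
        # perfectly correlated unequal volatilities: same family with
        # scale (s1-s2)^2 and volatility exponents 2 s_i (s_i - s_j)/scale
        spec = degenerate_unequal
        d = stationary_density_2p(spec)
        assert d.branch == "degenerate_unequal"
        s1, s2 = spec.sigma1, spec.sigma2
        scale = (s1 - s2) ** 2
        al1 = 2 * s1 / (s1 - s2)
        al2 = -2 * s2 / (s1 - s2)
        be = 2 * (spec.a1 - spec.a2 + spec.d21 - spec.d12) / scale
        xs = np.linspace(0.01, 0.99, 197)
        closed = ((be - al1) * np.log(xs) + (-be - al2) * np.log(1 - xs)
                  - (2 / scale) * (spec.d21 / xs + spec.d12 / (1 - xs)))
        constructed = d.log_density_unnormalized(xs)
        diff = constructed - closed
        assert np.max(np.abs(diff - diff.mean())) <= 1e-8
        assert d.scale == pytest.approx(scale)

    def test_point_mass_branch(self, sweep_rho1):
        d = stationary_density_2p(sweep_rho1)
        assert d.branch == "point_mass"
        assert d.ystar == pytest.approx((3 - math.sqrt(5)) / 2)
        with pytest.raises(ModelError):
            d.log_density_unnormalized(0.5)

    def test_one_way_dispersal_rejected(self):
        with pytest.raises(ModelError):
            stationary_density_2p(TwoPatchSpec(a1=1, a2=1, d12=1.0, d21=0.0))

    @pytest.mark.parametrize("a1, a2, d12, d21", [
        (3.0, 4.0, 1.0, 1.0), (4.0, 3.0, 1.0, 1.0), (1.0, 1.0, 0.5, 2.0),
    ])
    def test_drift_asymmetry_exponent_sign(self, a1, a2, d12, d21):
        # beta_exp carries the sign of a1 - a2 + d21 - d12 in every branch
        num = a1 - a2 + d21 - d12
        for rho, s1, s2 in ((0.0, 2.0, 1.0), (1.0, 2.0, 1.0)):
            spec = TwoPatchSpec(a1=a1, a2=a2, d12=d12, d21=d21,
                                sigma1=s1, sigma2=s2, rho=rho)
            d = stationary_density_2p(spec)
            assert math.copysign(1, d.beta_exp) == math.copysign(1, num)
            assert d.beta_exp == pytest.approx(2 * num / d.scale)


class TestQuadratureR:
    def test_point_mass_branch_redirects(self, sweep_rho1):
        with pytest.raises(ModelError, match="closedform"):
            r_quadrature_2p(sweep_rho1)

    def test_agrees_with_mc_independent_noise(self, sweep_rho0):
        rq = r_quadrature_2p(sweep_rho0)
        mc = r_mc_timeaverage(make_two_patch(sweep_rho0), T=200.0, burn_in=50.0,
                              replicates=8, dt=1e-3, seed=10)
        assert abs(rq.r - mc.r) <= 3 * mc.se

    def test_agrees_with_mc_rank_one_noise(self, degenerate_unequal):
        rq = r_quadrature_2p(degenerate_unequal)
        mc = r_mc_timeaverage(make_two_patch(degenerate_unequal), T=200.0,
                              burn_in=50.0, replicates=8, dt=1e-3, seed=11)
        assert abs(rq.r - mc.r) <= 3 * mc.se

    def test_symmetric_case_against_mc(self):
        spec = TwoPatchSpec(a1=2.0, a2=2.0, d12=1.0, d21=1.0,
                            sigma1=1.5, sigma2=1.5, rho=0.0)
        rq = r_quadrature_2p(spec)
        assert stationary_density_2p(spec).m1 == pytest.approx(0.5, abs=1e-9)
        mc = r_mc_timeaverage(make_two_patch(spec), T=200.0, burn_in=50.0,
                              replicates=8, dt=1e-3, seed=12)
        assert abs(rq.r - mc.r) <= 3 * mc.se + 1e-3


class TestMCTimeAverage:
    def test_constant_integrand_is_exact(self):
        # equal growth, fully synchronized equal noise: f = a - sigma^2/2
        # at every simplex point
        spec = TwoPatchSpec(a1=2.0, a2=2.0, d12=1.0, d21=1.0,
                            sigma1=2.0, sigma2=2.0, rho=1.0)
        res = r_mc_timeaverage(make_two_patch(spec), T=5.0, burn_in=1.0,
                               replicates=4, dt=1e-3, seed=0)
        assert res.r == pytest.approx(2.0 - 2.0, abs=1e-12)
        assert res.se <= 1e-12

    def test_zero_rates_zero_noise(self):
        m = generate_fixture("symmetric_n", n=3, a=0.0, sigma_sq=0.0)
        # zero Gamma makes Sigma singular by construction; integrand is 0
        m.Gamma = np.zeros((1, 3))
        m.Sigma = np.zeros((3, 3))
        res = r_mc_timeaverage(m, T=2.0, burn_in=0.5, replicates=2, dt=1e-2, seed=0)
        assert res.r == 0.0

    def test_replicate_guard(self, sweep_model):
        with pytest.raises(ModelError):
            r_mc_timeaverage(sweep_model, replicates=1)


class TestDispatch:
    def test_single_patch_route(self):
        m = generate_fixture("single_patch", a=3.0, sigma_sq=7.0)
        res = stochastic_growth_rate(m)
        assert res.method == "single_patch"
        assert res.r == pytest.approx(-0.5)

    def test_three_patch_routes_to_mc(self):
        m = generate_fixture("symmetric_n", n=3)
        res = stochastic_growth_rate(m, T=5.0, burn_in=1.0, replicates=2,
                                     dt=1e-2, seed=0)
        assert res.method == "mc_timeaverage"

    def test_zero_diffusion_routes_to_closed_form(self, sweep_rho1):
        assert stochastic_growth_rate(sweep_rho1).method == "closedform_equal_sigma"

    def test_generic_two_patch_routes_to_quadrature(self, sweep_rho0):
        assert stochastic_growth_rate(sweep_rho0).method == "quadrature_2p"

    def test_inapplicable_method_names_valid_set(self):
        m = generate_fixture("symmetric_n", n=3)
        with pytest.raises(ModelError, match="mc_timeaverage"):
            stochastic_growth_rate(m, method="quadrature_2p")


class TestParameterDependence:
    def test_r_decreasing_in_dispersal_fully_correlated(self):
        # perfect spatial correlation: mixing reduces growth
        rs = [r_closedform_equal_sigma(fixture_spec("two_patch_sweep", rho=1.0, alpha=al)).r
              for al in (0.5, 1, 2, 4, 8, 16)]
        assert all(b < a for a, b in zip(rs, rs[1:]))

    def test_continuity_in_coefficients(self, sweep_rho0):
        base = r_quadrature_2p(sweep_rho0).r
        gaps = []
        for delta in (0.1, 0.01, 0.001):
            spec = TwoPatchSpec(
                a1=sweep_rho0.a1 + delta, a2=sweep_rho0.a2,
                d12=sweep_rho0.d12 + delta, d21=sweep_rho0.d21,
                sigma1=sweep_rho0.sigma1, sigma2=sweep_rho0.sigma2, rho=0.0,
            )
            gaps.append(abs(r_quadrature_2p(spec).r - base))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] <= 0.01
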