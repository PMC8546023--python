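"""Analytic layer: scaling-function transform, aging-WK quadrature,
CTRW closed forms, exponent algebra, and regime classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subfbm import (AsymptoticConstants, DivergentTailError, ScalingFunction,
                    aging_wk_psd, asymptotic_psd, classify_regime,
                    ctrw_phi_ea, ctrw_phi_ta, ctrw_psd_asymptote, ctrw_ta_acf,
                    exponents_forward, exponents_invert, phi_ta_from_phi_ea,
                    psd_msd_relation)


class TestPhiTransform:
    def test_constant_phi_ea_elementary_integral(self):
        """Constant phi_EA = K with gamma = alpha transforms to
        K (1-y)^alpha / (1+alpha): evaluating the tail integral for a
        constant integrand is elementary and reproduces the CTRW TA scaling
        function."""
        alpha, dx, t0 = 0.7, math.sqrt(0.5), 1.3
        ea = ctrw_phi_ea(alpha, dx, t0)
        ta = phi_ta_from_phi_ea(ea)
        expected = ctrw_phi_ta(alpha, dx, t0)
        y = ta.y[ta.y < 1.0]
        np.testing.assert_allclose(ta.values[: y.size], expected(y),
                                   rtol=1e-8)

    def test_zero_maps_to_zero(self):
        ea = ScalingFunction(gamma=0.5, kind="EA",
                             phi=lambda z: np.zeros_like(np.asarray(z, float)))
        ta = phi_ta_from_phi_ea(ea)
        assert np.all(ta.values == 0.0)

    def test_power_law_against_independent_quadrature(self):
        """phi_EA(z) = z^-s: the transform matches both the closed form and
        an independent high-resolution Gauss-Legendre evaluation to 1e-8."""
        s, g = 0.6, 0.5
        ea = ScalingFunction(gamma=g, kind="EA",
                             phi=lambda z: np.asarray(z, float) ** -s)
        y_grid = np.linspace(0.05, 0.95, 19)
        ta = phi_ta_from_phi_ea(ea, y_grid=y_grid)
        # closed form: integral_a^inf z^(-s-2-g) dz = a^-(1+g+s)/(1+g+s)
        a = y_grid / (1 - y_grid)
        closed = y_grid ** (1 + g) / (1 - y_grid) \
            * a ** -(1 + g + s) / (1 + g + s)
        np.testing.assert_allclose(ta.values, closed, rtol=1e-8)
        # independent brute force in the u = a/z variable, 2000-node GL rule
        nodes, weights = np.polynomial.legendre.leggauss(2000)
        u = 0.5 * (nodes + 1.0)
        brute = [(1 - y) ** g * 0.5
                 * np.sum(weights * (a_i / u) ** -s * u**g)
                 for y, a_i in zip(y_grid, a)]
        np.testing.assert_allclose(ta.values, brute, rtol=1e-6)

    def test_divergent_tail_reported(self):
        ea = ScalingFunction(gamma=0.5, kind="EA",
                             phi=lambda z: np.asarray(z, float) ** 3.0)
        with pytest.raises(DivergentTailError):
            phi_ta_from_phi_ea(ea)

    def test_kind_contract(self):
        ta = ctrw_phi_ta(0.5)
        with pytest.raises(ValueError):
            phi_ta_from_phi_ea(ta)


class TestAgingWkQuadrature:
    def test_zero_function(self):
        sf = ScalingFunction(gamma=0.3, kind="TA",
                             phi=lambda y: np.zeros_like(np.asarray(y, float)))
        spec = aging_wk_psd(sf, 100.0, k_max=8)
        assert np.all(spec.values == 0.0)

    def test_triangle_closed_form(self):
        """phi_TA = (1-y)^-1 * triangle(y): the weighted integrand is the
        tent function whose cosine-series coefficients are -2/(pi^2 k^2) for
        odd k and 0 for even k."""
        gamma, tm = 0.5, 100.0
        sf = ScalingFunction(
            gamma=gamma, kind="TA",
            phi=lambda y: (1.0 - np.abs(2.0 * np.asarray(y, float) - 1.0))
            / (1.0 - np.asarray(y, float)))
        spec = aging_wk_psd(sf, tm, k_max=9, breakpoints=[0.5])
        ks = np.arange(1, 10)
        exact = 2 * tm ** (1 + gamma) * np.where(
            ks % 2 == 1, -2.0 / (np.pi**2 * ks**2), 0.0)
        np.testing.assert_allclose(spec.values, exact,
                                   atol=1e-8 * abs(exact[0]))

    def test_ctrw_quadrature_converges_to_asymptote(self):
        """Quadrature of the aging-WK integral with the CTRW scaling
        function approaches the t_m^-(1-alpha) omega^-2 law: within 2% at
        omega t_m >= 2 pi 64, with the error decreasing over the decade."""
        alpha, dx, t0, tm = 0.7, math.sqrt(0.5), 1.0, 2**12
        spec = aging_wk_psd(ctrw_phi_ta(alpha, dx, t0), tm, k_max=256)
        asym = ctrw_psd_asymptote(alpha, dx, t0, tm, spec.omegas)
        rel = np.abs(spec.values / asym - 1.0)
        assert rel[63] < 0.02
        assert np.all(rel[63:] < 0.02)
        decade = rel[[25, 50, 100, 200]]
        assert np.all(np.diff(decade) < 0)

    def test_wrong_kind_refused(self):
        with pytest.raises(ValueError):
            aging_wk_psd(ctrw_phi_ea(0.5), 10.0, k_max=4)


class TestCtrwClosedForms:
    def test_ta_acf_endpoints(self):
        alpha, dx, t0, tm = 0.6, 1.0, 1.0, 1000.0
        est = ctrw_ta_acf(alpha, dx, t0, tm, [0.0, 999.999])
        expected0 = 2 * dx**2 * tm**alpha / (t0**alpha * math.gamma(2 + alpha))
        assert abs(est.values[0] - expected0) < 1e-12 * expected0
        assert est.values[1] < 1e-3 * expected0

    def test_ta_acf_matches_simulation(self):
        """Closed-form mean TA-ACF against a simulated CTRW ensemble, with
        the Pareto cutoff mapped to the renewal scale.  The asymptotic form
        carries a finite-measurement-time positive bias (about +10% at
        t_m = 2^12), so the comparison allows 15%."""
        from subfbm import (FbmParams, WaitingTimeModel, simulate_ensemble,
                            ta_acf)

        wt = WaitingTimeModel(0.7)
        ens = simulate_ensemble(wt, FbmParams(0.5), t_m=2**12, dt=1.0,
                                n_real=1000, seed=31)
        lags = np.array([0.0, 512.0, 2048.0])
        measured = np.mean([ta_acf(tr, lags).values for tr in ens], axis=0)
        theory = ctrw_ta_acf(0.7, math.sqrt(0.5), wt.renewal_scale,
                             ens.t_m, lags).values
        assert np.max(np.abs(measured / theory - 1.0)) < 0.15

    def test_lag_bounds(self):
        with pytest.raises(ValueError):
            ctrw_ta_acf(0.5, 1.0, 1.0, 10.0, [10.0])


class TestExponentAlgebra:
    def test_brownian_corner(self):
        es = exponents_forward(1.0, 0.5)
        assert es.beta == 2.0 and es.z == 0.0
        assert es.regime == "boundary"

    def test_rejuvenating_point(self):
        es = exponents_forward(0.8, 0.75)
        assert abs(es.z - 0.2) < 1e-12
        assert es.regime == "III"

    def test_experimental_msd_point(self):
        es = exponents_forward(0.54, 0.32)
        assert abs(es.msd_lag_exp - 0.8056) < 1e-12
        assert abs(es.msd_aging_exp + 0.46) < 1e-12

    def test_invert_psd_route(self):
        res = exponents_invert(beta=1.75, z=-0.50, branch="I")
        assert abs(res.alpha - 0.50) < 1e-12
        assert abs(res.hurst - 0.25) < 1e-12

    def test_invert_msd_route(self):
        res = exponents_invert(branch="MSD", msd_lag_exp=0.81,
                               msd_aging_exp=-0.46)
        assert abs(res.alpha - 0.54) < 1e-12
        assert abs(res.hurst - 0.32) < 5e-3

    def test_invert_degenerate_branch(self):
        res = exponents_invert(beta=2.0, z=-0.2, branch="II/III")
        assert not res.identifiable
        assert abs(res.alpha_hurst_product - 0.4) < 1e-12
        with pytest.raises(ValueError):
            exponents_invert(beta=1.5, z=-0.2, branch="II/III")

    def test_invert_contracts(self):
        with pytest.raises(ValueError):
            exponents_invert(beta=1.75, z=0.1, branch="I")
        with pytest.raises(ValueError):
            exponents_invert(branch="nope")

    @given(alpha=st.floats(0.05, 0.999), hurst=st.floats(0.05, 0.499))
    @settings(max_examples=100, deadline=None)
    def test_regime_one_roundtrip(self, alpha, hurst):
        """Forward then invert is the identity everywhere in regime I."""
        es = exponents_forward(alpha, hurst)
        res = exponents_invert(beta=es.beta, z=es.z, branch="I")
        assert math.isclose(res.alpha, alpha, rel_tol=0, abs_tol=1e-9)
        assert math.isclose(res.hurst, hurst, rel_tol=0, abs_tol=1e-9)

    @given(alpha=st.floats(0.05, 1.0), hurst=st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_msd_roundtrip(self, alpha, hurst):
        es = exponents_forward(alpha, hurst)
        res = exponents_invert(branch="MSD", msd_lag_exp=es.msd_lag_exp,
                               msd_aging_exp=es.msd_aging_exp)
        assert math.isclose(res.hurst, hurst, rel_tol=0, abs_tol=1e-9)

    def test_seam_continuity(self):
        """The regime I and II/III formulas agree at H = 1/2: both give
        beta -> 2 and the same z."""
        lo = exponents_forward(0.6, 0.5 - 1e-9)
        hi = exponents_forward(0.6, 0.5 + 1e-9)
        assert abs(lo.beta - hi.beta) < 1e-8
        assert abs(lo.z - hi.z) < 1e-8


class TestRegimeClassification:
    @pytest.mark.parametrize("alpha,hurst,label", [
        (0.4, 0.3, "I"), (0.4, 0.7, "II"), (0.8, 0.75, "III"),
        (1.0, 0.5, "boundary"),
    ])
    def test_figure_placements(self, alpha, hurst, label):
        assert classify_regime(alpha, hurst) == label

    def test_turnover_line(self):
        """H = 1/(2 alpha) is the aging/rejuvenation turnover."""
        assert classify_regime(0.8, 1.0 / 1.6) == "boundary"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_regime(1.5, 0.5)


class TestAsymptoticLaws:
    def test_regime_one_exponents(self):
        es = exponents_forward(0.4, 0.3)
        assert abs(es.beta - 1.84) < 1e-12
        assert abs(es.z + 0.6) < 1e-12
        consts = AsymptoticConstants(c=1.0, D=1.0)
        w = np.array([1.0, 2.0])
        vals = asymptotic_psd(es, consts, w, t_m=1000.0)
        slope = np.log(vals[1] / vals[0]) / np.log(2.0)
        assert abs(slope + 1.84) < 1e-10

    def test_regime_two_is_omega_squared(self):
        es = exponents_forward(0.4, 0.7)
        assert es.beta == 2.0 and abs(es.z + 0.44) < 1e-12

    def test_alpha_to_one_limit(self):
        """alpha -> 1 with H < 1/2 gives the fBM frequency exponent 1+2H."""
        es = exponents_forward(1.0 - 1e-12, 0.3)
        assert abs(es.beta - (1.0 + 2 * 0.3)) < 1e-6

    def test_low_frequency_warning(self):
        es = exponents_forward(0.4, 0.3)
        consts = AsymptoticConstants(c=1.0, D=1.0)
        with pytest.warns(UserWarning):
            asymptotic_psd(es, consts, np.array([0.01]), t_m=100.0)


class TestPsdMsdRelation:
    def test_ctrw_routes_agree_identically(self):
        """Direct asymptote and the 2/(alpha omega^2) dMSD/dt_m route give
        the same numbers for the CTRW (algebraic identity)."""
        alpha, dx, t0, tm = 0.7, math.sqrt(0.5), 1.0, 4096.0
        w = 2 * np.pi * np.arange(8, 64) / tm
        direct = ctrw_psd_asymptote(alpha, dx, t0, tm, w)
        # MSD = 2 dx^2 t^alpha / (t0^alpha Gamma(1+alpha))
        msd_deriv = (2 * dx**2 * alpha * tm ** (alpha - 1)
                     / (t0**alpha * math.gamma(1 + alpha)))
        es = exponents_forward(alpha, 0.5)
        via_msd = psd_msd_relation(msd_deriv, es, w)
        np.testing.assert_allclose(direct, via_msd, rtol=1e-12)

    def test_persistent_branch_carries_half(self):
        """At equal MSD derivative, the H > 1/2 relation approaches half the
        CTRW relation as H -> 1/2 (prefactor 1/(2 alpha H) vs 2/alpha)."""
        es_ctrw = exponents_forward(0.7, 0.5)
        es_sup = exponents_forward(0.7, 0.5 + 1e-12)
        w = np.array([1.0])
        ratio = psd_msd_relation(1.0, es_sup, w) / psd_msd_relation(
            1.0, es_ctrw, w)
        assert abs(ratio[0] - 0.5) < 1e-9

    def test_regime_one_refused(self):
        es = exponents_forward(0.5, 0.3)
        with pytest.raises(ValueError):
            psd_msd_relation(1.0, es, np.array([1.0]))
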