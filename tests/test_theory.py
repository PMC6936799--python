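"""Closed-form geometry, correlation, and binning factors against their
defining integrals."""

import math

import numpy as np
import pytest
from scipy import integrate

from cpch.theory import (
    BinScheme,
    CpchModel,
    InvalidParameterError,
    OpticalConfig,
    SpeciesParams,
    binning_B2,
    binning_B2_discrete,
    binning_Bmn,
    correlation_G,
    diffusion_factor,
    factorial_cumulant,
    flow_factor,
    observation_volume,
    shape_factor,
)


# ---------------------------------------------------------------------------
# numeric oracles: direct integration of the defining expressions
# ---------------------------------------------------------------------------


def _gamma_quadrature(m, n, o: OpticalConfig) -> float:
    """Shape factor via quadrature of the PSF-product integral over space."""

    def axis_integral(wa, wb):
        f = lambda u: math.exp(-2.0 * (m / wa**2 + n / wb**2) * u * u)
        return integrate.quad(f, -np.inf, np.inf)[0]

    num = axis_integral(o.r_A, o.r_B) ** 2 * axis_integral(o.z_A, o.z_B)
    return num / observation_volume(o)


def _G_dim_quadrature(m, n, wa, wb, sigma2, shift=0.0) -> float:
    """One Cartesian factor of the two-point correlation integral:
    int int e^{-2m x^2/wa^2} e^{-2n y^2/wb^2} N(y - x - shift; sigma2) dx dy."""
    if sigma2 == 0:
        f = lambda x: math.exp(-2.0 * (m / wa**2 + n / wb**2) * x * x)
        return integrate.quad(f, -np.inf, np.inf)[0]
    norm = 1.0 / math.sqrt(2 * math.pi * sigma2)

    def f(y, x):
        return (
            math.exp(-2.0 * m * x * x / wa**2 - 2.0 * n * y * y / wb**2)
            * norm
            * math.exp(-((y - x - shift) ** 2) / (2 * sigma2))
        )

    L = 4 * max(wa, wb) + 6 * math.sqrt(sigma2) + abs(shift)
    val, _ = integrate.dblquad(f, -L, L, lambda x: -L, lambda x: L, epsabs=1e-12)
    return val


def _correlation_quadrature(m, n, tau, D, o: OpticalConfig, v=(0.0, 0.0)) -> float:
    """gamma_{m,n} kappa_{m,n} S_{m,n} via the defining 6D (separable)
    integral with the diffusion propagator (per-axis variance 2 D tau)."""
    s2 = 2.0 * D * tau
    ix = _G_dim_quadrature(m, n, o.r_A, o.r_B, s2, shift=v[0] * tau)
    iy = _G_dim_quadrature(m, n, o.r_A, o.r_B, s2, shift=v[1] * tau)
    iz = _G_dim_quadrature(m, n, o.z_A, o.z_B, s2)
    return ix * iy * iz / observation_volume(o)


def _B2_quadrature(T, tau_d, beta) -> float:
    """Defining second-order binning integral 2/T^2 int_0^T (T-t) kappa(t) dt."""
    f = lambda t: (T - t) * (1 + t / tau_d) ** -1 * (1 + beta * t / tau_d) ** -0.5
    val, _ = integrate.quad(f, 0, T, epsabs=1e-14, limit=200)
    return 2.0 * val / T**2


# ---------------------------------------------------------------------------
# observation volume and shape factors
# ---------------------------------------------------------------------------


class TestGeometry:
    def test_equal_channel_volume_reduction(self):
        o = OpticalConfig(r_A=0.3, z_A=1.5)
        assert observation_volume(o) == pytest.approx((math.pi / 2) ** 1.5 * 0.3**2 * 1.5)

    def test_volume_matches_direct_evaluation(self):
        o = OpticalConfig(r_A=0.25, z_A=1.25, r_B=0.25, z_B=1.25)
        expected = (math.pi / 2) ** 1.5 * ((2 * 0.25**2) / 2) * math.sqrt((2 * 1.25**2) / 2)
        assert observation_volume(o) == pytest.approx(expected, rel=1e-12)

    def test_volume_scaling_cubic(self, unequal_optics):
        o = unequal_optics
        o2 = OpticalConfig(2 * o.r_A, 2 * o.z_A, 2 * o.r_B, 2 * o.z_B)
        assert observation_volume(o2) == pytest.approx(8 * observation_volume(o), rel=1e-12)

    def test_invalid_lengths_raise(self):
        with pytest.raises(InvalidParameterError):
            OpticalConfig(r_A=-0.1, z_A=1.0)

    def test_identical_channel_shape_factors(self, equal_optics):
        assert shape_factor(1, 0, equal_optics) == pytest.approx(1.0)
        # published calibration values for the 3D Gaussian volume
        assert shape_factor(2, 1, equal_optics) == pytest.approx(0.192, abs=5e-4)
        assert shape_factor(2, 2, equal_optics) == pytest.approx(0.125, abs=5e-4)

    @pytest.mark.parametrize("m,n", [(1, 0), (1, 1), (2, 1), (3, 1), (2, 2)])
    def test_identical_channels_depend_on_total_order(self, equal_optics, m, n):
        assert shape_factor(m, n, equal_optics) == pytest.approx(
            (m + n) ** -1.5, rel=1e-14
        )

    @pytest.mark.parametrize("m,n", [(1, 0), (0, 2), (1, 1), (2, 1), (2, 2), (4, 0)])
    def test_unequal_channels_match_quadrature(self, unequal_optics, m, n):
        assert shape_factor(m, n, unequal_optics) == pytest.approx(
            _gamma_quadrature(m, n, unequal_optics), rel=1e-9
        )

    def test_zero_order_rejected(self, equal_optics):
        with pytest.raises(InvalidParameterError):
            shape_factor(0, 0, equal_optics)


# ---------------------------------------------------------------------------
# diffusion and flow factors
# ---------------------------------------------------------------------------


class TestCorrelationFactors:
    def test_kappa_is_one_at_zero_lag(self, unequal_optics):
        for m in range(5):
            for n in range(5):
                if m + n < 1:
                    continue
                assert diffusion_factor(m, n, 0.0, 50.0, unequal_optics) == 1.0

    def test_kappa_closed_form_1_1(self, equal_optics):
        # kappa_{1,1} = (1 + tau/tau_d)^-1 (1 + tau/(s^2 tau_d))^-1/2
        D, r, s = 100.0, equal_optics.r_A, equal_optics.s
        tau_d = r * r / (4 * D)
        for tau in (1e-6, 1e-4, 1e-2):
            expected = (1 + tau / tau_d) ** -1 * (1 + tau / (s * s * tau_d)) ** -0.5
            assert diffusion_factor(1, 1, tau, D, equal_optics) == pytest.approx(
                expected, rel=1e-12
            )

    def test_kappa_vanishes_at_long_lag(self, equal_optics):
        assert diffusion_factor(1, 1, 1e6, 100.0, equal_optics) < 1e-6

    def test_kappa_monotone_in_tau(self, unequal_optics):
        taus = np.logspace(-7, -1, 40)
        for m, n in [(1, 1), (2, 1), (2, 2), (3, 1)]:
            k = diffusion_factor(m, n, taus, 80.0, unequal_optics)
            assert np.all(np.diff(k) < 0)

    def test_flow_factor_unity_without_flow(self, unequal_optics):
        assert flow_factor(2, 1, 1e-4, 50.0, 0.0, 0.0, unequal_optics) == 1.0

    def test_flow_factor_monotone_in_speed(self, equal_optics):
        speeds = np.linspace(0, 20000, 12)
        vals = [flow_factor(1, 1, 1e-4, 50.0, v, 0.0, equal_optics) for v in speeds]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-3

    @pytest.mark.parametrize(
        "m,n,tau,D,v",
        [
            (1, 1, 5e-5, 100.0, (0.0, 0.0)),
            (2, 1, 2e-5, 50.0, (0.0, 0.0)),
            (1, 1, 5e-5, 100.0, (2000.0, -1000.0)),
            (2, 2, 1e-4, 30.0, (500.0, 0.0)),
        ],
    )
    def test_correlation_matches_defining_integral(self, unequal_optics, m, n, tau, D, v):
        o = unequal_optics
        expected = _correlation_quadrature(m, n, tau, D, o, v)
        got = shape_factor(m, n, o) * diffusion_factor(m, n, tau, D, o)
        got *= flow_factor(m, n, tau, D, v[0], v[1], o)
        assert got == pytest.approx(expected, rel=1e-7)

    def test_correlation_G_units_and_tau_independence_first_order(self, equal_optics):
        sp = SpeciesParams(N=2.0, eps_A=1e4, tau_d=50e-6)
        T = 10e-6
        g1 = correlation_G(1, 0, 0.0, sp, equal_optics, T=T)
        g2 = correlation_G(1, 0, 1e-3, sp, equal_optics, T=T)
        assert g1 == pytest.approx(sp.eps_A * T)  # gamma_{1,0} = 1
        assert g1 == pytest.approx(g2, rel=1e-14)


# ---------------------------------------------------------------------------
# binning functions
# ---------------------------------------------------------------------------


class TestBinning:
    def test_limit_small_alpha(self):
        assert binning_B2(1e-6 * 50e-6, 50e-6, 0.04) == pytest.approx(1.0, abs=1e-4)

    def test_monotone_decreasing_in_alpha(self):
        tau_d = 1.0
        alphas = np.logspace(-3, 2, 60)
        for beta in (0.04, 0.25):
            vals = binning_B2(alphas * tau_d, tau_d, beta)
            assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("beta", [0.04, 0.25])
    @pytest.mark.parametrize("alpha", [1e-3, 0.03, 0.3, 3.0, 30.0, 100.0])
    def test_matches_defining_quadrature(self, alpha, beta):
        tau_d = 175.7e-6
        assert binning_B2(alpha * tau_d, tau_d, beta) == pytest.approx(
            _B2_quadrature(alpha * tau_d, tau_d, beta), rel=1e-6
        )

    def test_invalid_beta(self):
        with pytest.raises(InvalidParameterError):
            binning_B2(1e-5, 1e-4, 1.5)
        with pytest.raises(InvalidParameterError):
            binning_B2(1e-5, 1e-4, -0.1)

    def test_discrete_binning_limits(self):
        tau_d, beta = 175.7e-6, 0.27
        # one sample per bin: no intra-bin motion, no correction
        assert binning_B2_discrete(10e-6, 10e-6, tau_d, beta) == 1.0
        # many samples per bin: converges to the continuous form
        cont = binning_B2(320e-6, tau_d, beta)
        disc = binning_B2_discrete(320e-6, 1e-7, tau_d, beta)
        assert disc == pytest.approx(cont, rel=2e-3)

    def test_product_approximation_branches(self):
        T, tA, tB, bA, bB = 1e-4, 175.7e-6, 200e-6, 0.27, 0.2
        b2A = binning_B2(T, tA, bA)
        b2B = binning_B2(T, tB, bB)
        assert binning_Bmn(1, 0, T, tA, tB, bA, bB) == 1.0
        assert binning_Bmn(0, 1, T, tA, tB, bA, bB) == 1.0
        assert binning_Bmn(1, 1, T, tA, tB, bA, bB) == 1.0
        assert binning_Bmn(3, 0, T, tA, tB, bA, bB) == pytest.approx(b2A**2, rel=1e-12)
        assert binning_Bmn(2, 2, T, tA, tB, bA, bB) == pytest.approx(b2A * b2B, rel=1e-12)


# ---------------------------------------------------------------------------
# factorial cumulants of models
# ---------------------------------------------------------------------------


class TestFactorialCumulants:
    def test_first_order_single_species(self, equal_optics):
        T = 10e-6
        sp = SpeciesParams(N=3.0, eps_A=2e4, tau_d=50e-6)
        model = CpchModel(equal_optics, (sp,))
        k10 = factorial_cumulant(1, 0, 0.0, T, model)
        assert k10 == pytest.approx(3.0 * 2e4 * T)

    def test_background_only_first_order(self, equal_optics):
        T = 10e-6
        sp = SpeciesParams(N=0.0, eps_A=1e4, tau_d=50e-6)
        model = CpchModel(equal_optics, (sp,), lambda_A=5e3, lambda_B=2e3)
        assert factorial_cumulant(1, 0, 0.0, T, model) == pytest.approx(5e3 * T)
        assert factorial_cumulant(0, 1, 0.0, T, model) == pytest.approx(2e3 * T)
        # background is Poisson: no contribution above first order
        assert factorial_cumulant(2, 0, 0.0, T, model) == pytest.approx(0.0, abs=1e-15)

    def test_two_species_mixture_form(self, equal_optics):
        """(K)_n = gamma_n (N1 eps1^n + N2 eps2^n) at tau = 0 for n <= 4."""
        T = 1.0
        sp1 = SpeciesParams(N=3.0, eps_A=0.4, tau_d=50e-6)
        sp2 = SpeciesParams(N=2.0, eps_A=0.8, tau_d=200e-6)
        model = CpchModel(equal_optics, (sp1, sp2))
        for n in range(1, 5):
            expected = n**-1.5 * (3.0 * 0.4**n + 2.0 * 0.8**n)
            got = factorial_cumulant(n, 0, 0.0, T, model, binning="none")
            assert got == pytest.approx(expected, rel=1e-12)

    def test_fcs_reduction_identity(self, equal_optics):
        """1 + (K)_{1,1}/((K)_{1,0}(K)_{0,1}) equals the classical FCS form."""
        T = 10e-6
        sp = SpeciesParams(N=4.0, eps_A=3e4, tau_d=80e-6)
        model = CpchModel(equal_optics, (sp,))
        s = equal_optics.s
        taus = np.logspace(-6, -2, 25)
        k11 = factorial_cumulant(1, 1, taus, T, model, binning="none")
        k10 = factorial_cumulant(1, 0, taus, T, model, binning="none")
        k01 = factorial_cumulant(0, 1, taus, T, model, binning="none")
        G = 1 + k11 / (k10 * k01)
        gamma2 = 2**-1.5
        expected = 1 + (gamma2 / 4.0) * (1 + taus / 80e-6) ** -1 * (
            1 + taus / (s * s * 80e-6)
        ) ** -0.5
        np.testing.assert_allclose(G, expected, rtol=1e-12)

    def test_flow_and_kappa_unity_grid(self, unequal_optics):
        for m in range(5):
            for n in range(5):
                if m + n < 1 or m + n > 4:
                    continue
                assert diffusion_factor(m, n, 0.0, 123.0, unequal_optics) == 1.0
                assert flow_factor(m, n, 1e-4, 123.0, 0.0, 0.0, unequal_optics) == 1.0


class TestBinScheme:
    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            BinScheme(pairs=((1.5e-5, 1e-5),), sampling_time=1e-5)  # tau not multiple
        with pytest.raises(InvalidParameterError):
            BinScheme(pairs=((2e-5, 1.5e-5),), sampling_time=1e-5)  # T not multiple

    def test_multitau_structure(self):
        scheme = BinScheme.multitau(1e-5, 1e-5, 8e-5)
        taus = np.array([p[0] for p in scheme.pairs])
        Ts = np.array([p[1] for p in scheme.pairs])
        assert np.all(np.diff(taus) > 0)
        assert np.all(np.diff(Ts) >= 0)
        # tau always an integer multiple of its T
        assert np.allclose(np.round(taus / Ts), taus / Ts)
        # T doubles every 4 lags
        assert list(Ts[:4]) == [1e-5] * 4
        assert Ts[4] == pytest.approx(2e-5)
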