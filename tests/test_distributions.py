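"""Joint count distributions: series, FFT, and recursion routes."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import poisson
from scipy.signal import fftconvolve

from cpch.theory import CpchModel, OpticalConfig, SpeciesParams, observation_volume
from cpch.distributions import (
    GridTooSmallError,
    SeriesConvergenceError,
    dual_color_pch,
    p1_series,
    pch_marginal,
    pch_pmf,
    pN_auto,
    pN_fft,
    pN_recursion,
)

T = 10e-6


@pytest.fixture
def species():
    return SpeciesParams.from_counts_per_bin(N=1.0, eps_A_bin=0.7, T=T, tau_d=50e-6)


class TestSingleMolecule:
    def test_dark_molecule_is_delta(self, equal_optics):
        sp = SpeciesParams(N=1.0, eps_A=0.0, tau_d=50e-6)
        p1 = p1_series(sp, equal_optics, 0.0, T, (8, 8))
        assert p1.values[0, 0] == 1.0
        assert p1.values.sum() == 1.0

    def test_marginal_is_pch_distribution(self, equal_optics, species):
        """Summing one axis gives the single-molecule PCH integral
        (1/V) int I^n e^{-I} / n! dx, independent of tau."""
        from scipy import integrate

        p1a = p1_series(species, equal_optics, 25e-6, T, (14, 14), binning="none")
        p1b = p1_series(species, equal_optics, 250e-6, T, (14, 14), binning="none")
        marg_a = p1a.values.sum(axis=1)
        marg_b = p1b.values.sum(axis=1)
        np.testing.assert_allclose(marg_a, marg_b, atol=1e-10)
        # PCH oracle by direct 3D quadrature (V_AB = V convention)
        o = equal_optics
        eps = species.eps_A * T
        v_ab = observation_volume(o)

        def pch_point(n):
            def rad(z):
                def f(rho):
                    I = eps * math.exp(-2 * rho**2 / o.r_A**2 - 2 * z**2 / o.z_A**2)
                    return 2 * math.pi * rho * I**n * math.exp(-I) / math.factorial(n)

                return integrate.quad(f, 0, 6 * o.r_A, epsabs=1e-13)[0]

            return integrate.quad(rad, -8 * o.z_A, 8 * o.z_A, epsabs=1e-13)[0] / v_ab

        for n in (1, 2, 3, 4):
            assert marg_a[n] == pytest.approx(pch_point(n), rel=1e-6)

    def test_matches_monte_carlo_evaluation(self, equal_optics, species, rng):
        """p_1(n_x, n_y | tau) against a 10^7-sample Monte-Carlo evaluation of
        the defining double integral (uniform x, diffusion-propagated y,
        Poisson counts)."""
        o = equal_optics
        tau, D = 50e-6, species.resolve_D(o)
        n_samp = 10_000_000
        box = np.array([2.0, 2.0, 8.0])  # um, >> observation volume
        x = (rng.random((n_samp, 3)) - 0.5) * box
        y = x + rng.standard_normal((n_samp, 3)) * math.sqrt(2 * D * tau)
        eps = species.eps_A * T

        def inten(pos):
            return eps * np.exp(
                -2 * (pos[:, 0] ** 2 + pos[:, 1] ** 2) / o.r_A**2
                - 2 * pos[:, 2] ** 2 / o.z_A**2
            )

        ca = rng.poisson(inten(x))
        cb = rng.poisson(inten(y))
        L = 6
        hist = np.bincount(ca * 16 + cb, minlength=16 * 16).reshape(16, 16)[:L, :L]
        mc = hist / n_samp
        p1 = p1_series(species, o, tau, T, (L, L), binning="none").values
        # MC probabilities are diluted by V_box / V_AB relative to the
        # V_AB-normalised series (V_AB = V convention)
        scale = box.prod() / observation_volume(o)
        for i in range(L):
            for j in range(L):
                if i == j == 0:
                    continue
                se = math.sqrt(max(mc[i, j], 1 / n_samp) / n_samp) * scale
                assert p1[i, j] == pytest.approx(mc[i, j] * scale, abs=4 * se + 1e-9)

    def test_series_overflow_raises(self, equal_optics):
        bright = SpeciesParams(N=1.0, eps_A=5e7, tau_d=50e-6)  # 500 counts/bin
        with pytest.raises(SeriesConvergenceError):
            p1_series(bright, equal_optics, 0.0, T, (8, 8))


class TestCompoundDistributions:
    def test_no_molecules_no_background_is_delta(self, equal_optics):
        sp = SpeciesParams(N=1e-12, eps_A=0.7 / T, tau_d=50e-6)
        model = CpchModel(equal_optics, (sp,))
        pmf = pN_fft(model, 25e-6, T, 8, 8)
        assert pmf.values[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_background_only_is_poisson_product(self, equal_optics):
        sp = SpeciesParams(N=0.0, eps_A=0.7 / T, tau_d=50e-6)
        model = CpchModel(equal_optics, (sp,), lambda_A=0.4 / T, lambda_B=0.15 / T)
        pmf = pN_fft(model, 25e-6, T, 16, 16)
        expected = np.outer(poisson.pmf(np.arange(16), 0.4), poisson.pmf(np.arange(16), 0.15))
        np.testing.assert_allclose(pmf.values, expected, atol=1e-12)

    def test_recursion_seed_value(self, equal_optics, species):
        model = CpchModel(equal_optics, (species,), lambda_A=0.1 / T, lambda_B=0.05 / T)
        pmf = pN_recursion(model, 25e-6, T, 20)
        p1 = p1_series(species, equal_optics, 25e-6, T, (20, 20)).values
        expected = math.exp(-species.N * (1 - p1[0, 0]) - 0.1 - 0.05)
        assert pmf.values[0, 0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("N", [0.1, 1.0, 25.0])
    @pytest.mark.parametrize("eps_bin", [0.1, 1.0])
    @pytest.mark.parametrize("tau_ratio", [0.1, 1.0, 10.0])
    def test_route_equivalence_grid(self, equal_optics, N, eps_bin, tau_ratio):
        """FFT (generating-function) and recursion routes agree elementwise
        to 1e-9 wherever the probability exceeds 1e-12."""
        tau_d = 50e-6
        sp = SpeciesParams(N=N, eps_A=eps_bin / T, tau_d=tau_d)
        model = CpchModel(equal_optics, (sp,))
        mean = N * eps_bin
        L = int(np.ceil(mean + 10 * math.sqrt(max(mean, 0.3)) + 8))
        pr = pN_recursion(model, tau_ratio * tau_d, T, L)
        pf = pN_fft(model, tau_ratio * tau_d, T, L, L)
        mask = pr.values > 1e-12
        assert np.max(np.abs(pr.values - pf.values)[mask]) < 1e-9
        assert pr.values.sum() == pytest.approx(1.0, abs=1e-6)
        assert pf.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_species_with_background_routes_agree(self, equal_optics):
        sp1 = SpeciesParams(N=2.0, eps_A=0.5 / T, tau_d=50e-6)
        sp2 = SpeciesParams(N=0.5, eps_A=1.2 / T, tau_d=300e-6)
        model = CpchModel(equal_optics, (sp1, sp2), lambda_A=0.1 / T, lambda_B=0.02 / T)
        pr = pN_recursion(model, 100e-6, T, 24)
        pf = pN_fft(model, 100e-6, T, 24, 24)
        mask = pr.values > 1e-12
        assert np.max(np.abs(pr.values - pf.values)[mask]) < 1e-9

    def test_channels_decorrelate_at_long_lag(self, equal_optics, species):
        model = CpchModel(equal_optics, (species,))
        pmf = pN_fft(model, 1.0, T, 16, 16)
        prod = np.outer(pmf.marginal(axis=1), pmf.marginal(axis=0))
        assert np.max(np.abs(pmf.values - prod)) < 1e-6

    def test_mixture_is_convolution_of_components(self, equal_optics):
        """Compound-Poisson property: the mixture PMF equals the 2D
        convolution of the single-species PMFs."""
        sp1 = SpeciesParams(N=1.5, eps_A=0.5 / T, tau_d=50e-6)
        sp2 = SpeciesParams(N=0.8, eps_A=1.0 / T, tau_d=200e-6)
        tau = 50e-6
        mix = pN_fft(CpchModel(equal_optics, (sp1, sp2)), tau, T, 28, 28)
        a = pN_fft(CpchModel(equal_optics, (sp1,)), tau, T, 28, 28)
        b = pN_fft(CpchModel(equal_optics, (sp2,)), tau, T, 28, 28)
        conv = fftconvolve(a.values, b.values)[:28, :28]
        np.testing.assert_allclose(mix.values, conv, atol=1e-9)

    def test_grid_too_small_raises(self, equal_optics):
        sp = SpeciesParams(N=25.0, eps_A=1.0 / T, tau_d=50e-6)
        model = CpchModel(equal_optics, (sp,))
        with pytest.raises(GridTooSmallError):
            pN_fft(model, 25e-6, T, 6, 6)

    def test_factorial_moments_from_pmf_match_closed_form(self, equal_optics, species):
        """Direct summation of the PMF reproduces the closed-form factorial
        cumulants (N-molecule case) within truncation tolerance."""
        from cpch.theory import factorial_cumulant
        from cpch.moments import convert_moments

        model = CpchModel(equal_optics, (species,))
        tau = 25e-6
        pmf = pN_auto(model, tau, T, binning="none")
        nx = np.arange(pmf.values.shape[0], dtype=float)
        ny = np.arange(pmf.values.shape[1], dtype=float)
        raw = {
            (m, n): float(np.sum(pmf.values * np.outer(nx**m, ny**n)))
            for m in range(5)
            for n in range(5)
            if (m, n) != (0, 0)
        }
        fk = convert_moments(raw, "M", "fK")
        for m, n in [(1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]:
            expected = factorial_cumulant(m, n, tau, T, model, binning="none")
            assert fk[(m, n)] == pytest.approx(expected, rel=1e-6, abs=1e-12)


class TestSpecialCases:
    def test_dual_color_factorizes_for_channel_exclusive_species(self):
        o = OpticalConfig(r_A=0.25, z_A=1.25, r_B=0.3, z_B=1.5)
        only_a = SpeciesParams(N=1.0, eps_A=0.6 / T, eps_B=0.0, tau_d=50e-6)
        model = CpchModel(o, (only_a,))
        pmf = dual_color_pch(model, T, max_counts=(14, 14))
        prod = np.outer(pmf.marginal(axis=1), pmf.marginal(axis=0))
        np.testing.assert_allclose(pmf.values, prod, atol=1e-10)

    def test_single_channel_tau_zero_is_diagonal(self, single_species_model):
        with pytest.warns(UserWarning, match="diagonal"):
            pmf = dual_color_pch(single_species_model, T)
        off_diag = pmf.values - np.diag(np.diag(pmf.values))
        assert np.all(off_diag == 0)
        # diagonal equals the 1D PCH
        pch = pch_pmf(single_species_model, T)
        L = min(pch.size, pmf.values.shape[0])
        np.testing.assert_allclose(np.diag(pmf.values)[:L], pch[:L], atol=1e-12)

    def test_dual_color_equals_fft_at_tau_zero(self):
        o = OpticalConfig(r_A=0.25, z_A=1.25, r_B=0.3, z_B=1.5)
        sp = SpeciesParams(N=2.0, eps_A=0.5 / T, eps_B=0.3 / T, tau_d=80e-6)
        model = CpchModel(o, (sp,))
        d = dual_color_pch(model, T, max_counts=(16, 16))
        f = pN_fft(model, 0.0, T, 16, 16)
        np.testing.assert_allclose(d.values, f.values, atol=1e-12)

    def test_sampling_matches_pmf(self, single_species_model, rng):
        pmf = pN_auto(single_species_model, 25e-6, T)
        draws = pmf.sample(200_000, rng)
        emp = np.bincount(draws[:, 0], minlength=pmf.values.shape[0]) / draws.shape[0]
        np.testing.assert_allclose(emp, pmf.marginal(axis=1), atol=5e-3)
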