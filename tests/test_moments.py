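"""Moment-family conversions, delta-method variances, FCS/FCA reductions."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpch.theory import CpchModel, OpticalConfig, SpeciesParams, factorial_cumulant
from cpch.moments import (
    CumulantTable,
    convert_moments,
    cumulant_gradients,
    default_orders,
    fca_cumulants,
    fcs_curve_model,
    fcs_from_cpch,
    model_cumulant_table,
    mom_variance,
    required_raw_orders,
)

ORDERS = [(m, n) for m in range(5) for n in range(5) if (m, n) != (0, 0)]


def raw_moments_of_pmf(pmf: np.ndarray):
    nx = np.arange(pmf.shape[0], dtype=float)
    ny = np.arange(pmf.shape[1], dtype=float)
    return {
        (m, n): float(np.sum(pmf * np.outer(nx**m, ny**n))) for (m, n) in ORDERS
    }


def sympy_cumulants(pmf: np.ndarray, kind: str):
    """Oracle: cumulants as log-series coefficients of the (factorial-)
    moment generating polynomial, via sympy -- independent of the package's
    conversion recursions."""
    import sympy as sp

    nx = np.arange(pmf.shape[0], dtype=float)
    ny = np.arange(pmf.shape[1], dtype=float)
    if kind == "fK":

        def falling(v, k):
            out = np.ones_like(v)
            for i in range(k):
                out = out * (v - i)
            return out

        mom = {
            (m, n): float(np.sum(pmf * np.outer(falling(nx, m), falling(ny, n))))
            for m in range(5)
            for n in range(5)
        }
    else:  # ordinary cumulants from raw moments
        mom = {
            (m, n): float(np.sum(pmf * np.outer(nx**m, ny**n)))
            for m in range(5)
            for n in range(5)
        }
    t, s, eps = sp.symbols("t s eps")
    P = sum(
        sp.Float(mom[(m, n)], 30)
        * (eps * t) ** m
        * (eps * s) ** n
        / (math.factorial(m) * math.factorial(n))
        for m in range(5)
        for n in range(5)
        if m + n <= 4
    )
    series = sp.series(sp.log(P), eps, 0, 5).removeO()
    poly = sp.Poly(sp.expand(series), t, s, eps)
    out = {}
    for (m, n) in ORDERS:
        coeff = poly.coeff_monomial(t**m * s**n * eps ** (m + n))
        out[(m, n)] = float(coeff) * math.factorial(m) * math.factorial(n)
    return out


class TestConversions:
    def test_poisson_factorial_cumulants(self):
        """Only the first factorial cumulant of Poisson counts is non-zero."""
        from scipy.stats import poisson

        lam_a, lam_b = 0.6, 1.3
        pa = poisson.pmf(np.arange(30), lam_a)
        pb = poisson.pmf(np.arange(30), lam_b)
        raw = raw_moments_of_pmf(np.outer(pa, pb))
        fk = convert_moments(raw, "M", "fK")
        assert fk[(1, 0)] == pytest.approx(lam_a, rel=1e-9)
        assert fk[(0, 1)] == pytest.approx(lam_b, rel=1e-9)
        for (m, n), v in fk.items():
            if m + n > 1:
                assert abs(v) < 1e-9

    @pytest.mark.parametrize("kind", ["fM", "K", "fK"])
    def test_round_trip_exact_rational(self, kind, rng):
        table = {
            o: Fraction(int(rng.integers(1, 50)), int(rng.integers(1, 9))) for o in ORDERS
        }
        back = convert_moments(convert_moments(table, "M", kind), kind, "M")
        assert all(back[o] == table[o] for o in ORDERS)

    @pytest.mark.parametrize("kind", ["fM", "K", "fK"])
    def test_against_generating_function_oracle(self, kind, rng):
        pmf = rng.random((4, 4))
        pmf /= pmf.sum()
        raw = raw_moments_of_pmf(pmf)
        got = convert_moments(raw, "M", kind)
        if kind == "fM":
            # brute force: direct sums of falling factorials
            nx = np.arange(4, dtype=float)
            ny = np.arange(4, dtype=float)

            def falling(v, k):
                out = np.ones_like(v)
                for i in range(k):
                    out = out * (v - i)
                return out

            for (m, n) in ORDERS:
                expected = float(np.sum(pmf * np.outer(falling(nx, m), falling(ny, n))))
                assert got[(m, n)] == pytest.approx(expected, abs=1e-10)
        else:
            oracle = sympy_cumulants(pmf, kind)  # exact up to total order 4
            for o in ORDERS:
                if o[0] + o[1] <= 4:
                    assert got[o] == pytest.approx(oracle[o], rel=1e-7, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_conversion_chain_closure(self, seed):
        """M -> fK -> K -> fM -> M is the identity on random small PMFs."""
        rng = np.random.default_rng(seed)
        pmf = rng.random((5, 5)) ** 2
        pmf /= pmf.sum()
        raw = raw_moments_of_pmf(pmf)
        t = convert_moments(raw, "M", "fK")
        t = convert_moments(t, "fK", "K")
        t = convert_moments(t, "K", "fM")
        t = convert_moments(t, "fM", "M")
        for o in ORDERS:
            assert t[o] == pytest.approx(raw[o], rel=1e-8, abs=1e-10)

    def test_missing_lower_orders_rejected(self):
        from cpch.theory import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            convert_moments({(2, 0): 1.0}, "M", "fK")


class TestMomVariance:
    def test_first_order_closed_form(self):
        raw = {(1, 0): 0.3, (2, 0): 0.4, (0, 1): 0.2, (0, 2): 0.3, (1, 1): 0.1}
        v = mom_variance(raw, (1, 0), 250.0)
        assert v == pytest.approx((0.4 - 0.09) / 250.0, rel=1e-12)

    def test_scales_inversely_with_sample_size(self, rng):
        pmf = rng.random((4, 4))
        pmf /= pmf.sum()
        raw = raw_moments_of_pmf(pmf)
        # fill the extended staircase needed for the (2,2) variance
        need = required_raw_orders([(2, 2)])
        nx = np.arange(4, dtype=float)
        ny = np.arange(4, dtype=float)
        for (a, b) in need:
            raw[(a, b)] = float(np.sum(pmf * np.outer(nx**a, ny**b)))
        v1 = mom_variance(raw, (2, 2), 100.0)
        v2 = mom_variance(raw, (2, 2), 1000.0)
        assert v1 == pytest.approx(10 * v2, rel=1e-12)
        assert v1 >= 0

    def test_matches_replicate_scatter_iid_sampling(self, rng):
        """Delta-method variance vs the across-replicate scatter of (K)_{2,2}
        for iid draws from a fixed joint PMF (50 replicates, 3x tolerance)."""
        from cpch.moments import factorial_cumulants_from_raw

        # a correlated 3x3 PMF
        pmf = np.array([[0.3, 0.1, 0.02], [0.1, 0.2, 0.05], [0.02, 0.05, 0.16]])
        pmf /= pmf.sum()
        flat = pmf.ravel()
        orders = [(2, 2)]
        need = required_raw_orders(orders)
        N_d = 20000
        vals, quoted = [], []
        for _ in range(50):
            idx = rng.choice(flat.size, size=N_d, p=flat)
            a, b = np.divmod(idx, pmf.shape[1])
            a = a.astype(float)
            b = b.astype(float)
            raw = {(x, y): float(np.mean(a**x * b**y)) for (x, y) in need}
            v, var = factorial_cumulants_from_raw(raw, orders, N_d)
            vals.append(v[(2, 2)])
            quoted.append(var[(2, 2)])
        emp = np.var(vals, ddof=1)
        q = np.mean(quoted)
        assert q == pytest.approx(emp, rel=2.0)  # within 3x either way
        assert q > 0

    def test_gradients_match_finite_differences(self, rng):
        pmf = rng.random((4, 4))
        pmf /= pmf.sum()
        raw = raw_moments_of_pmf(pmf)
        grads = cumulant_gradients(raw, (2, 1), "fK")
        from cpch.moments import cumulant_poly, _poly_eval

        poly = cumulant_poly(2, 1, "fK")
        for var, g in grads.items():
            bumped = dict(raw)
            h = 1e-7
            bumped[var] = raw[var] + h
            fd = (_poly_eval(poly, bumped) - _poly_eval(poly, raw)) / h
            assert g == pytest.approx(fd, rel=1e-5)


class TestFcsAndFca:
    def test_fcs_reduces_to_classical_form(self, equal_optics):
        """G(tau) from model cumulants equals the closed-form single-species
        FCS curve to near machine precision."""
        N, tau_d = 4.0, 80e-6
        sp = SpeciesParams(N=N, eps_A=3e4, tau_d=tau_d)
        model = CpchModel(equal_optics, (sp,))
        taus = np.logspace(-6, -1, 40)
        curve = fcs_curve_model(model, taus, T=10e-6)
        s = equal_optics.s
        gamma2 = 2**-1.5
        expected = 1 + (gamma2 / N) * (1 + taus / tau_d) ** -1 * (
            1 + taus / (s * s * tau_d)
        ) ** -0.5
        np.testing.assert_allclose(curve.G, expected, rtol=1e-12)

    def test_fcs_long_lag_limit(self, single_species_model):
        curve = fcs_curve_model(single_species_model, [10.0], T=10e-6)
        assert curve.G[0] == pytest.approx(1.0, abs=1e-5)

    def test_fcs_tau_zero_uses_1d_moments(self, single_species_model):
        """At tau = 0 the curve point is M_2/M_1^2 of the 1D counts."""
        T = 10e-6
        table = model_cumulant_table(
            single_species_model, [0.0], T, orders=[(1, 0), (0, 1), (2, 0), (1, 1)],
            binning="none",
        )
        curve = fcs_from_cpch(table)
        k1 = table.value(1, 0, 0.0)
        k2 = table.value(2, 0, 0.0)
        assert curve.G[0] == pytest.approx((k1 + k1**2 + k2) / k1**2, rel=1e-12)

    def test_fca_equals_marginal_cumulants(self, single_species_model):
        T = 10e-6
        fca = fca_cumulants(single_species_model, n_max=4, T=T, binning="none")
        for n in range(1, 5):
            expected = factorial_cumulant(n, 0, 0.0, T, single_species_model, binning="none")
            assert fca[n] == pytest.approx(expected, rel=1e-12)

    def test_fca_two_species_closed_form(self, equal_optics):
        sp1 = SpeciesParams(N=3.0, eps_A=0.4, tau_d=50e-6)
        sp2 = SpeciesParams(N=2.0, eps_A=0.8, tau_d=50e-6)
        model = CpchModel(equal_optics, (sp1, sp2))
        fca = fca_cumulants(model, n_max=4, T=1.0, binning="none")
        for n in range(1, 5):
            assert fca[n] == pytest.approx(
                n**-1.5 * (3.0 * 0.4**n + 2.0 * 0.8**n), rel=1e-12
            )


class TestCumulantTable:
    def test_csv_round_trip(self, tmp_path, single_species_model):
        table = model_cumulant_table(single_species_model, [1e-5, 1e-4], 1e-5)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = CumulantTable.from_csv(path)
        assert back.kind == table.kind
        np.testing.assert_allclose(back.data.value, table.data.value)

    def test_default_orders(self):
        orders = default_orders(4)
        assert (0, 0) not in orders
        assert len(orders) == 14
        assert all(1 <= m + n <= 4 for m, n in orders)
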