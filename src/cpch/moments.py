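"""Moment algebra for photon-count statistics.

Conversions between the four moment families of a bivariate count
distribution -- raw moments ``M_{m,n}``, factorial moments ``(M)_{m,n}``,
cumulants ``K_{m,n}`` and factorial cumulants ``(K)_{m,n}`` -- plus the
delta-method ("moments of moments") sampling variances of empirical
(factorial) cumulants, and the FCS / FCA special cases.

The conversions are generated programmatically with exact rational
arithmetic: factorial and raw moments are related per axis by Stirling
numbers (falling-factorial expansions), and cumulants are related to moments
of the same family by the bivariate Leibniz recursion

    (M)_{m,n} = sum_{j=1..m} sum_{k=0..n} C(m-1,j-1) C(n,k)
                (K)_{j,k} (M)_{m-j,n-k}            (m >= 1),

which follows from d/dt g = g d/dt log g.  Every factorial cumulant is also
available as an explicit polynomial in the raw moments, from which the
partial derivatives needed by the first-order variance formula

    Var[X_{p,r}] = sum dX/dM_{x,y} dX/dM_{u,v} Cov[M_{x,y}, M_{u,v}],
    Cov[M_{x,y}, M_{u,v}] = (M_{x+u,y+v} - M_{x,y} M_{u,v}) / N_d

are obtained exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .theory import CpchModel, factorial_cumulant, InvalidParameterError

__all__ = [
    "CumulantTable",
    "FcsCurve",
    "convert_moments",
    "mom_variance",
    "required_raw_orders",
    "factorial_cumulants_from_raw",
    "fcs_from_cpch",
    "fcs_curve_model",
    "fca_cumulants",
    "default_orders",
]

Order = Tuple[int, int]
KINDS = ("M", "fM", "K", "fK")
_KIND_ALIASES = {
    "raw": "M",
    "M": "M",
    "factorial_moment": "fM",
    "fM": "fM",
    "cumulant": "K",
    "K": "K",
    "factorial_cumulant": "fK",
    "fK": "fK",
}


def default_orders(max_total: int = 4) -> List[Order]:
    """All (m, n) with 1 <= m+n <= max_total, the standard fitting set."""
    return [
        (m, n)
        for total in range(1, max_total + 1)
        for m in range(total, -1, -1)
        for n in (total - m,)
    ]


# ---------------------------------------------------------------------------
# exact polynomial machinery
# ---------------------------------------------------------------------------
# A polynomial in the raw moments is a dict: monomial -> Fraction, where a
# monomial is a sorted tuple of ((a, b), power) pairs and M_{0,0} == 1.

Monomial = Tuple[Tuple[Order, int], ...]
Poly = Dict[Monomial, Fraction]

_ONE: Monomial = ()


def _poly_const(c) -> Poly:
    c = Fraction(c)
    return {_ONE: c} if c else {}


def _poly_var(a: int, b: int) -> Poly:
    if a == 0 and b == 0:
        return _poly_const(1)
    return {(((a, b), 1),): Fraction(1)}


def _poly_add(p: Poly, q: Poly, cq=Fraction(1)) -> Poly:
    out = dict(p)
    for mono, c in q.items():
        nc = out.get(mono, Fraction(0)) + cq * c
        if nc:
            out[mono] = nc
        else:
            out.pop(mono, None)
    return out


def _mono_mul(m1: Monomial, m2: Monomial) -> Monomial:
    d = dict(m1)
    for var, p in m2:
        d[var] = d.get(var, 0) + p
    return tuple(sorted(d.items()))


def _poly_mul(p: Poly, q: Poly) -> Poly:
    out: Poly = {}
    for m1, c1 in p.items():
        for m2, c2 in q.items():
            mono = _mono_mul(m1, m2)
            nc = out.get(mono, Fraction(0)) + c1 * c2
            if nc:
                out[mono] = nc
            else:
                out.pop(mono, None)
    return out


def _poly_diff(p: Poly, var: Order) -> Poly:
    out: Poly = {}
    for mono, c in p.items():
        d = dict(mono)
        if var not in d:
            continue
        power = d[var]
        if power == 1:
            del d[var]
        else:
            d[var] = power - 1
        out[tuple(sorted(d.items()))] = out.get(tuple(sorted(d.items())), Fraction(0)) + c * power
    return {m: c for m, c in out.items() if c}


def _poly_eval(p: Poly, values: Mapping[Order, float]):
    total = 0.0 if not _all_fractions(values) else Fraction(0)
    for mono, c in p.items():
        term = c if isinstance(total, Fraction) else float(c)
        for var, power in mono:
            term = term * values[var] ** power
        total = total + term
    return total


def _all_fractions(values: Mapping[Order, object]) -> bool:
    return all(isinstance(v, Fraction) for v in values.values()) and len(values) > 0


@lru_cache(maxsize=None)
def _stirling1(n: int, k: int) -> int:
    """Signed Stirling numbers of the first kind: (x)_n = sum_k s(n,k) x^k."""
    if n == 0:
        return 1 if k == 0 else 0
    if k == 0 or k > n:
        return 0
    return _stirling1(n - 1, k - 1) - (n - 1) * _stirling1(n - 1, k)


@lru_cache(maxsize=None)
def _stirling2(n: int, k: int) -> int:
    """Stirling numbers of the second kind: x^n = sum_k S(n,k) (x)_k."""
    if n == 0:
        return 1 if k == 0 else 0
    if k == 0 or k > n:
        return 0
    return _stirling2(n - 1, k - 1) + k * _stirling2(n - 1, k)


@lru_cache(maxsize=None)
def factorial_moment_poly(m: int, n: int) -> "tuple":
    """(M)_{m,n} as a polynomial in the raw moments (linear)."""
    p: Poly = {}
    for j in range(m + 1):
        s1m = _stirling1(m, j)
        if not s1m:
            continue
        for k in range(n + 1):
            s1n = _stirling1(n, k)
            if not s1n:
                continue
            p = _poly_add(p, _poly_var(j, k), Fraction(s1m * s1n))
    return tuple(sorted(p.items()))


@lru_cache(maxsize=None)
def _cumulant_poly_generic(m: int, n: int, factorial: bool) -> "tuple":
    """(K)_{m,n} (or K_{m,n}) as a polynomial in the raw moments."""
    if m + n == 0:
        raise InvalidParameterError("cumulant order (0,0) is undefined")

    def mom(j, k) -> Poly:
        if factorial:
            return dict(factorial_moment_poly(j, k))
        return _poly_var(j, k)

    p = mom(m, n)
    if m >= 1:
        for j in range(1, m + 1):
            for k in range(0, n + 1):
                if (j, k) == (m, n) or (j, k) == (0, 0):
                    continue
                coef = Fraction(math.comb(m - 1, j - 1) * math.comb(n, k))
                term = _poly_mul(dict(_cumulant_poly_generic(j, k, factorial)), mom(m - j, n - k))
                p = _poly_add(p, term, -coef)
    else:  # m == 0, n >= 1: distinguish the second axis
        for k in range(1, n):
            coef = Fraction(math.comb(n - 1, k - 1))
            term = _poly_mul(dict(_cumulant_poly_generic(0, k, factorial)), mom(0, n - k))
            p = _poly_add(p, term, -coef)
    return tuple(sorted(p.items()))


def cumulant_poly(m: int, n: int, kind: str = "fK") -> Poly:
    """Polynomial of K_{m,n} ('K') or (K)_{m,n} ('fK') in the raw moments."""
    kind = _KIND_ALIASES[kind]
    if kind not in ("K", "fK"):
        raise InvalidParameterError("cumulant_poly supports kinds 'K' and 'fK'")
    return dict(_cumulant_poly_generic(m, n, kind == "fK"))


# ---------------------------------------------------------------------------
# numeric conversions between kinds
# ---------------------------------------------------------------------------


def _require(table: Mapping[Order, float], orders: Iterable[Order]):
    missing = [o for o in orders if o != (0, 0) and o not in table]
    if missing:
        raise InvalidParameterError(f"conversion needs lower orders, missing: {missing}")


def _get(table: Mapping[Order, float], o: Order):
    if o == (0, 0):
        return 1
    return table[o]


def _lower_orders(m: int, n: int) -> List[Order]:
    return [(j, k) for j in range(m + 1) for k in range(n + 1) if (j, k) != (0, 0)]


def _linear_stirling(table, m, n, stirling):
    total = 0
    for j in range(m + 1):
        sj = stirling(m, j)
        if not sj:
            continue
        for k in range(n + 1):
            sk = stirling(n, k)
            if not sk:
                continue
            total = total + sj * sk * _get(table, (j, k))
    return total


def _moments_from_cumulants(K: Mapping[Order, float], orders) -> Dict[Order, float]:
    """Forward Leibniz recursion: moments of the same family from cumulants."""
    M: Dict[Order, float] = {}

    def mom(j, k):
        if (j, k) == (0, 0):
            return 1
        return M[(j, k)]

    for m, n in sorted(orders, key=lambda o: (o[0] + o[1], o)):
        if m >= 1:
            total = 0
            for j in range(1, m + 1):
                for k in range(0, n + 1):
                    total = total + math.comb(m - 1, j - 1) * math.comb(n, k) * _get(
                        K, (j, k)
                    ) * mom(m - j, n - k)
        else:
            total = _get(K, (0, n))
            for k in range(1, n):
                total = total + math.comb(n - 1, k - 1) * _get(K, (0, k)) * mom(0, n - k)
        M[(m, n)] = total
    return M


def _cumulants_from_moments(M: Mapping[Order, float], orders) -> Dict[Order, float]:
    K: Dict[Order, float] = {}

    def get_k(j, k):
        return K[(j, k)]

    for m, n in sorted(orders, key=lambda o: (o[0] + o[1], o)):
        total = _get(M, (m, n))
        if m >= 1:
            for j in range(1, m + 1):
                for k in range(0, n + 1):
                    if (j, k) == (m, n):
                        continue
                    total = total - math.comb(m - 1, j - 1) * math.comb(n, k) * get_k(
                        j, k
                    ) * _get(M, (m - j, n - k))
        else:
            for k in range(1, n):
                total = total - math.comb(n - 1, k - 1) * get_k(0, k) * _get(M, (0, n - k))
        K[(m, n)] = total
    return K


def convert_moments(
    table: Mapping[Order, float], from_kind: str, to_kind: str
) -> Dict[Order, float]:
    """Convert a complete {(m, n): value} table between moment kinds.

    Kinds: 'M' raw moments, 'fM' factorial moments, 'K' cumulants,
    'fK' factorial cumulants.  The table must contain every order (j, k) <=
    (m, n) componentwise for each (m, n) present (conversion at an order
    needs all lower orders).  Exact when fed Fractions.
    """
    from_kind = _KIND_ALIASES[from_kind]
    to_kind = _KIND_ALIASES[to_kind]
    orders = sorted(table.keys(), key=lambda o: (o[0] + o[1], o))
    for m, n in orders:
        _require(table, _lower_orders(m, n))
    if from_kind == to_kind:
        return dict(table)

    # hub: raw moments
    if from_kind == "M":
        raw = dict(table)
    elif from_kind == "fM":
        raw = {(m, n): _linear_stirling(table, m, n, _stirling2) for m, n in orders}
    elif from_kind == "K":
        raw = _moments_from_cumulants(table, orders)
    else:  # fK -> fM -> M
        fM = _moments_from_cumulants(table, orders)
        raw = {(m, n): _linear_stirling(fM, m, n, _stirling2) for m, n in orders}

    if to_kind == "M":
        return raw
    if to_kind == "fM":
        return {(m, n): _linear_stirling(raw, m, n, _stirling1) for m, n in orders}
    if to_kind == "K":
        return _cumulants_from_moments(raw, orders)
    fM = {(m, n): _linear_stirling(raw, m, n, _stirling1) for m, n in orders}
    return _cumulants_from_moments(fM, orders)


# ---------------------------------------------------------------------------
# moments of moments (delta-method variances)
# ---------------------------------------------------------------------------


def required_raw_orders(targets: Iterable[Order]) -> List[Order]:
    """Raw-moment orders needed to compute the targets' values and variances."""
    need = set()
    for p, r in targets:
        for x in range(p + 1):
            for y in range(r + 1):
                for u in range(p + 1):
                    for v in range(r + 1):
                        if (x, y) != (0, 0) and (u, v) != (0, 0):
                            need.add((x + u, y + v))
                        if (x, y) != (0, 0):
                            need.add((x, y))
    return sorted(need, key=lambda o: (o[0] + o[1], o))


def mom_variance(
    raw_moments: Mapping[Order, float],
    target: Order,
    N_d: float,
    kind: str = "fK",
) -> float:
    """First-order sampling variance of an empirical (factorial) cumulant.

    ``raw_moments`` must contain every order up to (2p, 2r) componentwise for
    the target (p, r) (see :func:`required_raw_orders`); ``N_d`` is the
    number of data points the moments were averaged over.  Assumes the data
    points are independent, which undercounts the variance of low-order
    cumulants of strongly correlated traces (the classic first-cumulant
    caveat); see ``autocorrelation_inflation`` in the empirical pipeline.
    """
    if N_d <= 0:
        raise InvalidParameterError("N_d must be > 0")
    p, r = target
    poly = cumulant_poly(p, r, kind)
    vars_ = sorted({var for mono in poly for var, _ in mono})
    _require(raw_moments, vars_)
    grads = {}
    for var in vars_:
        g = _poly_eval(_poly_diff(poly, var), raw_moments)
        if g:
            grads[var] = g
    var_total = 0.0
    for (x, y), gx in grads.items():
        for (u, v), gu in grads.items():
            try:
                mxy_uv = _get(raw_moments, (x + u, y + v))
            except KeyError:
                raise InvalidParameterError(
                    f"variance of {target} needs raw moment {(x + u, y + v)}"
                )
            cov = (mxy_uv - _get(raw_moments, (x, y)) * _get(raw_moments, (u, v))) / N_d
            var_total = var_total + float(gx) * float(gu) * float(cov)
    return float(var_total)


def cumulant_gradients(
    raw_moments: Mapping[Order, float], target: Order, kind: str = "fK"
) -> Dict[Order, float]:
    """Partials d(K)_{p,r}/dM_{x,y} evaluated at the raw moments.

    These define the influence function of the cumulant estimator,
    psi_i = sum_{x,y} grad_{x,y} a_i^x b_i^y: the cumulant is (to first
    order) the sample mean of psi, which is what the delta-method variance
    (and its serial-correlation correction) is computed from.
    """
    poly = cumulant_poly(*target, kind)
    vars_ = sorted({var for mono in poly for var, _ in mono})
    _require(raw_moments, vars_)
    out = {}
    for var in vars_:
        g = float(_poly_eval(_poly_diff(poly, var), raw_moments))
        if g:
            out[var] = g
    return out


def factorial_cumulants_from_raw(
    raw_moments: Mapping[Order, float],
    orders: Sequence[Order],
    N_d: Optional[float] = None,
) -> Tuple[Dict[Order, float], Dict[Order, float]]:
    """Values (and, if N_d given, variances) of (K)_{m,n} from raw moments."""
    values = {}
    for o in orders:
        poly = cumulant_poly(*o, "fK")
        values[o] = float(_poly_eval(poly, raw_moments))
    variances = {}
    if N_d is not None:
        for o in orders:
            variances[o] = mom_variance(raw_moments, o, N_d, "fK")
    return values, variances


# ---------------------------------------------------------------------------
# tables and curves
# ---------------------------------------------------------------------------


@dataclass
class CumulantTable:
    """Tidy table of moments/cumulants per (m, n, tau, T).

    ``data`` columns: m, n, tau_s, T_s, value, variance, N_d.  ``kind`` is
    one of 'M', 'fM', 'K', 'fK'.  Model-derived tables carry variance = NaN.
    """

    data: pd.DataFrame
    kind: str = "fK"

    _COLUMNS = ["m", "n", "tau_s", "T_s", "value", "variance", "N_d"]

    def __post_init__(self):
        self.kind = _KIND_ALIASES[self.kind]
        for col in self._COLUMNS:
            if col not in self.data.columns:
                if col in ("variance", "N_d"):
                    self.data[col] = np.nan
                else:
                    raise InvalidParameterError(f"CumulantTable missing column {col}")
        self.data = self.data[self._COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records, kind="fK"):
        return cls(pd.DataFrame.from_records(records, columns=cls._COLUMNS), kind=kind)

    def select(self, m=None, n=None, tau_s=None) -> pd.DataFrame:
        df = self.data
        if m is not None:
            df = df[df.m == m]
        if n is not None:
            df = df[df.n == n]
        if tau_s is not None:
            df = df[np.isclose(df.tau_s, tau_s)]
        return df

    def value(self, m, n, tau_s) -> float:
        df = self.select(m=m, n=n, tau_s=tau_s)
        if len(df) != 1:
            raise KeyError(f"no unique entry for (m={m}, n={n}, tau={tau_s})")
        return float(df.value.iloc[0])

    def to_csv(self, path):
        df = self.data.copy()
        df.insert(0, "kind", self.kind)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        kind = df["kind"].iloc[0] if "kind" in df.columns else "fK"
        return cls(df.drop(columns=["kind"], errors="ignore"), kind=kind)


def model_cumulant_table(
    model: CpchModel,
    taus: Sequence[float],
    T: float,
    orders: Optional[Sequence[Order]] = None,
    binning: str = "continuous",
    dt: Optional[float] = None,
    closed_box_p: float = 0.0,
) -> CumulantTable:
    """Theoretical factorial-cumulant table for a model on a tau grid."""
    orders = list(orders) if orders is not None else default_orders(4)
    records = []
    for m, n in orders:
        vals = factorial_cumulant(
            m, n, np.asarray(taus, float), T, model, binning, dt, closed_box_p=closed_box_p
        )
        vals = np.atleast_1d(vals)
        for tau, v in zip(taus, vals):
            records.append((m, n, float(tau), float(T), float(v), np.nan, np.nan))
    return CumulantTable.from_records(records, kind="fK")


@dataclass
class FcsCurve:
    """An FCS autocorrelation curve G(tau) with per-point variance."""

    tau: np.ndarray
    G: np.ndarray
    variance: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"tau_s": self.tau, "G": self.G})
        if self.variance is not None:
            df["sigma_G"] = np.sqrt(self.variance)
        return df


def fcs_from_cpch(
    table: CumulantTable,
    raw_by_tau: Optional[Mapping[float, Mapping[Order, float]]] = None,
) -> FcsCurve:
    """FCS curve from the first factorial cumulants of a cPCH table.

    G(tau) = 1 + (K)_{1,1}/((K)_{1,0} (K)_{0,1}) for tau > 0.  At tau = 0 the
    single-channel data are one-dimensional (each bin compared with itself),
    and the joint moment is replaced by the second moment of the 1D counts:
    M_{1,1}(0) = (K)_1 + (K)_1^2 + (K)_2, taken from the (2,0)/(1,0) entries.

    When ``raw_by_tau`` supplies the empirical raw moments per tau, the
    per-point variance is propagated by the delta method from the raw-moment
    covariances.
    """
    if table.kind != "fK":
        raise InvalidParameterError("fcs_from_cpch expects a factorial-cumulant table")
    taus = np.array(sorted(table.data.tau_s.unique()))
    G = np.empty_like(taus)
    var = np.full_like(taus, np.nan)
    for i, tau in enumerate(taus):
        if tau > 0:
            k10 = table.value(1, 0, tau)
            k01 = table.value(0, 1, tau)
            k11 = table.value(1, 1, tau)
            if k10 == 0 or k01 == 0:
                raise InvalidParameterError("FCS undefined: zero mean counts (dark data)")
            G[i] = 1.0 + k11 / (k10 * k01)
        else:
            k1 = table.value(1, 0, tau)
            k2 = table.value(2, 0, tau)
            if k1 == 0:
                raise InvalidParameterError("FCS undefined: zero mean counts (dark data)")
            m11 = k1 + k1**2 + k2  # 1D second raw moment
            G[i] = m11 / k1**2
        if raw_by_tau is not None and tau in raw_by_tau:
            raw = raw_by_tau[tau]
            df = table.select(tau_s=tau)
            N_d = float(df.N_d.iloc[0])
            var[i] = _fcs_point_variance(raw, N_d, tau > 0)
    return FcsCurve(tau=taus, G=G, variance=None if raw_by_tau is None else var)


def _fcs_point_variance(raw: Mapping[Order, float], N_d: float, joint: bool) -> float:
    """Delta-method variance of G = M11/(M10 M01) (or M20/M10^2 at tau=0)."""
    if joint:
        m10, m01, m11 = raw[(1, 0)], raw[(0, 1)], raw[(1, 1)]
        grads = {
            (1, 1): 1.0 / (m10 * m01),
            (1, 0): -m11 / (m10**2 * m01),
            (0, 1): -m11 / (m10 * m01**2),
        }
    else:
        m10, m20 = raw[(1, 0)], raw[(2, 0)]
        grads = {(2, 0): 1.0 / m10**2, (1, 0): -2.0 * m20 / m10**3}
    var = 0.0
    for (x, y), gx in grads.items():
        for (u, v), gu in grads.items():
            cov = (raw[(x + u, y + v)] - raw[(x, y)] * raw[(u, v)]) / N_d
            var += gx * gu * cov
    return var


def fcs_curve_model(model: CpchModel, taus, T: float, binning="none", dt=None) -> FcsCurve:
    """Model FCS curve G(tau) = 1 + (K)_{1,1}/((K)_{1,0}(K)_{0,1})."""
    taus = np.asarray(taus, float)
    k10 = factorial_cumulant(1, 0, taus, T, model, binning, dt)
    k01 = factorial_cumulant(0, 1, taus, T, model, binning, dt)
    k11 = factorial_cumulant(1, 1, taus, T, model, binning, dt)
    return FcsCurve(tau=taus, G=1.0 + np.atleast_1d(k11) / (np.atleast_1d(k10) * np.atleast_1d(k01)))


def fca_cumulants(source, n_max: int = 4, tau: float = 0.0, T: float = 1.0, **kw) -> Dict[int, float]:
    """1D fluorescence cumulants (K)_n used by FCA.

    For a :class:`CpchModel`, returns (K)_n = sum_i N_i (eps_A,i T)^n gamma_n
    (the m-axis factorial cumulants with the other order set to zero).  For a
    :class:`CumulantTable`, returns the empirical n-axis marginal cumulants
    (K)_{n,0} at the requested tau.
    """
    if isinstance(source, CpchModel):
        return {
            n: float(factorial_cumulant(n, 0, tau, T, source, **kw)) for n in range(1, n_max + 1)
        }
    if isinstance(source, CumulantTable):
        if source.kind != "fK":
            raise InvalidParameterError("fca_cumulants expects a factorial-cumulant table")
        taus = sorted(source.data.tau_s.unique())
        use_tau = tau if tau in taus else taus[0]
        return {n: source.value(n, 0, use_tau) for n in range(1, n_max + 1)}
    raise TypeError("source must be a CpchModel or CumulantTable")
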