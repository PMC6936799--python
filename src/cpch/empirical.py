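"""From photon data to empirical cPCH histograms, moments and fit energies.

Two data routes are supported.  Binned count traces (one value per bin time
T) are paired directly: the counts of bin i and bin i + tau/T form one entry
of the joint histogram p*(n_a, n_b | tau, T).  Arrival-time data (integer
detector ticks) are first reduced to the sparse list of bins with positive
counts, and the histogram is assembled from the intersection / set
differences of that list with its lag-shifted copy, so the full (possibly
enormous) dense bin array is never materialised.

Raw moments of the pair ensemble, M_{m,n}(tau) = <n_a^m n_b^n>, feed the
moment engine to produce factorial cumulants with delta-method variances;
the two fit energies of the method (per-histogram-cell E_p and
per-cumulant E_K) are computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .theory import BinScheme, InvalidParameterError
from .moments import (
    CumulantTable,
    cumulant_gradients,
    default_orders,
    factorial_cumulants_from_raw,
    required_raw_orders,
)

__all__ = [
    "ArrivalTrace",
    "CpchHistogram",
    "bin_arrival_times",
    "build_cpch_hist",
    "histogram_from_pairs",
    "raw_moments_from_pairs",
    "empirical_moments",
    "cumulant_table_from_counts",
    "raw_moment_tables_from_counts",
    "energy_Ep",
    "energy_EK",
]

Order = Tuple[int, int]


@dataclass
class ArrivalTrace:
    """Photon arrival times as integer multiples of the detector clock.

    ``times`` are non-decreasing integer ticks; ``sampling_time`` is the
    detector clock in seconds; ``duration`` the trace length in seconds.
    """

    times: np.ndarray
    sampling_time: float
    duration: float
    channel: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise InvalidParameterError("arrival times must be non-decreasing")
        if self.times.size and self.times[0] < 0:
            raise InvalidParameterError("negative arrival times")
        if self.times.size and self.times[-1] * self.sampling_time > self.duration:
            raise InvalidParameterError("arrival time beyond trace duration")


@dataclass
class CpchHistogram:
    """Joint histogram of photon-count pairs at one (tau, T).

    ``counts[n_a, n_b]`` is the number of bin pairs with those counts;
    ``total_pairs`` the number of pairs considered (sum of counts).
    """

    counts: np.ndarray
    tau: float
    T: float
    total_pairs: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if int(self.counts.sum()) != int(self.total_pairs):
            raise InvalidParameterError("histogram does not account for all bin pairs")

    @property
    def pmf(self) -> np.ndarray:
        """Empirical probability distribution (normalised histogram)."""
        return self.counts / float(self.total_pairs)

    def raw_moments(self, orders: Iterable[Order]) -> Dict[Order, float]:
        na = np.arange(self.counts.shape[0], dtype=float)
        nb = np.arange(self.counts.shape[1], dtype=float)
        p = self.pmf
        return {
            (m, n): float(np.sum(p * np.outer(na**m, nb**n))) for (m, n) in orders
        }


def bin_arrival_times(trace: ArrivalTrace, T: float):
    """Assign photons to counting bins of length T (sparse representation).

    T must be an integer multiple of the sampling time.  Photon at tick t
    falls in bin ceil(t / T_ticks) (1-based); a photon at tick 0 is assigned
    to bin 1.  Returns (positive_bins, counts, n_bins): the sorted 1-based
    indices of bins containing photons, their photon counts, and the total
    number of bins ceil(duration / T).
    """
    T_ticks = round(T / trace.sampling_time)
    if T_ticks < 1 or abs(T - T_ticks * trace.sampling_time) > 1e-9 * T:
        raise InvalidParameterError("T must be an integer multiple of the sampling time")
    n_bins = int(math.ceil(trace.duration / T - 1e-12))
    if trace.times.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), n_bins
    b = -(-trace.times // T_ticks)  # ceil division
    b = np.maximum(b, 1)
    positive, counts = np.unique(b, return_counts=True)
    return positive.astype(np.int64), counts.astype(np.int64), n_bins


def histogram_from_pairs(a: np.ndarray, b: np.ndarray, tau: float, T: float) -> CpchHistogram:
    """Dense route: 2D histogram of already-paired count arrays."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise InvalidParameterError("paired arrays must have equal length")
    if a.size == 0:
        raise InvalidParameterError("empty histogram: no bin pairs")
    La = int(a.max()) + 1
    Lb = int(b.max()) + 1
    flat = np.bincount(a.astype(np.int64) * Lb + b.astype(np.int64), minlength=La * Lb)
    return CpchHistogram(flat.reshape(La, Lb), tau=tau, T=T, total_pairs=a.size)


def build_cpch_hist(
    source: Union[ArrivalTrace, np.ndarray],
    tau: float,
    T: float,
    second_channel: Union[ArrivalTrace, np.ndarray, None] = None,
    sampling_time: Optional[float] = None,
) -> CpchHistogram:
    """Empirical cPCH histogram at lag tau and bin time T.

    For binned count arrays the pairing is direct.  For arrival-time traces
    the sparse three-part procedure is used: pairs with both counts positive
    come from the intersection of the positive-bin list with its lag-shifted
    copy; pairs with exactly one positive count from the set differences; and
    the (0, 0) count is the remainder, total pairs minus pairs with any
    positive count.  Only pairs fully inside the trace are used (no
    wraparound): total_pairs = n_bins - tau/T.
    """
    tau_k = int(round(tau / T))
    if abs(tau - tau_k * T) > 1e-9 * max(tau, T):
        raise InvalidParameterError("tau must be an integer multiple of T")

    if isinstance(source, ArrivalTrace):
        bpos_a, cnt_a, n_bins = bin_arrival_times(source, T)
        if second_channel is None:
            bpos_b, cnt_b = bpos_a, cnt_a
        else:
            bpos_b, cnt_b, n_bins_b = bin_arrival_times(second_channel, T)
            n_bins = min(n_bins, n_bins_b)
        return _sparse_hist(bpos_a, cnt_a, bpos_b, cnt_b, n_bins, tau_k, tau, T)

    counts_a = np.asarray(source)
    counts_b = counts_a if second_channel is None else np.asarray(second_channel)
    n_bins = min(counts_a.size, counts_b.size)
    if tau_k >= n_bins:
        raise InvalidParameterError("lag tau spans the whole trace: no pairs left")
    if tau_k == 0 and second_channel is None:
        a = b = counts_a
    else:
        a = counts_a[: n_bins - tau_k]
        b = counts_b[tau_k:n_bins]
    return histogram_from_pairs(a, b, tau=tau, T=T)


def _sparse_hist(bpos_a, cnt_a, bpos_b, cnt_b, n_bins, tau_k, tau, T) -> CpchHistogram:
    total_pairs = n_bins - tau_k
    if total_pairs <= 0:
        raise InvalidParameterError("lag tau spans the whole trace: no pairs left")
    # first elements: bins i in [1, n_bins - tau_k]; second: bins i + tau_k
    sel_a = bpos_a <= total_pairs
    first_bins, first_cnt = bpos_a[sel_a], cnt_a[sel_a]
    sel_b = bpos_b > tau_k
    second_bins, second_cnt = bpos_b[sel_b] - tau_k, cnt_b[sel_b]

    common, ia, ib = np.intersect1d(first_bins, second_bins, return_indices=True)
    both_a, both_b = first_cnt[ia], second_cnt[ib]
    only_a = np.delete(first_cnt, ia)
    only_b = np.delete(second_cnt, ib)

    La = int(max(first_cnt.max() if first_cnt.size else 0, 0)) + 1
    Lb = int(max(second_cnt.max() if second_cnt.size else 0, 0)) + 1
    hist = np.zeros((La, Lb), dtype=np.int64)
    if both_a.size:
        np.add.at(hist, (both_a, both_b), 1)
    if only_a.size:
        np.add.at(hist, (only_a, np.zeros_like(only_a)), 1)
    if only_b.size:
        np.add.at(hist, (np.zeros_like(only_b), only_b), 1)
    hist[0, 0] = total_pairs - (both_a.size + only_a.size + only_b.size)
    return CpchHistogram(hist, tau=tau, T=T, total_pairs=total_pairs)


# ---------------------------------------------------------------------------
# moments from data
# ---------------------------------------------------------------------------


def raw_moments_from_pairs(
    a: np.ndarray,
    b: np.ndarray,
    orders: Sequence[Order],
    pow_a: Optional[Mapping[int, np.ndarray]] = None,
    pow_b: Optional[Mapping[int, np.ndarray]] = None,
) -> Dict[Order, float]:
    """Raw moments M_{m,n} = <a^m b^n> of paired count arrays.

    ``pow_a``/``pow_b`` may supply precomputed power arrays (views are fine)
    to amortise the cost across many lags.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    N = a.size
    if N == 0:
        raise InvalidParameterError("no pairs")

    def powers(x, cache, k):
        if cache is not None and k in cache:
            return cache[k]
        return x**k

    out = {}
    for m, n in orders:
        if m == 0:
            out[(m, n)] = float(np.sum(powers(b, pow_b, n))) / N
        elif n == 0:
            out[(m, n)] = float(np.sum(powers(a, pow_a, m))) / N
        else:
            out[(m, n)] = float(np.dot(powers(a, pow_a, m), powers(b, pow_b, n))) / N
    return out


def empirical_moments(hist: CpchHistogram, max_order: int = 4) -> CumulantTable:
    """Raw moments M_{m,n}(tau) of a histogram as a CumulantTable (kind 'M')."""
    orders = default_orders(max_order)
    raw = hist.raw_moments(orders)
    records = [
        (m, n, hist.tau, hist.T, raw[(m, n)], np.nan, hist.total_pairs) for (m, n) in orders
    ]
    return CumulantTable.from_records(records, kind="M")


def _rebin(counts: np.ndarray, factor: int) -> np.ndarray:
    n = (counts.size // factor) * factor
    return counts[:n].reshape(-1, factor).sum(axis=1)


def autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocovariance c_0..c_max_lag of a 1D series (FFT-based)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(n + max_lag).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acf / n


def _batch_raw_moments(
    pow_a: Mapping[int, np.ndarray],
    pow_b: Mapping[int, np.ndarray],
    raw_orders: Sequence[Order],
    n_batches: int,
):
    """Full and per-batch raw moments of a paired (possibly sliced) trace.

    The trace is cut into ``n_batches`` contiguous blocks (each much longer
    than the correlation time); per-batch means of a^x b^y support
    batch-means variance estimates of any smooth moment functional.
    Returns (raw, batch_raw, n_used).
    """
    n = min(next(iter(pow_a.values())).size, next(iter(pow_b.values())).size)
    B = max(2, min(n_batches, n // 16))
    L = n // B
    n_used = B * L

    def bmeans(x):
        return x[:n_used].reshape(B, L).mean(axis=1)

    batch = {}
    for x, y in raw_orders:
        if x == 0:
            batch[(x, y)] = bmeans(pow_b[y])
        elif y == 0:
            batch[(x, y)] = bmeans(pow_a[x])
        else:
            batch[(x, y)] = bmeans(pow_a[x] * pow_b[y])
    raw = {o: float(v.mean()) for o, v in batch.items()}
    return raw, batch, n_used


def _batch_variance(raw, batch, target: Order, kind: str = "fK") -> float:
    """Batch-means sampling variance of one (factorial) cumulant.

    First-order delta method with the cumulant's influence function applied
    to the per-batch raw moments: psi_b = sum grad_{x,y} <a^x b^y>_b; the
    variance of the full-trace estimate is var(psi_b)/B.  Unlike the
    independent-points covariance formula, this honours serial correlation
    up to the batch length.
    """
    grads = cumulant_gradients(raw, target, kind)
    psi = None
    for var, g in grads.items():
        term = g * batch[var]
        psi = term if psi is None else psi + term
    if psi is None:
        return 0.0
    B = psi.size
    return float(np.var(psi, ddof=1) / B)


def long_run_variance_inflation(counts: np.ndarray, max_lag: Optional[int] = None) -> float:
    """Variance inflation of the sample mean due to serial correlation.

    Ratio of the long-run variance (c_0 + 2 sum_k (1 - k/N) c_k) to the
    naive iid variance c_0; ~1 for white counts, large when the trace is
    correlated over many bins.  Used to correct the moments-of-moments
    variance of the first factorial cumulants, which assumes independent
    bins.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    if max_lag is None:
        max_lag = min(n // 10, 4096)
    c = autocovariance(counts, max_lag)
    if c[0] <= 0:
        return 1.0
    k = np.arange(1, max_lag + 1)
    lrv = c[0] + 2.0 * np.sum((1.0 - k / n) * c[1:])
    return float(max(lrv / c[0], 1.0))


def cumulant_table_from_counts(
    counts: np.ndarray,
    dt: float,
    taus: Optional[Sequence[float]] = None,
    T: Optional[float] = None,
    scheme: Optional[BinScheme] = None,
    counts_b: Optional[np.ndarray] = None,
    max_order: int = 4,
    orders: Optional[Sequence[Order]] = None,
    first_cumulant_inflation: Union[None, float, str] = None,
    variance_mode: str = "iid",
    n_batches: int = 64,
) -> CumulantTable:
    """Empirical factorial cumulants (K)_{m,n}(tau, T) with variances.

    ``counts`` is a binned trace sampled every ``dt`` seconds; either give a
    flat lag grid (``taus`` at fixed bin ``T``) or a :class:`BinScheme` whose
    bin size grows with the lag (multi-tau).  Counts are re-binned to each T
    by summation.  Variances come from the moments-of-moments delta method
    with N_d = the number of bin pairs at each lag.  That method assumes
    independent data points, which badly undercounts the variance of the
    first-order cumulants (they are sample means of a correlated trace); the
    optional ``first_cumulant_inflation`` multiplies their variance by a
    given factor, or, with "auto", by the trace's own long-run-variance
    ratio (see :func:`long_run_variance_inflation`).  Off by default;
    approximate.

    ``variance_mode="batch"`` replaces the independent-points covariance with
    a batch-means estimate for every order: the cumulant's influence
    function is applied to per-batch raw moments (``n_batches`` contiguous
    blocks) and the variance of the batch means is used, which honours
    serial correlation at all orders up to the batch length.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise InvalidParameterError("counts must be a 1D binned trace per channel")
    if scheme is None:
        if taus is None or T is None:
            raise InvalidParameterError("give either (taus, T) or a BinScheme")
        pairs = [(float(tau), float(T)) for tau in taus]
    else:
        pairs = list(scheme.pairs)
    orders = list(orders) if orders is not None else default_orders(max_order)
    raw_orders = required_raw_orders(orders)
    max_m = max(a for a, b in raw_orders)
    max_n = max(b for a, b in raw_orders)

    records = []
    by_T: Dict[float, List[float]] = {}
    for tau, Tk in pairs:
        by_T.setdefault(Tk, []).append(tau)
    for Tk, tau_list in by_T.items():
        factor = int(round(Tk / dt))
        if factor < 1 or abs(Tk - factor * dt) > 1e-9 * Tk:
            raise InvalidParameterError("each T must be an integer multiple of dt")
        ca = _rebin(counts, factor) if factor > 1 else counts
        cb = ca if counts_b is None else (
            _rebin(np.asarray(counts_b), factor) if factor > 1 else np.asarray(counts_b)
        )
        fa = ca.astype(np.float64)
        fb = cb.astype(np.float64) if counts_b is not None else fa
        if first_cumulant_inflation == "auto":
            max_lag = int(max(round(t / Tk) for t, _ in pairs))
            inflation = long_run_variance_inflation(fa, min(4 * max(max_lag, 16), fa.size // 10))
        else:
            inflation = first_cumulant_inflation
        pow_a = {k: fa**k for k in range(1, max_m + 1)}
        pow_b = pow_a if counts_b is None else {k: fb**k for k in range(1, max_n + 1)}
        for tau in tau_list:
            k = int(round(tau / Tk))
            if abs(tau - k * Tk) > 1e-9 * max(tau, Tk):
                raise InvalidParameterError("tau must be an integer multiple of T")
            if k >= ca.size:
                raise InvalidParameterError("lag tau spans the whole trace")
            if k == 0 and counts_b is None:
                sl_a = {p: v for p, v in pow_a.items()}
                sl_b = sl_a
                N_d = fa.size
            else:
                sl_a = {p: v[: v.size - k] for p, v in pow_a.items()}
                sl_b = {p: v[k:] for p, v in pow_b.items()}
                N_d = fa.size - k
            if variance_mode == "batch":
                raw, batch, n_used = _batch_raw_moments(sl_a, sl_b, raw_orders, n_batches)
                values = {}
                variances = {}
                for o in orders:
                    values[o] = float(
                        _poly_eval_cached(o, raw)
                    )
                    variances[o] = _batch_variance(raw, batch, o)
                N_d = n_used
            else:
                raw = raw_moments_from_pairs(
                    fa[: fa.size - k] if k else fa,
                    (fb if counts_b is not None else fa)[k:],
                    raw_orders,
                    pow_a=sl_a,
                    pow_b=sl_b,
                )
                values, variances = factorial_cumulants_from_raw(raw, orders, N_d)
            for m, n in orders:
                var = variances[(m, n)]
                if variance_mode != "batch" and inflation is not None and m + n == 1:
                    var *= inflation
                records.append((m, n, tau, Tk, values[(m, n)], var, N_d))
    return CumulantTable.from_records(records, kind="fK")


def _poly_eval_cached(order: Order, raw: Mapping[Order, float]) -> float:
    from .moments import cumulant_poly, _poly_eval

    return float(_poly_eval(cumulant_poly(*order, "fK"), raw))


def raw_moment_tables_from_counts(
    counts: np.ndarray, dt: float, taus: Sequence[float], T: float, orders: Sequence[Order]
) -> Dict[float, Dict[Order, float]]:
    """Raw moments per tau (helper for FCS error propagation)."""
    factor = int(round(T / dt))
    ca = _rebin(counts, factor) if factor > 1 else np.asarray(counts)
    fa = ca.astype(np.float64)
    out = {}
    for tau in taus:
        k = int(round(tau / T))
        a = fa[: fa.size - k] if k else fa
        b = fa[k:]
        out[float(tau)] = raw_moments_from_pairs(a, b, orders)
    return out


# ---------------------------------------------------------------------------
# fit energies
# ---------------------------------------------------------------------------


def energy_Ep(
    model_pmfs: Mapping[Tuple[float, float], np.ndarray],
    empirical_hists: Mapping[Tuple[float, float], CpchHistogram],
) -> float:
    """Per-cell fit energy E_p of the cPCH distributions.

    E_p = [1/sum_tau L(tau)] sum_tau sum_cells (p_model - p_emp)^2 / sigma_p^2
    with sigma_p^2 = p_emp (1 - p_emp) / N_d (binomial standard error per
    cell).  Cells with sigma_p = 0 (empirical p of exactly 0 or 1) are
    excluded; the model should score about 1 when correct.
    """
    keys = set(model_pmfs) & set(empirical_hists)
    if set(model_pmfs) != set(empirical_hists):
        raise InvalidParameterError("model and empirical (tau, T) grids do not match")
    total = 0.0
    n_cells = 0
    for key in keys:
        hist = empirical_hists[key]
        p_emp = hist.pmf
        p_mod = np.asarray(model_pmfs[key], dtype=float)
        La = min(p_emp.shape[0], p_mod.shape[0])
        Lb = min(p_emp.shape[1], p_mod.shape[1])
        pe = np.zeros((max(p_emp.shape[0], p_mod.shape[0]), max(p_emp.shape[1], p_mod.shape[1])))
        pm = pe.copy()
        pe[: p_emp.shape[0], : p_emp.shape[1]] = p_emp
        pm[: p_mod.shape[0], : p_mod.shape[1]] = p_mod
        sigma2 = pe * (1.0 - pe) / hist.total_pairs
        ok = sigma2 > 0
        total += float(np.sum((pm[ok] - pe[ok]) ** 2 / sigma2[ok]))
        n_cells += int(np.count_nonzero(ok))
    if n_cells == 0:
        raise InvalidParameterError("no usable histogram cells for E_p")
    return total / n_cells


def energy_EK(model_table: CumulantTable, empirical_table: CumulantTable) -> float:
    """Per-cumulant fit energy E_K (variance-normalised sum of squares).

    E_K = [1/sum_tau L(tau)] sum_tau sum_{m,n} ((K)_model - (K)_emp)^2 /
    sigma_K^2, over the entries shared by the two tables.  Entries with zero
    or missing empirical variance are excluded (with a warning).
    """
    em = empirical_table.data
    mo = model_table.data
    merged = em.merge(
        mo, on=["m", "n", "tau_s", "T_s"], suffixes=("_emp", "_mod"), how="inner"
    )
    if len(merged) != len(em):
        raise InvalidParameterError("model table does not cover the empirical (m,n,tau,T) grid")
    var = merged.variance_emp.to_numpy()
    good = np.isfinite(var) & (var > 0)
    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(f"E_K: excluded {n_bad} entries with zero/missing variance")
    if not np.any(good):
        raise InvalidParameterError("no usable cumulant entries for E_K")
    dev = merged.value_mod.to_numpy()[good] - merged.value_emp.to_numpy()[good]
    return float(np.sum(dev**2 / var[good]) / good.sum())
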