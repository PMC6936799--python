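"""cPCH probability distributions by three routes.

The joint distribution p_N(n_x, n_y | tau) of photon counts in two bins a
lag tau apart is a compound Poisson built from the single-molecule
distribution p_1: molecules enter the observation volume as a Poisson
process, so the N-molecule probability generating function is
exp(N (g_1 - 1)) (times a Poisson background factor per channel).

Routes implemented:

* ``p1_series`` -- the single-molecule distribution as the alternating
  series over its factorial moments (M)_{m,n}(tau, T), which are available
  in closed form for the Gaussian observation volume;
* ``pN_fft`` -- evaluate the generating function on the unit circle with the
  FFT of p_1 and invert (fast, the workhorse);
* ``pN_recursion`` -- the exact recursion seeded at p(0,0) =
  exp(-sum_i N_i (1 - p_1^i(0,0)) - lambda_A - lambda_B), used as an
  independent cross-check of the FFT route.

PCH is the marginal over either axis (independent of tau); dual-colour PCH
is the tau = 0 joint distribution.  For single-channel data at tau = 0 the
two counts are the same number, so the distribution is diagonal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numba
import numpy as np

from .theory import (
    CpchModel,
    InvalidParameterError,
    OpticalConfig,
    SpeciesParams,
    binning_Bmn,
    diffusion_factor,
    shape_factor,
)

__all__ = [
    "JointPMF",
    "SingleMoleculePMF",
    "SeriesConvergenceError",
    "GridTooSmallError",
    "p1_series",
    "pN_fft",
    "pN_recursion",
    "pN_auto",
    "pch_marginal",
    "pch_pmf",
    "dual_color_pch",
]

_K_CAP = 200
_CLIP_FAIL = 1e-6


class SeriesConvergenceError(RuntimeError):
    """The factorial-moment series did not converge; use the FFT route with a
    larger grid or reduce the brightness/bin time."""


class GridTooSmallError(ValueError):
    """Count grid leaves more than the allowed tail mass; enlarge it."""


@dataclass
class SingleMoleculePMF:
    """p_1(n_x, n_y | tau) on a finite count grid (V_AB/V = 1 convention)."""

    values: np.ndarray
    tau: float
    T: float
    truncation: int
    volume_ratio: float = 1.0


@dataclass
class JointPMF:
    """Joint count distribution on [0..L_t-1] x [0..L_s-1] at one (tau, T)."""

    values: np.ndarray
    tau: float
    T: float
    meta: Optional[str] = None
    clip_deficit: float = 0.0

    def marginal(self, axis: int = 1) -> np.ndarray:
        return self.values.sum(axis=axis)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw count pairs from the distribution (returns (n, 2) ints)."""
        p = self.values.ravel()
        p = np.maximum(p, 0)
        p = p / p.sum()
        idx = rng.choice(p.size, size=n, p=p)
        return np.column_stack(np.unravel_index(idx, self.values.shape))


def _factorial_moment_table(
    species: SpeciesParams,
    optical: OpticalConfig,
    tau: float,
    T: float,
    La: int,
    Lb: int,
    binning: str = "continuous",
    dt: Optional[float] = None,
) -> np.ndarray:
    """(M)_{a,b}(tau, T) for a < La, b < Lb (closed form, Eq-of-motion free)."""
    o = optical
    D = species.resolve_D(optical)
    ea = species.eps_A * T
    eb = species.eps_B * T
    tau_A = species.resolve_tau_d(optical, "A")
    tau_B = species.resolve_tau_d(optical, "B")
    beta_A = optical.beta
    beta_B = (optical.r_B / optical.z_B) ** 2
    a = np.arange(La, dtype=float)[:, None]
    b = np.arange(Lb, dtype=float)[None, :]
    tot = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        # shape factor (general two-channel Gaussian form)
        ga = a / o.r_A**2 + b / o.r_B**2
        gb = a / o.z_A**2 + b / o.z_B**2
        den = ((o.r_A**2 + o.r_B**2) / 2.0) * math.sqrt((o.z_A**2 + o.z_B**2) / 2.0)
        gamma = 1.0 / (ga * np.sqrt(gb) * den)
        # diffusion factor
        xr = 8.0 * a * b * D * tau / (b * o.r_A**2 + a * o.r_B**2 + 1e-300)
        xz = 8.0 * a * b * D * tau / (b * o.z_A**2 + a * o.z_B**2 + 1e-300)
        kappa = (1.0 + xr) ** -1.0 * (1.0 + xz) ** -0.5
    # binning: product of per-channel B2 powers
    b2A = binning_Bmn(2, 0, T, tau_A, tau_B, beta_A, beta_B, mode=binning, dt=dt)
    b2B = binning_Bmn(0, 2, T, tau_A, tau_B, beta_A, beta_B, mode=binning, dt=dt)
    B = b2A ** np.maximum(a - 1, 0) * b2B ** np.maximum(b - 1, 0)
    with np.errstate(over="ignore"):  # overflow -> inf, caught by the caller
        tab = ea**a * eb**b * gamma * kappa * B
    tab[0, 0] = 1.0
    return tab


def p1_series(
    species: SpeciesParams,
    optical: OpticalConfig,
    tau: float,
    T: float,
    max_counts: Tuple[int, int] = (16, 16),
    tol: float = 1e-14,
    binning: str = "continuous",
    dt: Optional[float] = None,
) -> SingleMoleculePMF:
    """Single-molecule joint distribution from its factorial moments.

    p_1(n_x, n_y) = sum_k (-1)^k / (n_x! n_y! k!) sum_m C(k, m)
                    (M)_{n_x+k-m, n_y+m}(tau, T),
    truncated adaptively at the k where the largest term contribution drops
    below ``tol`` (hard cap 200, beyond which a
    :class:`SeriesConvergenceError` suggests the FFT route).
    """
    La, Lb = max_counts
    if species.eps_A == 0 and species.eps_B == 0:
        values = np.zeros((La, Lb))
        values[0, 0] = 1.0
        return SingleMoleculePMF(values, tau, T, truncation=0)
    tab = _factorial_moment_table(species, optical, tau, T, La + _K_CAP, Lb + _K_CAP, binning, dt)
    if not np.all(np.isfinite(tab)):
        raise SeriesConvergenceError(
            "factorial moments overflow at the orders the series needs; "
            "the brightness per bin is too large for the series route"
        )
    # work in probability scale: each term divided by nx! ny! (per axis, to
    # avoid overflowing factorial products) so the tolerance is absolute
    lg_a = np.array([math.lgamma(v + 1) for v in range(La)])
    lg_b = np.array([math.lgamma(v + 1) for v in range(Lb)])
    inv_f2 = np.exp(-lg_a)[:, None] * np.exp(-lg_b)[None, :]
    acc = np.zeros((La, Lb))
    inv_fact = 1.0
    converged = False
    k_used = 0
    for k in range(_K_CAP + 1):
        if k > 0:
            inv_fact /= k
        term = np.zeros((La, Lb))
        for m_ in range(k + 1):
            coef = math.comb(k, m_)
            term += coef * tab[k - m_ : k - m_ + La, m_ : m_ + Lb]
        term *= (-1.0) ** k * inv_fact * inv_f2
        acc += term
        k_used = k
        if np.max(np.abs(term)) < tol and k >= 2:
            converged = True
            break
    if not converged:
        raise SeriesConvergenceError(
            "series did not converge within 200 terms; use pN_fft with a larger grid"
        )
    return SingleMoleculePMF(acc, tau, T, truncation=k_used)


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1)).bit_length()


def _channel_grid(model: CpchModel, T: float, nsigma: float = 10.0) -> Tuple[int, int]:
    mean_a = model.lambda_A * T + sum(sp.N * sp.eps_A * T for sp in model.species)
    mean_b = model.lambda_B * T + sum(sp.N * sp.eps_B * T for sp in model.species)
    var_a = mean_a + sum(
        sp.N * (sp.eps_A * T) ** 2 * shape_factor(2, 0, model.optical) for sp in model.species
    )
    var_b = mean_b + sum(
        sp.N * (sp.eps_B * T) ** 2 * shape_factor(0, 2, model.optical) for sp in model.species
    )
    La = int(math.ceil(mean_a + nsigma * math.sqrt(var_a))) + 8
    Lb = int(math.ceil(mean_b + nsigma * math.sqrt(var_b))) + 8
    return La, Lb


def pN_fft(
    model: CpchModel,
    tau: float,
    T: float,
    L_t: int,
    L_s: int,
    binning: str = "continuous",
    dt: Optional[float] = None,
    tail_tol: float = 1e-9,
) -> JointPMF:
    """N-molecule cPCH distribution via the generating function and FFT.

    exp(sum_q N_q (g_1^(q) - 1) + background) is evaluated on the FFT grid
    (padded to at least twice the requested size to suppress circular
    aliasing) and inverted; tiny negative ringing (> -1e-12) is clipped and
    the distribution renormalised.  Raises :class:`GridTooSmallError` if the
    marginal tail mass on the requested grid exceeds ``tail_tol``.
    """
    Pa = _next_pow2(2 * L_t)
    Pb = _next_pow2(2 * L_s)
    acc = np.zeros((Pa, Pb), dtype=complex)
    for sp in model.species:
        if sp.N == 0:
            continue
        p1 = p1_series(sp, model.optical, tau, T, (min(L_t + 24, Pa), min(L_s + 24, Pb)),
                       binning=binning, dt=dt)
        pad = np.zeros((Pa, Pb))
        pad[: p1.values.shape[0], : p1.values.shape[1]] = p1.values
        g1 = np.fft.fft2(pad)
        acc += sp.N * (g1 - 1.0)
    ka = np.exp(-2j * np.pi * np.arange(Pa) / Pa) - 1.0
    kb = np.exp(-2j * np.pi * np.arange(Pb) / Pb) - 1.0
    acc += (model.lambda_A * T) * ka[:, None] + (model.lambda_B * T) * kb[None, :]
    full = np.fft.ifft2(np.exp(acc)).real
    neg = full.min()
    clip = float(-neg) if neg < 0 else 0.0
    if clip > _CLIP_FAIL:
        raise GridTooSmallError(f"FFT ringing too large (max clip {clip:.2e}); enlarge grid")
    full = np.clip(full, 0.0, None)
    full /= full.sum()
    vals = full[:L_t, :L_s]
    # tail mass check: anything outside the requested window
    outside = 1.0 - vals.sum()
    if outside > tail_tol:
        raise GridTooSmallError(
            f"tail mass {outside:.2e} outside the [{L_t},{L_s}] grid; enlarge it"
        )
    vals = vals / vals.sum()
    return JointPMF(values=vals, tau=tau, T=T, clip_deficit=clip)


@numba.njit(cache=True)
def _recursion_kernel(W, lamA, lamB, p00, L):
    p = np.zeros((L, L))
    p[0, 0] = p00
    for ny in range(1, L):
        acc = lamB * p[0, ny - 1]
        for q in range(1, ny + 1):
            acc += q * p[0, ny - q] * W[0, q]
        p[0, ny] = acc / ny
    for nx in range(1, L):
        acc = lamA * p[nx - 1, 0]
        for q in range(1, nx + 1):
            acc += q * p[nx - q, 0] * W[q, 0]
        p[nx, 0] = acc / nx
        for ny in range(1, L):
            acc = lamA * p[nx - 1, ny]
            for z in range(0, ny + 1):
                for q in range(1, nx + 1):
                    acc += q * p[nx - q, ny - z] * W[q, z]
            p[nx, ny] = acc / nx
    return p


def pN_recursion(
    model: CpchModel,
    tau: float,
    T: float,
    max_counts: int,
    binning: str = "continuous",
    dt: Optional[float] = None,
) -> JointPMF:
    """N-molecule cPCH distribution via the exact recursion.

    Seeds p(0,0) = exp(-sum_i N_i (1 - p_1^i(0,0)) - lambda_A - lambda_B),
    then fills the n_x = 0 column, the n_y = 0 row, and the interior, in that
    order.  O(L^4); intended for moderate grids and as the independent oracle
    for the FFT route.
    """
    L = max_counts
    W = np.zeros((L, L))
    expo = -(model.lambda_A + model.lambda_B) * T
    for sp in model.species:
        if sp.N == 0:
            continue
        p1 = p1_series(sp, model.optical, tau, T, (L, L), binning=binning, dt=dt)
        W += sp.N * p1.values
        expo -= sp.N * (1.0 - p1.values[0, 0])
    if expo < -700.0:
        raise InvalidParameterError(
            "recursion seed underflows (occupancy too high); use the FFT route"
        )
    p00 = math.exp(expo)
    vals = _recursion_kernel(W, model.lambda_A * T, model.lambda_B * T, p00, L)
    return JointPMF(values=vals, tau=tau, T=T)


def pN_auto(
    model: CpchModel,
    tau: float,
    T: float,
    binning: str = "continuous",
    dt: Optional[float] = None,
) -> JointPMF:
    """FFT-route distribution on an automatically sized grid."""
    La, Lb = _channel_grid(model, T)
    return pN_fft(model, tau, T, La, Lb, binning=binning, dt=dt)


def pch_marginal(pmf: JointPMF, axis: int = 0) -> np.ndarray:
    """PCH: the 1D count distribution, summing the other axis of the joint.

    Independent of tau (a molecule's instantaneous emission statistics do
    not depend on when the other bin was recorded).
    """
    return pmf.values.sum(axis=1 - axis)


def pch_pmf(
    model: CpchModel,
    T: float,
    max_counts: Optional[int] = None,
    binning: str = "continuous",
    dt: Optional[float] = None,
) -> np.ndarray:
    """Single-channel (channel A) PCH distribution p_N(n) at bin time T."""
    pmf = pN_auto(model, tau=0.0, T=T, binning=binning, dt=dt)
    out = pch_marginal(pmf, axis=0)
    if max_counts is not None:
        if max_counts > out.size:
            out = np.pad(out, (0, max_counts - out.size))
        out = out[:max_counts]
    return out


def dual_color_pch(
    model: CpchModel,
    T: float,
    max_counts: Optional[Tuple[int, int]] = None,
    binning: str = "continuous",
    dt: Optional[float] = None,
) -> JointPMF:
    """Dual-colour PCH: the cPCH distribution at zero time shift.

    With two distinct channels this is the full joint distribution at
    tau = 0.  In single-channel mode the two counts are literally the same
    bin, so the joint distribution is zero off the diagonal; a warning is
    issued and the diagonal form is returned.
    """
    if model.optical.identical_channels and all(
        sp.eps_A == sp.eps_B for sp in model.species
    ):
        warnings.warn(
            "single-channel tau=0 distribution is diagonal (each bin compared "
            "with itself); returning the diagonal form"
        )
        pch = pch_pmf(model, T, binning=binning, dt=dt)
        L = pch.size if max_counts is None else max_counts[0]
        vals = np.zeros((L, L))
        np.fill_diagonal(vals, pch[:L] if pch.size >= L else np.pad(pch, (0, L - pch.size)))
        return JointPMF(values=vals, tau=0.0, T=T)
    if max_counts is None:
        return pN_auto(model, 0.0, T, binning=binning, dt=dt)
    return pN_fft(model, 0.0, T, max_counts[0], max_counts[1], binning=binning, dt=dt)
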