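"""Closed-form building blocks of cPCH theory.

The observation volume of a confocal / two-channel instrument is modelled as a
3D Gaussian intensity profile per channel,

    I_A(x) = eps_A * exp(-2(x^2+y^2)/r_A^2 - 2 z^2/z_A^2),

with radial and axial 1/e^2 beam-waist parameters ``r_A`` and ``z_A`` and the
molecular brightness ``eps_A`` (detected counts from one molecule at beam
centre).  Everything in this module is an analytic consequence of that
profile: the effective two-channel observation volume ``V_AB``, the shape
factors ``gamma_{m,n}`` (normalised spatial moments of the PSF product), the
diffusion decay ``kappa_{m,n}(tau, D)`` of the higher-order two-point
correlation functions, the flow/scanning factor ``S_{m,n}``, the binning
functions ``B_2`` / ``B_{m,n}`` that correct for molecular motion during a
long counting bin ``T``, and the factorial cumulants ``(K)_{m,n}(tau, T)`` of
the photon counts for a mixture of diffusing species plus Poisson background.

Units: lengths in um, times in s, diffusion coefficients in um^2/s,
brightnesses canonically in counts/s (``eps_o``); counts/bin values are
``eps_o * T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "InvalidParameterError",
    "UnitError",
    "OpticalConfig",
    "SpeciesParams",
    "CpchModel",
    "BinScheme",
    "observation_volume",
    "shape_factor",
    "diffusion_factor",
    "flow_factor",
    "correlation_G",
    "binning_B2",
    "binning_B2_discrete",
    "binning_Bmn",
    "factorial_cumulant",
    "tau_d_from_D",
    "D_from_tau_d",
]


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class UnitError(ValueError):
    """Inconsistent brightness/time units (counts/bin vs counts/s)."""


def tau_d_from_D(D: float, r: float) -> float:
    """Radial diffusion time tau_d = r^2 / (4 D) of a 3D Gaussian beam."""
    if D <= 0 or r <= 0:
        raise InvalidParameterError("D and r must be positive")
    return r * r / (4.0 * D)


def D_from_tau_d(tau_d: float, r: float) -> float:
    if tau_d <= 0 or r <= 0:
        raise InvalidParameterError("tau_d and r must be positive")
    return r * r / (4.0 * tau_d)


@dataclass(frozen=True)
class OpticalConfig:
    """Beam geometry of the two detection channels.

    ``r_*``/``z_*`` are the radial and axial 1/e^2 beam-waist parameters in
    um.  Channel B defaults to a copy of channel A (single-colour mode).
    """

    r_A: float
    z_A: float
    r_B: Optional[float] = None
    z_B: Optional[float] = None

    def __post_init__(self):
        if self.r_B is None:
            object.__setattr__(self, "r_B", self.r_A)
        if self.z_B is None:
            object.__setattr__(self, "z_B", self.z_A)
        for name in ("r_A", "z_A", "r_B", "z_B"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @property
    def identical_channels(self) -> bool:
        return self.r_A == self.r_B and self.z_A == self.z_B

    @property
    def s(self) -> float:
        """Structure factor s = z_A / r_A (axial-to-radial waist ratio)."""
        return self.z_A / self.r_A

    @property
    def beta(self) -> float:
        """beta = (r_A/z_A)^2 = 1/s^2, the binning-function shape parameter."""
        return (self.r_A / self.z_A) ** 2

    @classmethod
    def from_structure_factor(cls, r: float, s: float) -> "OpticalConfig":
        return cls(r_A=r, z_A=s * r)


@dataclass(frozen=True)
class SpeciesParams:
    """One fluorescent species: occupancy, brightness, mobility.

    ``N`` is the mean molecule count in the observation volume ``V_AB``.
    ``eps_A``/``eps_B`` are brightnesses in counts/s (``eps_o``); use
    :meth:`from_counts_per_bin` when the natural unit is counts per bin.
    Exactly one of ``D`` (um^2/s) or ``tau_d`` (s) must be given; the other
    is derived through tau_d = r_A^2/(4D) once the optics are known.
    """

    N: float
    eps_A: float
    eps_B: Optional[float] = None
    D: Optional[float] = None
    tau_d: Optional[float] = None

    def __post_init__(self):
        if self.eps_B is None:
            object.__setattr__(self, "eps_B", self.eps_A)
        if self.N < 0:
            raise InvalidParameterError("N must be >= 0")
        if self.eps_A < 0 or self.eps_B < 0:
            raise InvalidParameterError("brightness must be >= 0")
        if (self.D is None) == (self.tau_d is None):
            raise InvalidParameterError("give exactly one of D or tau_d")
        if self.D is not None and self.D < 0:
            raise InvalidParameterError("D must be >= 0")
        if self.tau_d is not None and self.tau_d <= 0:
            raise InvalidParameterError("tau_d must be > 0")

    @classmethod
    def from_counts_per_bin(
        cls,
        N: float,
        eps_A_bin: float,
        T: float,
        eps_B_bin: Optional[float] = None,
        D: Optional[float] = None,
        tau_d: Optional[float] = None,
    ) -> "SpeciesParams":
        """Build from brightness in counts per bin of duration ``T`` seconds."""
        if T <= 0:
            raise UnitError("reference bin time T must be > 0 to convert counts/bin")
        eps_B = None if eps_B_bin is None else eps_B_bin / T
        return cls(N=N, eps_A=eps_A_bin / T, eps_B=eps_B, D=D, tau_d=tau_d)

    def resolve_D(self, optical: OpticalConfig) -> float:
        if self.D is not None:
            return self.D
        return D_from_tau_d(self.tau_d, optical.r_A)

    def resolve_tau_d(self, optical: OpticalConfig, channel: str = "A") -> float:
        r = optical.r_A if channel == "A" else optical.r_B
        if self.D is not None:
            if self.D == 0.0:
                return math.inf
            return tau_d_from_D(self.D, r)
        if channel == "A":
            return self.tau_d
        return self.tau_d * (r / optical.r_A) ** 2


@dataclass(frozen=True)
class CpchModel:
    """Optical geometry + species mixture + Poisson backgrounds (+ flow).

    Backgrounds are rates in counts/s (``lambda_A * T`` counts per bin of
    length ``T``).  ``flow`` is an optional (v_x, v_y) in um/s.
    """

    optical: OpticalConfig
    species: Tuple[SpeciesParams, ...]
    lambda_A: float = 0.0
    lambda_B: float = 0.0
    flow: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if len(self.species) < 1:
            raise InvalidParameterError("need at least one species")
        if self.lambda_A < 0 or self.lambda_B < 0:
            raise InvalidParameterError("backgrounds must be >= 0")

    def with_species(self, species) -> "CpchModel":
        return replace(self, species=tuple(species))


@dataclass(frozen=True)
class BinScheme:
    """Lag/bin pairs (tau_k, T_k) on a detector clock.

    Each T must be an integer multiple of ``sampling_time`` and each tau an
    integer multiple of its T (tau = 0 allowed: the same-bin diagonal).
    """

    pairs: Tuple[Tuple[float, float], ...]
    sampling_time: float

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple((float(t), float(T)) for t, T in self.pairs))
        if self.sampling_time <= 0:
            raise InvalidParameterError("sampling_time must be > 0")
        for tau, T in self.pairs:
            if T <= 0:
                raise InvalidParameterError("T must be > 0")
            if tau < 0:
                raise InvalidParameterError("tau must be >= 0")
            if not _is_int_multiple(T, self.sampling_time):
                raise InvalidParameterError(
                    f"T={T} is not an integer multiple of the sampling time"
                )
            if tau > 0 and not _is_int_multiple(tau, T):
                raise InvalidParameterError(f"tau={tau} is not an integer multiple of T={T}")

    @classmethod
    def multitau(
        cls,
        sampling_time: float,
        t_min: float,
        t_max: float,
        points_per_octave: int = 4,
    ) -> "BinScheme":
        """Geometric lag grid: T doubles every ``points_per_octave`` lags.

        Starts at tau = T = t_min and grows until tau would exceed the range
        implied by ``t_max`` (the largest bin size used).
        """
        pairs = []
        T = max(round(t_min / sampling_time), 1)
        tau = T
        while T * sampling_time <= t_max + 1e-15:
            for _ in range(points_per_octave):
                pairs.append((tau * sampling_time, T * sampling_time))
                tau += T
            T *= 2
            tau = (tau // T + (tau % T > 0)) * T
        return cls(pairs=tuple(pairs), sampling_time=sampling_time)


def _is_int_multiple(a: float, b: float, rtol: float = 1e-9) -> bool:
    k = round(a / b)
    return k >= 1 and abs(a - k * b) <= rtol * a


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def observation_volume(optical: OpticalConfig) -> float:
    """Effective two-channel observation volume V_AB in um^3.

    V_AB = (pi/2)^{3/2} ((r_A^2+r_B^2)/2) ((z_A^2+z_B^2)/2)^{1/2}; reduces to
    (pi/2)^{3/2} r^2 z for identical channels.
    """
    o = optical
    return (
        (math.pi / 2.0) ** 1.5
        * ((o.r_A**2 + o.r_B**2) / 2.0)
        * math.sqrt((o.z_A**2 + o.z_B**2) / 2.0)
    )


def shape_factor(m: int, n: int, optical: Optional[OpticalConfig] = None) -> float:
    """Shape factor gamma_{m,n} of the Gaussian observation volume.

    gamma_{m,n} = (1/V_AB) * integral (I_A/eps_A)^m (I_B/eps_B)^n dx.  For
    identical channels this is (m+n)^{-3/2}.  The general form follows from
    the Gaussian integrals: with a = m/r_A^2 + n/r_B^2 and
    b = m/z_A^2 + n/z_B^2 the integral is (pi/2)^{3/2} a^{-1} b^{-1/2}.
    """
    if m < 0 or n < 0 or m + n < 1:
        raise InvalidParameterError("shape factor requires m,n >= 0 and m+n >= 1")
    if optical is None or optical.identical_channels:
        return float(m + n) ** -1.5
    o = optical
    a = m / o.r_A**2 + n / o.r_B**2
    b = m / o.z_A**2 + n / o.z_B**2
    num = a ** -1.0 * b ** -0.5
    den = ((o.r_A**2 + o.r_B**2) / 2.0) * math.sqrt((o.z_A**2 + o.z_B**2) / 2.0)
    return num / den


def diffusion_factor(m: int, n: int, tau, D: float, optical: OpticalConfig):
    """Diffusion decay kappa_{m,n}(tau, D) of the two-point correlation.

    kappa = [1 + 8mnD tau/(n r_A^2 + m r_B^2)]^-1
            [1 + 8mnD tau/(n z_A^2 + m z_B^2)]^-1/2,
    normalised so kappa(0) = 1; kappa = 1 for all tau when m*n = 0.
    Accepts scalar or array ``tau``.
    """
    if m < 0 or n < 0 or m + n < 1:
        raise InvalidParameterError("diffusion factor requires m,n >= 0 and m+n >= 1")
    if D < 0:
        raise InvalidParameterError("D must be >= 0")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidParameterError("tau must be >= 0")
    if m * n == 0 or D == 0:
        out = np.ones_like(tau)
        return float(out) if out.ndim == 0 else out
    o = optical
    xr = 8.0 * m * n * D * tau / (n * o.r_A**2 + m * o.r_B**2)
    xz = 8.0 * m * n * D * tau / (n * o.z_A**2 + m * o.z_B**2)
    out = (1.0 + xr) ** -1.0 * (1.0 + xz) ** -0.5
    return float(out) if out.ndim == 0 else out


def flow_factor(
    m: int,
    n: int,
    tau,
    D: float,
    v_x: float,
    v_y: float,
    optical: OpticalConfig,
):
    """Flow/scanning suppression S_{m,n}(tau) of the correlation function.

    S = exp[-2mn tau^2 (v_x^2+v_y^2) / ((n r_A^2 + m r_B^2)
            (1 + 8mnD tau/(n r_A^2 + m r_B^2)))];
    S = 1 when v = 0 or when m*n = 0.
    """
    if m < 0 or n < 0 or m + n < 1:
        raise InvalidParameterError("flow factor requires m,n >= 0 and m+n >= 1")
    if not (np.isfinite(v_x) and np.isfinite(v_y)):
        raise InvalidParameterError("flow velocity components must be finite")
    tau = np.asarray(tau, dtype=float)
    if m * n == 0 or (v_x == 0.0 and v_y == 0.0):
        out = np.ones_like(tau)
        return float(out) if out.ndim == 0 else out
    o = optical
    r2 = n * o.r_A**2 + m * o.r_B**2
    out = np.exp(
        -2.0 * m * n * tau**2 * (v_x**2 + v_y**2) / (r2 * (1.0 + 8.0 * m * n * D * tau / r2))
    )
    return float(out) if out.ndim == 0 else out


def flow_factor_displacement(
    m: int,
    n: int,
    tau: float,
    D: float,
    dx_um: float,
    dy_um: float,
    optical: OpticalConfig,
):
    """Flow factor parameterised by the displacement (v tau) in um.

    For raster scanning the physical displacement between pixels, not the
    nominal velocity, sets the suppression: v_x tau = d_x delta_x etc.
    """
    if m * n == 0 or (dx_um == 0.0 and dy_um == 0.0):
        return 1.0
    o = optical
    r2 = n * o.r_A**2 + m * o.r_B**2
    return math.exp(
        -2.0 * m * n * (dx_um**2 + dy_um**2) / (r2 * (1.0 + 8.0 * m * n * D * tau / r2))
    )


def correlation_G(
    m: int,
    n: int,
    tau,
    species: SpeciesParams,
    optical: OpticalConfig,
    T: float = 1.0,
    flow: Optional[Tuple[float, float]] = None,
):
    """Higher-order two-point correlation G_{m,n}(tau) for one species.

    G = (eps_A T)^m (eps_B T)^n gamma_{m,n} kappa_{m,n}(tau, D) [S_{m,n}].
    ``T`` converts the canonical counts/s brightnesses to counts/bin; with
    the default T=1 the species brightnesses are used as-is.
    """
    if m < 0 or n < 0 or m + n < 1:
        raise InvalidParameterError("correlation order requires m+n >= 1")
    D = species.resolve_D(optical)
    g = shape_factor(m, n, optical)
    out = (
        (species.eps_A * T) ** m
        * (species.eps_B * T) ** n
        * g
        * diffusion_factor(m, n, tau, D, optical)
    )
    if flow is not None:
        out = out * flow_factor(m, n, tau, D, flow[0], flow[1], optical)
    return out


# ---------------------------------------------------------------------------
# binning functions
# ---------------------------------------------------------------------------

_BETA_LO = 1e-6
_BETA_HI = 1.0 - 1e-9


def binning_B2(T, tau_d: float, beta: float):
    """Second-order binning function B_2(T, tau_d) of a 3D Gaussian volume.

    B_2 = (2/T^2) * int_0^T (T-t) kappa_{1,1}(t) dt evaluated in closed form,
    with alpha = T/tau_d and beta = (r/z)^2:

        B_2 = 4/(alpha^2 beta) [ beta(1+alpha)/sqrt(1-beta)
              * atanh( sqrt(1-beta)(W-1) / (beta + W - 1) ) + 1 - W ],
        W = sqrt(1 + alpha beta).

    A fourth-order series is used for alpha < 1e-3 where the closed form
    cancels catastrophically; B_2 -> 1 as alpha -> 0.  ``beta`` is clamped to
    [1e-6, 1 - 1e-9] because the atanh argument hits a branch limit at
    beta -> 1 (spherical volume).
    """
    if tau_d <= 0:
        raise InvalidParameterError("tau_d must be > 0")
    if beta <= 0 or beta > 1:
        raise InvalidParameterError("beta must lie in (0, 1]")
    beta = min(max(beta, _BETA_LO), _BETA_HI)
    alpha = np.asarray(T, dtype=float) / tau_d
    if np.any(alpha <= 0):
        raise InvalidParameterError("T must be > 0")
    scalar = alpha.ndim == 0
    alpha = np.atleast_1d(alpha)
    out = np.empty_like(alpha)
    small = alpha < 1e-3
    if np.any(small):
        a = alpha[small]
        c1 = -(1.0 + beta / 2.0)
        c2 = 1.0 + beta / 2.0 + 3.0 * beta**2 / 8.0
        c3 = -(1.0 + beta / 2.0 + 3.0 * beta**2 / 8.0 + 5.0 * beta**3 / 16.0)
        out[small] = 1.0 + c1 * a / 3.0 + c2 * a**2 / 6.0 + c3 * a**3 / 10.0
    if np.any(~small):
        a = alpha[~small]
        W = np.sqrt(1.0 + a * beta)
        c = math.sqrt(1.0 - beta)
        at = np.arctanh(c * (W - 1.0) / (beta + W - 1.0))
        out[~small] = 4.0 / (a**2 * beta) * (beta * (1.0 + a) / c * at + 1.0 - W)
    return float(out[0]) if scalar else out


def binning_B2_discrete(T: float, dt: float, tau_d: float, beta: float) -> float:
    """Binning function for counts re-binned from a discrete sampling clock.

    When the raw data are sampled at interval ``dt`` with positions frozen
    within each sample (as in the discrete-time simulator), the exact
    second-order correction for a bin of M = T/dt samples is the double
    average of kappa_{1,1} over the sub-bin lag grid:

        B_2 = (1/M^2) [ M + 2 sum_{k=1}^{M-1} (M-k) kappa_{1,1}(k dt) ].

    Equals 1 at T = dt and converges to the continuous B_2 as M -> inf.
    """
    M = int(round(T / dt))
    if M < 1 or abs(T - M * dt) > 1e-9 * T:
        raise InvalidParameterError("T must be an integer multiple of dt")
    if M == 1:
        return 1.0
    k = np.arange(1, M)
    kk = (1.0 + k * dt / tau_d) ** -1.0 * (1.0 + beta * k * dt / tau_d) ** -0.5
    return float((M + 2.0 * np.sum((M - k) * kk)) / M**2)


def binning_Bmn(
    m: int,
    n: int,
    T: float,
    tau_A: float,
    tau_B: float,
    beta_A: float,
    beta_B: Optional[float] = None,
    mode: str = "continuous",
    dt: Optional[float] = None,
) -> float:
    """Higher-order binning function B_{m,n} via the product approximation.

    B_{m,n} = B_2(T, tau_A)^{m-1} * B_2(T, tau_B)^{n-1} (each factor dropped
    when its channel order is 0), so B_{1,0} = B_{0,1} = B_{1,1} = 1.
    ``mode`` selects the continuous closed form ("continuous"), the
    discrete-sampling form ("discrete", requires ``dt``), or no correction
    ("none").
    """
    if m < 0 or n < 0 or m + n < 1:
        raise InvalidParameterError("binning order requires m+n >= 1")
    if mode == "none":
        return 1.0
    if beta_B is None:
        beta_B = beta_A

    def b2(tau_d, beta):
        if not math.isfinite(tau_d):
            return 1.0
        if mode == "continuous":
            return binning_B2(T, tau_d, beta)
        if mode == "discrete":
            if dt is None:
                raise InvalidParameterError("discrete binning mode requires dt")
            return binning_B2_discrete(T, dt, tau_d, beta)
        raise InvalidParameterError(f"unknown binning mode {mode!r}")

    out = 1.0
    if m > 1:
        out *= b2(tau_A, beta_A) ** (m - 1)
    if n > 1:
        out *= b2(tau_B, beta_B) ** (n - 1)
    return out


# ---------------------------------------------------------------------------
# factorial cumulants of a model
# ---------------------------------------------------------------------------


def _species_G(m, n, tau_arr, T, sp, o, binning, dt, flow):
    """(eps_A T)^m (eps_B T)^n gamma kappa B [S] for one species."""
    D = sp.resolve_D(o)
    g = shape_factor(m, n, o)
    kappa = diffusion_factor(m, n, tau_arr, D, o)
    B = binning_Bmn(
        m,
        n,
        T,
        sp.resolve_tau_d(o, "A"),
        sp.resolve_tau_d(o, "B"),
        o.beta,
        (o.r_B / o.z_B) ** 2,
        mode=binning if m + n > 1 else "none",
        dt=dt,
    )
    out = (sp.eps_A * T) ** m * (sp.eps_B * T) ** n * g * kappa * B
    if flow is not None:
        out = out * flow_factor(m, n, tau_arr, D, flow[0], flow[1], o)
    return out


def factorial_cumulant(
    m: int,
    n: int,
    tau,
    T: float,
    model: CpchModel,
    binning: str = "continuous",
    dt: Optional[float] = None,
    closed_box_p: float = 0.0,
):
    """Model factorial cumulant (K)_{m,n}(tau, T) of the photon counts.

    First order: (K)_{1,0} = lambda_A T + sum_i N_i (eps_A,i T) gamma_{1,0}
    (and symmetrically for (0,1)); the Poisson background contributes only at
    first order.  Higher orders:

        (K)_{m,n} = gamma_{m,n} sum_i N_i (eps_A,i T)^m (eps_B,i T)^n
                    kappa_{m,n}(tau, D_i) B_{m,n}(T, tau_i)

    with the binning mode of :func:`binning_Bmn`.  ``tau`` may be an array.

    ``closed_box_p`` applies the leading closed-volume (canonical-ensemble)
    correction: when the number of molecules in a finite volume V is fixed,
    the occupancy of the observation volume is binomial rather than Poisson
    and the cumulants of order >= 2 are depressed.  With p = V_AB/V the
    generating function is N log(1 + p(g1-1))/p instead of N (g1-1), whose
    first-order-in-p term subtracts (p/2) N_i times the convolution square
    of the single-molecule factorial moments.  p = 0 (open volume, exact
    compound Poisson) is the default; the correction matters only for
    simulations in small periodic boxes.
    """
    if m < 0 or n < 0 or m + n < 1:
        raise InvalidParameterError("cumulant order requires m+n >= 1")
    if T <= 0:
        raise UnitError("bin time T must be > 0 (brightness is counts/s)")
    o = model.optical
    tau_arr = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau_arr)
    for sp in model.species:
        term = sp.N * _species_G(m, n, tau_arr, T, sp, o, binning, dt, model.flow)
        if closed_box_p > 0.0 and m + n >= 2:
            corr = np.zeros_like(tau_arr)
            for a in range(m + 1):
                for b in range(n + 1):
                    if (a, b) == (0, 0) or (a, b) == (m, n):
                        continue
                    c = math.comb(m, a) * math.comb(n, b)
                    corr = corr + c * _species_G(a, b, tau_arr, T, sp, o, binning, dt, model.flow) * _species_G(
                        m - a, n - b, tau_arr, T, sp, o, binning, dt, model.flow
                    )
            term = term - 0.5 * closed_box_p * sp.N * corr
        out = out + term
    if m + n == 1:
        out = out + (model.lambda_A if m == 1 else model.lambda_B) * T
    return float(out) if out.ndim == 0 else out
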