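"""Analytic two-species solution from 1D factorial cumulants.

For two species resolved by brightness alone, the first four factorial
cumulants obey (K)_n = gamma_n (N1 eps1^n + N2 eps2^n).  Writing
a_n = (K)_n / gamma_n, the brightnesses are the two roots of the quadratic
x^2 - c1 x - c0 whose coefficients solve the 2x2 Hankel system

    a3 = c1 a2 + c0 a1,      a4 = c1 a3 + c0 a2,

(the classic Prony/method-of-moments inversion; algebraically equivalent to
solving the quartic system directly), after which N1, N2 follow linearly
from a1, a2.  The solution is unique up to the species labels; statistical
noise in the empirical cumulants can push it off the physical domain
(negative or complex values), which is flagged rather than raised.  Sampling
cumulants within their moments-of-moments errors and inverting each draw
yields an efficient sampler of plausible (N, eps) sets used to initialise
the fitting algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .theory import InvalidParameterError

__all__ = ["TwoSpeciesSolution", "invert_two_species", "sample_parameter_sets", "forward_cumulants"]

_DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class TwoSpeciesSolution:
    """One inversion result; species sorted so that eps1 >= eps2."""

    N1: float
    eps1: float
    N2: float
    eps2: float
    physical: bool
    degenerate: bool = False  # data consistent with a single species
    cumulants: Optional[Tuple[float, float, float, float]] = None
    gammas: Optional[Tuple[float, float, float, float]] = None

    def as_array(self) -> np.ndarray:
        return np.array([self.N1, self.eps1, self.N2, self.eps2])


def forward_cumulants(
    N1: float, eps1: float, N2: float, eps2: float, gammas: Sequence[float]
) -> np.ndarray:
    """(K)_n = gamma_n (N1 eps1^n + N2 eps2^n) for n = 1..len(gammas)."""
    g = np.asarray(gammas, dtype=float)
    n = np.arange(1, g.size + 1)
    return g * (N1 * eps1**n + N2 * eps2**n)


def invert_two_species(
    K: Sequence[float], gammas: Sequence[float]
) -> TwoSpeciesSolution:
    """Recover (N1, eps1, N2, eps2) from factorial cumulants (K)_1..(K)_4.

    Exact on noiseless inputs.  When the Hankel determinant vanishes (the
    data are consistent with a single species) the single-species solution is
    returned in species 1 with ``degenerate=True``.  Noisy inputs can produce
    complex or negative intermediate values; these are returned with
    ``physical=False`` (with real parts) instead of raising.
    """
    K = [float(k) for k in K]
    gammas = [float(g) for g in gammas]
    if len(K) < 4 or len(gammas) < 4:
        raise InvalidParameterError("need cumulants and shape factors up to fourth order")
    if any(g <= 0 for g in gammas[:4]):
        raise InvalidParameterError("shape factors must be positive")
    if not all(math.isfinite(k) for k in K[:4]):
        raise InvalidParameterError("cumulants must be finite")
    a = [K[i] / gammas[i] for i in range(4)]
    det = a[1] * a[1] - a[0] * a[2]
    scale = max(abs(a[1] * a[1]), abs(a[0] * a[2]), 1e-300)
    src = (tuple(K[:4]), tuple(gammas[:4]))
    if abs(det) <= _DEGENERACY_RTOL * scale:
        # single species: eps = a2/a1, N = a1^2/a2
        if a[0] <= 0 or a[1] <= 0:
            return TwoSpeciesSolution(0, 0, 0, 0, False, True, *src)
        eps = a[1] / a[0]
        return TwoSpeciesSolution(
            a[0] ** 2 / a[1], eps, 0.0, 0.0, physical=a[0] > 0, degenerate=True,
            cumulants=src[0], gammas=src[1],
        )
    c1 = (a[2] * a[1] - a[0] * a[3]) / det
    c0 = (a[1] * a[3] - a[2] * a[2]) / det
    disc = c1 * c1 + 4.0 * c0
    physical = disc >= 0
    sq = math.sqrt(abs(disc))
    eps1 = (c1 + sq) / 2.0
    eps2 = (c1 - sq) / 2.0
    if eps1 == eps2:
        return TwoSpeciesSolution(0, eps1, 0, eps2, False, False, *src)
    # linear solve for N1, N2 from a1 = N1 e1 + N2 e2, a2 = N1 e1^2 + N2 e2^2
    N1 = (a[1] - eps2 * a[0]) / (eps1 * (eps1 - eps2))
    N2 = (a[0] * eps1 - a[1]) / (eps2 * (eps1 - eps2)) if eps2 != 0 else math.nan
    physical = (
        physical
        and all(math.isfinite(v) for v in (N1, N2, eps1, eps2))
        and min(N1, N2) >= 0
        and min(eps1, eps2) > 0
    )
    if eps1 < eps2:
        eps1, eps2, N1, N2 = eps2, eps1, N2, N1
    return TwoSpeciesSolution(N1, eps1, N2, eps2, bool(physical), False, *src)


def sample_parameter_sets(
    K: Sequence[float],
    variances: Sequence[float],
    n_samples: int,
    gammas: Sequence[float],
    seed: int = 0,
    max_attempts_factor: int = 200,
) -> List[TwoSpeciesSolution]:
    """Physical two-species solutions sampled within the cumulant errors.

    Each factorial cumulant is drawn from an independent Gaussian centred on
    its empirical value with the moments-of-moments variance
    (cumulant-cumulant covariances are ignored, an approximation), then
    inverted; non-physical draws are discarded.  Reproducible under ``seed``.
    Raises if no physical solution is found within ``n_samples *
    max_attempts_factor`` draws (a sign that more data, or the full cPCH
    route, is needed).
    """
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    K = np.asarray(K, dtype=float)[:4]
    sig = np.sqrt(np.asarray(variances, dtype=float)[:4])
    rng = np.random.default_rng(int(seed) % 2**31)
    out: List[TwoSpeciesSolution] = []
    attempts = 0
    cap = n_samples * max_attempts_factor
    while len(out) < n_samples and attempts < cap:
        attempts += 1
        draw = K + sig * rng.standard_normal(4)
        sol = invert_two_species(draw, gammas)
        if sol.physical and not sol.degenerate:
            out.append(sol)
    if not out:
        raise InvalidParameterError(
            "no physical two-species solutions within the sampled errors; "
            "collect more data or fit the joint cPCH cumulants instead"
        )
    return out
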