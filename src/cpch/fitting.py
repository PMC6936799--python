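"""Nested-sampling fits of cPCH factorial cumulants and distributions.

The fit energy (E_K over factorial cumulants, or E_p over histogram cells)
is minimised with a population Monte-Carlo scheme in the nested-sampling
family: a set of live parameter vectors is maintained; at every iteration
the worst (highest-energy) vector is recorded and replaced by a copy of
another live vector, refined by per-parameter Metropolis updates.  Proposals
are normal (log-normal for diffusion parameters), step sizes adapt to the
acceptance ratio, moves are subject to the nested hard constraint (never
above the energy of the point just removed), and below ``E_min`` --- the
energy at which a model is statistically compatible with the data ---
acceptance is unconditional so the compatible region is explored rather than
only its minimum.  The best-fit values are the means of the recorded vectors
after burn-in; their standard deviations serve as uncertainties.

The user-facing surface follows the Model/Results convention:
``CumulantFitModel(table, n_species=...).fit(seed=...)`` returns a
:class:`FitResult` with ``params``, ``bse`` and ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .theory import InvalidParameterError
from .moments import CumulantTable
from . import inversion as _inversion

__all__ = ["Parameter", "FitSpec", "FitResult", "nested_sample", "CumulantFitModel",
           "SpatialCumulantFitModel"]

_GAMMA2 = 2.0**-1.5


@dataclass(frozen=True)
class Parameter:
    """One fit parameter: bounds, scale and free/fixed status."""

    name: str
    lower: float
    upper: float
    free: bool = True
    log_scale: bool = False
    value: Optional[float] = None  # fixed value or initial hint

    def __post_init__(self):
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise InvalidParameterError(f"{self.name}: bounds must be finite")
        if self.lower >= self.upper:
            raise InvalidParameterError(f"{self.name}: lower bound must be < upper bound")
        if self.log_scale and self.lower <= 0:
            raise InvalidParameterError(f"{self.name}: log-scale parameter needs positive bounds")


@dataclass
class FitSpec:
    """Algorithm settings for the nested-sampling optimiser."""

    parameters: Tuple[Parameter, ...]
    n_live: int = 100
    E_min: float = 2.0
    inner_iterations: int = 20
    max_replacements: int = 1200
    burn_in_fraction: float = 0.25
    seed: int = 0
    energy_kind: str = "EK"
    orderings: Tuple[Tuple[str, str], ...] = ()  # (low, high): theta[low] <= theta[high]
    stagnation_window: int = 100
    stagnation_rtol: float = 1e-4
    energy_stop: Optional[float] = None

    def __post_init__(self):
        if not any(p.free for p in self.parameters):
            raise InvalidParameterError("at least one parameter must be free")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise InvalidParameterError("duplicate parameter names")


@dataclass
class FitResult:
    """Outcome of a nested-sampling fit.

    ``params``/``bse`` are the post-burn-in means and standard deviations of
    the recorded (replaced) parameter vectors; ``best_params`` is the single
    lowest-energy vector seen; ``chain`` holds the recorded vectors and their
    energies in replacement order.
    """

    params: Dict[str, float]
    bse: Dict[str, float]
    best_params: Dict[str, float]
    energy: float
    energy_at_mean: float
    chain: pd.DataFrame
    n_energy_evaluations: int
    spec: FitSpec
    meta: Dict[str, object] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "cPCH nested-sampling fit",
            f"  energy kind: {self.spec.energy_kind}   "
            f"best energy: {self.energy:.4g}   energy at mean: {self.energy_at_mean:.4g}",
            f"  live points: {self.spec.n_live}   replacements: {len(self.chain)}   "
            f"energy evaluations: {self.n_energy_evaluations}",
            "",
            f"  {'parameter':>10s} {'estimate':>14s} {'std err':>12s}",
        ]
        for name, v in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"  {name:>10s} {v:>14.6g} {se:>12.3g}")
        for name, v in self.meta.get("derived", {}).items():
            lines.append(f"  {name:>10s} {v:>14.6g} {'(derived)':>12s}")
        return "\n".join(lines)


def nested_sample(
    energy_fn: Callable[[np.ndarray], float],
    spec: FitSpec,
    init_points: Optional[np.ndarray] = None,
) -> FitResult:
    """Minimise ``energy_fn`` over the parameters of ``spec``.

    ``init_points`` (n x n_params) seeds the live set; missing points are
    drawn uniformly within bounds (log-uniformly for log-scale parameters).
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(int(spec.seed) % 2**31)
    params = spec.parameters
    n_par = len(params)
    free_idx = [i for i, p in enumerate(params) if p.free]
    name_to_idx = {p.name: i for i, p in enumerate(params)}
    orderings = [(name_to_idx[a], name_to_idx[b]) for a, b in spec.orderings]
    lower = np.array([p.lower for p in params])
    upper = np.array([p.upper for p in params])
    log_scale = np.array([p.log_scale for p in params])

    def draw_uniform() -> np.ndarray:
        theta = np.empty(n_par)
        for i, p in enumerate(params):
            if not p.free:
                theta[i] = p.value if p.value is not None else 0.5 * (p.lower + p.upper)
            elif p.log_scale:
                theta[i] = math.exp(rng.uniform(math.log(p.lower), math.log(p.upper)))
            else:
                theta[i] = rng.uniform(p.lower, p.upper)
        return theta

    def ok(theta: np.ndarray) -> bool:
        for i in free_idx:
            if not (lower[i] <= theta[i] <= upper[i]):
                return False
        for a, b in orderings:
            if theta[a] > theta[b]:
                return False
        return True

    # live set
    live = []
    if init_points is not None:
        for row in np.asarray(init_points, dtype=float):
            theta = row.copy()
            for i, p in enumerate(params):
                if not p.free:
                    theta[i] = p.value if p.value is not None else theta[i]
            if ok(theta):
                live.append(theta)
            if len(live) >= spec.n_live:
                break
    attempts = 0
    while len(live) < spec.n_live:
        theta = draw_uniform()
        attempts += 1
        if ok(theta):
            live.append(theta)
        if attempts > 1000 * spec.n_live:
            raise InvalidParameterError("could not initialise live points within bounds")
    live = np.array(live)
    energies = np.array([energy_fn(t) for t in live])
    n_eval = len(live)
    if not np.all(np.isfinite(energies)):
        raise InvalidParameterError("non-finite energy among the initial live points")

    # per-live-point per-parameter step sizes
    steps = np.zeros((spec.n_live, n_par))
    for i, p in enumerate(params):
        if p.log_scale:
            steps[:, i] = 0.25 * math.log(p.upper / p.lower)
        else:
            steps[:, i] = 0.1 * (p.upper - p.lower)

    chain_rows = []
    mean_prev = live.mean(axis=0)
    for it in range(spec.max_replacements):
        iw = int(np.argmax(energies))
        E_removed = float(energies[iw])
        chain_rows.append((it, E_removed, live[iw].copy()))
        if spec.energy_stop is not None and E_removed <= spec.energy_stop:
            break
        donors = [j for j in range(spec.n_live) if j != iw]
        j = int(rng.choice(donors))
        theta = live[j].copy()
        E_cur = float(energies[j])
        step = steps[j].copy()
        # ensemble (stretch/differential) moves along the live set's own
        # spread: essential for mixing along curved parameter ridges, where
        # one-parameter-at-a-time proposals crawl
        for _ in range(spec.inner_iterations // 2):
            a, b = rng.choice(spec.n_live, size=2, replace=False)
            if a == iw or b == iw or a == b:
                continue
            gamma_f = rng.uniform(0.3, 1.2)
            prop = theta.copy()
            for i in free_idx:
                if log_scale[i]:
                    prop[i] = theta[i] * (live[a][i] / live[b][i]) ** gamma_f
                else:
                    prop[i] = theta[i] + gamma_f * (live[a][i] - live[b][i])
            if not ok(prop):
                continue
            E_prop = energy_fn(prop)
            n_eval += 1
            if E_prop <= E_removed and (
                E_prop < spec.E_min
                or E_prop <= E_cur
                or rng.random() < math.exp(-(E_prop - E_cur))
            ):
                theta = prop
                E_cur = E_prop
        for i in free_idx:
            n_acc = 0
            n_rej = 0
            for _ in range(spec.inner_iterations):
                prop = theta.copy()
                if log_scale[i]:
                    prop[i] = theta[i] * math.exp(step[i] * rng.standard_normal())
                else:
                    prop[i] = theta[i] + step[i] * rng.standard_normal()
                if not ok(prop):
                    n_rej += 1
                    continue
                E_prop = energy_fn(prop)
                n_eval += 1
                # nested hard constraint, then free acceptance below E_min,
                # else a unit-temperature Metropolis step
                if (
                    E_prop <= E_removed
                    and (
                        E_prop < spec.E_min
                        or E_prop <= E_cur
                        or rng.random() < math.exp(-(E_prop - E_cur))
                    )
                ):
                    theta = prop
                    E_cur = E_prop
                    n_acc += 1
                else:
                    n_rej += 1
            if n_acc > n_rej:
                step[i] *= math.exp(1.0 / n_acc)
            elif n_rej > n_acc:
                step[i] /= math.exp(1.0 / n_rej)
        live[iw] = theta
        energies[iw] = E_cur
        steps[iw] = step
        if (it + 1) % spec.stagnation_window == 0:
            mean_now = live.mean(axis=0)
            denom = np.maximum(np.abs(mean_prev), 1e-300)
            if np.max(np.abs(mean_now - mean_prev) / denom) < spec.stagnation_rtol:
                break
            mean_prev = mean_now

    names = [p.name for p in params]
    chain = pd.DataFrame(
        [dict(zip(names, row), iteration=i, energy=E) for i, E, row in chain_rows]
    )
    # burn-in: at least the configured fraction, and always discard recorded
    # points whose energy exceeds E_min (not yet compatible with the data)
    burn = int(len(chain) * spec.burn_in_fraction)
    below = np.nonzero(chain.energy.to_numpy() <= spec.E_min)[0]
    if below.size:
        burn = max(burn, int(below[0]))
    if burn >= len(chain) - 1:
        burn = int(len(chain) * spec.burn_in_fraction)
    post = chain.iloc[burn:]
    means = {n: float(post[n].mean()) for n in names}
    bse = {n: float(post[n].std(ddof=1)) if len(post) > 1 else float("nan") for n in names}
    all_points = np.vstack([live, np.array([r for _, _, r in chain_rows])])
    all_E = np.concatenate([energies, [E for _, E, _ in chain_rows]])
    ibest = int(np.argmin(all_E))
    best = dict(zip(names, all_points[ibest]))
    theta_mean = np.array([means[n] for n in names])
    for i, p in enumerate(params):
        if not p.free and p.value is not None:
            theta_mean[i] = p.value
            means[p.name] = p.value
            bse[p.name] = 0.0
    E_mean = float(energy_fn(theta_mean)) if ok(theta_mean) else float("nan")
    n_eval += 1
    return FitResult(
        params=means,
        bse=bse,
        best_params=best,
        energy=float(all_E[ibest]),
        energy_at_mean=E_mean,
        chain=chain,
        n_energy_evaluations=n_eval,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# single-colour cumulant model (identical channels)
# ---------------------------------------------------------------------------


def _prepare_table(table: CumulantTable):
    df = table.data
    good = np.isfinite(df.variance.to_numpy()) & (df.variance.to_numpy() > 0)
    df = df[good]
    if len(df) == 0:
        raise InvalidParameterError("no cumulant entries with usable variances")
    return (
        df.m.to_numpy(int),
        df.n.to_numpy(int),
        df.tau_s.to_numpy(float),
        df.T_s.to_numpy(float),
        df.value.to_numpy(float),
        df.variance.to_numpy(float),
        df,
    )


class CumulantFitModel:
    """Fit a single-colour species mixture to empirical factorial cumulants.

    Free parameters per species: occupancy ``N{i}``, brightness ``eps{i}``
    (counts/s), diffusion time ``tau_d{i}`` (s, log-scale proposals); shared:
    structure factor ``s`` and the shape factors ``gamma3``, ``gamma4``
    (``gamma1 = 1`` and ``gamma2 = 2^{-3/2}`` are exact for the Gaussian
    volume and held fixed).  ``fixed`` maps parameter names to frozen values.
    ``binning`` is the B_{m,n} mode: 'none', 'continuous' (Eq.-46-style
    closed form) or 'discrete' (counts re-binned from a dt-sampled trace;
    requires ``dt``).
    """

    def __init__(
        self,
        table: CumulantTable,
        n_species: int = 1,
        binning: str = "none",
        dt: Optional[float] = None,
        fixed: Optional[Mapping[str, float]] = None,
        bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
        closed_box_p: float = 0.0,
        periodic_image_L2_over_r2: Optional[float] = None,
    ):
        if table.kind != "fK":
            raise InvalidParameterError("CumulantFitModel expects factorial cumulants")
        if binning == "discrete" and dt is None:
            raise InvalidParameterError("discrete binning requires the sampling dt")
        self.table = table
        self.n_species = int(n_species)
        self.binning = binning
        self.dt = dt
        self.fixed = dict(fixed or {})
        self.closed_box_p = float(closed_box_p)
        # periodic simulation box: wrap-around returns add image terms to the
        # diffusion factor, exp(-c_mn (L^2/r^2)/(1 + c_mn tau/tau_d)) per
        # lateral dimension; L^2/r^2 is a known constant of the generator
        self.periodic_image_L2_over_r2 = periodic_image_L2_over_r2
        (self._m, self._n, self._tau, self._T, self._K, self._var, self._df) = _prepare_table(
            table
        )
        self.T_ref = float(np.min(self._T))
        mn = self._m + self._n
        self._gamma_order = mn
        self._c_mn = np.where(mn > 0, 2.0 * self._m * self._n / np.maximum(mn, 1), 0.0)
        self._bin_expo = np.maximum(self._m - 1, 0) + np.maximum(self._n - 1, 0)
        self._is_first = mn == 1
        k1 = self._K[self._is_first]
        self._k1_scale = float(np.mean(k1 / self._T[self._is_first])) if k1.size else 1.0
        self._bounds = dict(bounds or {})
        # discrete-binning bookkeeping: concatenated sub-bin lag grids of the
        # unique bin sizes, so B2(T, tau_d) is one vectorised kappa pass
        self._uniq_T = np.unique(self._T)
        self._T_index = np.searchsorted(self._uniq_T, self._T)
        if self.binning == "discrete":
            self._b2_grids = []
            for idx, T in enumerate(self._uniq_T):
                M = int(round(T / self.dt))
                if M > 1:
                    k = np.arange(1, M)
                    self._b2_grids.append((idx, k * self.dt, 2.0 * (M - k) / M**2))
            self._b2_M = np.array([int(round(T / self.dt)) for T in self._uniq_T])
        # closed-box correction bookkeeping: ordered pair-partitions
        # (a,b)+(c,d) = (m,n) of every row of order >= 2, flattened
        self._parts = None
        if self.closed_box_p > 0.0:
            rows, coeffs, sides = [], [], ([], [], [], [])
            for j in range(self._m.size):
                m, n = int(self._m[j]), int(self._n[j])
                if m + n < 2:
                    continue
                for a in range(m + 1):
                    for b in range(n + 1):
                        if (a, b) in ((0, 0), (m, n)):
                            continue
                        rows.append(j)
                        coeffs.append(math.comb(m, a) * math.comb(n, b))
                        sides[0].append(a)
                        sides[1].append(b)
                        sides[2].append(m - a)
                        sides[3].append(n - b)
            self._parts = (
                np.array(rows, dtype=int),
                np.array(coeffs, dtype=float),
                np.array(sides[0], dtype=int),
                np.array(sides[1], dtype=int),
                np.array(sides[2], dtype=int),
                np.array(sides[3], dtype=int),
            )

    # -- parameter layout ---------------------------------------------------
    def _parameters(self) -> List[Parameter]:
        mean_rate = max(self._k1_scale, 1e-3)
        pars: List[Parameter] = []
        for i in range(1, self.n_species + 1):
            pars.append(Parameter(f"N{i}", *self._bounds.get(f"N{i}", (1e-3, 1e3)), log_scale=True))
            pars.append(
                Parameter(
                    f"eps{i}",
                    *self._bounds.get(f"eps{i}", (mean_rate * 1e-3, mean_rate * 1e3)),
                    log_scale=True,
                )
            )
            pars.append(
                Parameter(
                    f"tau_d{i}",
                    *self._bounds.get(f"tau_d{i}", (self.T_ref / 10.0, 1.0)),
                    log_scale=True,
                )
            )
        pars.append(Parameter("s", *self._bounds.get("s", (1.05, 10.0))))
        pars.append(Parameter("gamma3", *self._bounds.get("gamma3", (0.02, 0.5))))
        pars.append(Parameter("gamma4", *self._bounds.get("gamma4", (0.005, 0.4))))
        out = []
        for p in pars:
            if p.name in self.fixed:
                v = float(self.fixed[p.name])
                lo, hi = min(p.lower, v - abs(v) * 0.1 - 1e-12), max(p.upper, v)
                out.append(replace(p, free=False, value=v, lower=lo, upper=hi + 1e-12))
            else:
                out.append(p)
        return out

    # -- model cumulants ----------------------------------------------------
    def _b2_single(self, T: float, tau_d: float, beta: float) -> float:
        from .theory import binning_B2, binning_B2_discrete

        if self.binning == "none":
            return 1.0
        if self.binning == "discrete":
            if abs(T - self.dt) <= 1e-12 * T:
                return 1.0
            return binning_B2_discrete(T, self.dt, tau_d, beta)
        return float(binning_B2(T, tau_d, beta))

    def model_cumulants(self, theta: Mapping[str, float]) -> np.ndarray:
        s = theta["s"]
        glut = np.array([0.0, 1.0, _GAMMA2, theta["gamma3"], theta["gamma4"]])
        gam = glut[self._gamma_order]
        out = np.zeros_like(self._tau)
        s2 = s * s
        for i in range(1, self.n_species + 1):
            N = theta[f"N{i}"]
            eps = theta[f"eps{i}"]
            tau_d = theta[f"tau_d{i}"]
            x = self._c_mn * self._tau / tau_d
            kappa = (1.0 + x) ** -1.0 * (1.0 + x / s2) ** -0.5
            if self.periodic_image_L2_over_r2 is not None:
                img = np.exp(-self._c_mn * self.periodic_image_L2_over_r2 / (1.0 + x))
                img = np.where(self._c_mn > 0, img, 0.0)
                kappa = kappa * (1.0 + 2.0 * img) ** 2
            if self.binning == "none":
                B = 1.0
                b2 = None
            elif self.binning == "discrete":
                b2_uniq = 1.0 / self._b2_M.astype(float)
                for idx, kdt, w in self._b2_grids:
                    u = kdt / tau_d
                    kap = (1.0 + u) ** -1.0 * (1.0 + u / s2) ** -0.5
                    b2_uniq[idx] += float(w @ kap)
                b2 = b2_uniq[self._T_index]
                B = b2**self._bin_expo
            else:
                b2_by_T = {
                    T: self._b2_single(T, tau_d, 1.0 / s2) for T in self._uniq_T
                }
                b2 = np.array([b2_by_T[T] for T in self._T])
                B = b2**self._bin_expo
            out = out + N * (eps * self._T) ** (self._m + self._n) * gam * kappa * B
            if self._parts is not None:
                out = out - 0.5 * self.closed_box_p * N * self._box_correction(
                    eps, tau_d, s2, glut, b2
                )
        return out

    def _box_correction(self, eps, tau_d, s2, glut, b2) -> np.ndarray:
        """Leading canonical-ensemble term: convolution square of the
        single-species factorial moments, accumulated per table row."""
        rows, coeff, a, b, c, d = self._parts

        def G(mm, nn):
            mn = mm + nn
            cab = np.where(mn > 0, 2.0 * mm * nn / np.maximum(mn, 1), 0.0)
            x = cab * self._tau[rows] / tau_d
            kappa = (1.0 + x) ** -1.0 * (1.0 + x / s2) ** -0.5
            gam = glut[mn]
            if b2 is None:
                B = 1.0
            else:
                expo = np.maximum(mm - 1, 0) + np.maximum(nn - 1, 0)
                B = b2[rows] ** expo
            return (eps * self._T[rows]) ** mn * gam * kappa * B

        terms = coeff * G(a, b) * G(c, d)
        out = np.zeros_like(self._tau)
        np.add.at(out, rows, terms)
        return out

    def energy_theta(self, theta: Mapping[str, float]) -> float:
        K_mod = self.model_cumulants(theta)
        return float(np.sum((K_mod - self._K) ** 2 / self._var) / self._K.size)

    def _energy_vec(self, names: Sequence[str]) -> Callable[[np.ndarray], float]:
        def fn(vec: np.ndarray) -> float:
            return self.energy_theta(dict(zip(names, vec)))

        return fn

    # -- initialisation -----------------------------------------------------
    def _moment_guess(self):
        """Rough single-species (N, eps_rate, tau_d) from low-order cumulants."""
        df = self._df
        ref = df[df.T_s == self.T_ref]
        k1 = float(ref[(ref.m + ref.n == 1)].value.mean())
        sel2 = ((ref.m == 2) & (ref.n == 0)) | ((ref.m == 0) & (ref.n == 2))
        k2 = float(ref[sel2].value.mean())
        if not (k1 > 0 and k2 > 0):
            return None
        eps_bin = k2 / (_GAMMA2 * k1)
        N = k1 / eps_bin
        # tau_d from the lag where the (1,1) correlation halves
        k11 = ref[(ref.m == 1) & (ref.n == 1)].sort_values("tau_s")
        tau_d = None
        if len(k11) >= 2 and k11.value.iloc[0] > 0:
            half = 0.5 * k11.value.iloc[0]
            below = k11[k11.value < half]
            tau_d = float(below.tau_s.iloc[0]) if len(below) else float(k11.tau_s.iloc[-1])
        return N, eps_bin / self.T_ref, tau_d

    def _init_points(self, pars: List[Parameter], n: int, seed: int) -> Optional[np.ndarray]:
        if self.n_species == 1:
            guess = self._moment_guess()
            if guess is None:
                return None
            N0, eps0, tau0 = guess
            rng = np.random.default_rng((seed + 23) % 2**31)
            names = [p.name for p in pars]
            rows = []
            for _ in range(n):
                point = {}
                point["N1"] = N0 * math.exp(0.5 * rng.standard_normal())
                point["eps1"] = eps0 * math.exp(0.5 * rng.standard_normal())
                if tau0:
                    point["tau_d1"] = tau0 * math.exp(0.7 * rng.standard_normal())
                for p in pars:
                    if p.name in point:
                        continue
                    if not p.free:
                        point[p.name] = p.value
                    elif p.log_scale:
                        point[p.name] = math.exp(
                            rng.uniform(math.log(p.lower), math.log(p.upper))
                        )
                    else:
                        point[p.name] = rng.uniform(p.lower, p.upper)
                rows.append([point[nm] for nm in names])
            return np.array(rows)
        if self.n_species != 2:
            return None
        # analytic two-species inversion of the 1D cumulants seeds the live set
        names = [p.name for p in pars]
        g3 = self.fixed.get("gamma3", 3.0**-1.5)
        g4 = self.fixed.get("gamma4", 4.0**-1.5)
        gammas = [1.0, _GAMMA2, g3, g4]
        df = self._df
        K1d, V1d = [], []
        for order in range(1, 5):
            sel = (df.m == order) & (df.n == 0)
            if not sel.any():
                return None
            K1d.append(float(df.value[sel].mean()))
            V1d.append(float(df.variance[sel].mean()))
        try:
            sols = _inversion.sample_parameter_sets(
                K1d, V1d, n_samples=n, gammas=gammas, seed=seed, max_attempts_factor=50
            )
        except InvalidParameterError:
            return None
        rng = np.random.default_rng((seed + 17) % 2**31)
        rows = []
        for sol in sols:
            point = {}
            # counts/bin at T_ref -> counts/s; label eps1 <= eps2
            e_hi, e_lo = sol.eps1 / self.T_ref, sol.eps2 / self.T_ref
            point["eps1"], point["eps2"] = e_lo, e_hi
            point["N1"], point["N2"] = sol.N2, sol.N1
            for p in pars:
                if p.name in point:
                    continue
                if p.free:
                    if p.log_scale:
                        point[p.name] = math.exp(rng.uniform(math.log(p.lower), math.log(p.upper)))
                    else:
                        point[p.name] = rng.uniform(p.lower, p.upper)
                else:
                    point[p.name] = p.value
            rows.append([point[nm] for nm in names])
        return np.array(rows)

    def fit(
        self,
        seed: int = 0,
        n_live: int = 100,
        max_replacements: int = 1200,
        E_min: float = 2.0,
        inner_iterations: int = 20,
        energy_stop: Optional[float] = None,
    ) -> FitResult:
        pars = self._parameters()
        orderings = (("eps1", "eps2"),) if self.n_species == 2 else ()
        spec = FitSpec(
            parameters=tuple(pars),
            n_live=n_live,
            E_min=E_min,
            inner_iterations=inner_iterations,
            max_replacements=max_replacements,
            seed=seed,
            energy_kind="EK",
            orderings=orderings,
            energy_stop=energy_stop,
        )
        names = [p.name for p in pars]
        init = self._init_points(pars, max(n_live // 2, 1), seed)
        res = nested_sample(self._energy_vec(names), spec, init_points=init)
        derived = {}
        for i in range(1, self.n_species + 1):
            derived[f"eps{i}_per_bin"] = res.params[f"eps{i}"] * self.T_ref
            derived[f"tau_d{i}_us"] = res.params[f"tau_d{i}"] * 1e6
        res.meta["derived"] = derived
        res.meta["T_ref"] = self.T_ref
        res.meta["binning"] = self.binning
        return res


class HistogramFitModel:
    """Fit a single-colour species mixture to empirical cPCH histograms.

    Minimises the per-cell energy E_p: for each (tau, T) the model joint
    distribution is computed by the generating-function FFT route and
    compared with the empirical histogram.  Much more expensive per
    evaluation than the cumulant route (one FFT set per histogram per
    proposal); practical for small grids, or to cross-check a cumulant fit.
    Free parameters per species: N{i}, eps{i} (counts/s), tau_d{i}; shared:
    structure factor s.
    """

    def __init__(self, histograms, n_species: int = 1,
                 fixed: Optional[Mapping[str, float]] = None,
                 bounds: Optional[Mapping[str, Tuple[float, float]]] = None):
        self.hists = dict(histograms)
        if not self.hists:
            raise InvalidParameterError("no histograms")
        self.n_species = int(n_species)
        self.fixed = dict(fixed or {})
        self._bounds = dict(bounds or {})
        self.T_ref = min(T for (_, T) in self.hists)

    def _parameters(self) -> List[Parameter]:
        pars: List[Parameter] = []
        for i in range(1, self.n_species + 1):
            pars.append(Parameter(f"N{i}", *self._bounds.get(f"N{i}", (1e-3, 1e3)), log_scale=True))
            pars.append(Parameter(f"eps{i}", *self._bounds.get(f"eps{i}", (1e2, 1e7)), log_scale=True))
            pars.append(Parameter(f"tau_d{i}", *self._bounds.get(f"tau_d{i}", (1e-6, 1e-1)), log_scale=True))
        pars.append(Parameter("s", *self._bounds.get("s", (1.05, 10.0))))
        out = []
        for p in pars:
            if p.name in self.fixed:
                v = float(self.fixed[p.name])
                out.append(replace(p, free=False, value=v,
                                   lower=min(p.lower, v - abs(v) * 0.1 - 1e-12),
                                   upper=max(p.upper, v + 1e-12)))
            else:
                out.append(p)
        return out

    def _model(self, theta: Mapping[str, float]):
        from .theory import CpchModel, OpticalConfig, SpeciesParams

        optical = OpticalConfig.from_structure_factor(r=0.25, s=theta["s"])
        species = tuple(
            SpeciesParams(
                N=theta[f"N{i}"], eps_A=theta[f"eps{i}"], tau_d=theta[f"tau_d{i}"]
            )
            for i in range(1, self.n_species + 1)
        )
        return CpchModel(optical, species)

    def energy_theta(self, theta: Mapping[str, float]) -> float:
        from .distributions import pN_fft, GridTooSmallError
        from .empirical import energy_Ep

        model = self._model(theta)
        pmfs = {}
        for (tau, T), hist in self.hists.items():
            L = max(hist.counts.shape) + 8
            try:
                pmfs[(tau, T)] = pN_fft(model, tau, T, L, L, binning="none").values
            except GridTooSmallError:
                return float("inf")
        return energy_Ep(pmfs, self.hists)

    def fit(self, seed: int = 0, n_live: int = 30, max_replacements: int = 300,
            E_min: float = 2.0, inner_iterations: int = 10) -> FitResult:
        pars = self._parameters()
        spec = FitSpec(
            parameters=tuple(pars), n_live=n_live, E_min=E_min,
            inner_iterations=inner_iterations, max_replacements=max_replacements,
            seed=seed, energy_kind="Ep",
            orderings=(("eps1", "eps2"),) if self.n_species == 2 else (),
        )
        names = [p.name for p in pars]

        def fn(vec):
            return self.energy_theta(dict(zip(names, vec)))

        res = nested_sample(fn, spec)
        res.meta["derived"] = {
            f"eps{i}_per_bin": res.params[f"eps{i}"] * self.T_ref
            for i in range(1, self.n_species + 1)
        }
        return res


# ---------------------------------------------------------------------------
# spatial (raster-image) cumulant model
# ---------------------------------------------------------------------------


class SpatialCumulantFitModel:
    """Fit a species mixture to spatial cPCH factorial cumulants.

    The empirical table must carry the pixel offsets (columns d_x, d_y, as
    produced by :func:`cpch.spatial.spatial_cumulant_table`).  Free
    parameters per species: ``N{i}``, ``eps{i}`` (counts/s) and the diffusion
    coefficient ``D{i}`` (um^2/s, log-scale); shared: beam waist ``r`` (um),
    structure factor ``s``, and ``gamma3``/``gamma4``.  Because the scanning
    displacement is known in physical units, spatial cPCH constrains r and D
    separately (not just tau_d = r^2/4D).
    """

    def __init__(
        self,
        table: CumulantTable,
        geom,
        n_species: int = 1,
        fixed: Optional[Mapping[str, float]] = None,
        bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    ):
        if "d_x" not in table.data.columns:
            raise InvalidParameterError("spatial table must carry d_x/d_y offset columns")
        self.table = table
        self.geom = geom
        self.n_species = int(n_species)
        self.fixed = dict(fixed or {})
        self._bounds = dict(bounds or {})
        (self._m, self._n, self._tau, self._T, self._K, self._var, df) = _prepare_table(table)
        self._dx_um = df.d_x.to_numpy(float) * geom.delta_x
        self._dy_um = df.d_y.to_numpy(float) * geom.delta_y
        self.T_ref = float(np.min(self._T))
        mn = self._m + self._n
        self._gamma_order = mn
        self._mn_prod = (self._m * self._n).astype(float)
        self._mn_sum = np.maximum(mn, 1).astype(float)
        k1 = self._K[mn == 1]
        self._k1_scale = float(np.mean(k1 / self._T[mn == 1])) if k1.size else 1.0

    def _parameters(self) -> List[Parameter]:
        mean_rate = max(self._k1_scale, 1e-3)
        pars: List[Parameter] = []
        for i in range(1, self.n_species + 1):
            pars.append(Parameter(f"N{i}", *self._bounds.get(f"N{i}", (1e-3, 1e3)), log_scale=True))
            pars.append(
                Parameter(
                    f"eps{i}",
                    *self._bounds.get(f"eps{i}", (mean_rate * 1e-3, mean_rate * 1e3)),
                    log_scale=True,
                )
            )
            pars.append(
                Parameter(f"D{i}", *self._bounds.get(f"D{i}", (1e-2, 1e4)), log_scale=True)
            )
        pars.append(Parameter("r", *self._bounds.get("r", (0.05, 1.0))))
        pars.append(Parameter("s", *self._bounds.get("s", (1.05, 10.0))))
        pars.append(Parameter("gamma3", *self._bounds.get("gamma3", (0.02, 0.5))))
        pars.append(Parameter("gamma4", *self._bounds.get("gamma4", (0.005, 0.4))))
        out = []
        for p in pars:
            if p.name in self.fixed:
                v = float(self.fixed[p.name])
                lo, hi = min(p.lower, v - abs(v) * 0.1 - 1e-12), max(p.upper, v + 1e-12)
                out.append(replace(p, free=False, value=v, lower=lo, upper=hi))
            else:
                out.append(p)
        return out

    def model_cumulants(self, theta: Mapping[str, float]) -> np.ndarray:
        s = theta["s"]
        r = theta["r"]
        gammas = {1: 1.0, 2: _GAMMA2, 3: theta["gamma3"], 4: theta["gamma4"]}
        gam = np.array([gammas[int(o)] for o in self._gamma_order])
        out = np.zeros_like(self._tau)
        r2 = r * r
        for i in range(1, self.n_species + 1):
            N = theta[f"N{i}"]
            eps = theta[f"eps{i}"]
            D = theta[f"D{i}"]
            denom = self._mn_sum * r2
            x = 8.0 * self._mn_prod * D * self._tau / denom
            kappa = (1.0 + x) ** -1.0 * (1.0 + x / (s * s)) ** -0.5
            S = np.exp(
                -2.0
                * self._mn_prod
                * (self._dx_um**2 + self._dy_um**2)
                / (denom * (1.0 + x))
            )
            out = out + N * (eps * self._T) ** (self._m + self._n) * gam * kappa * S
        return out

    def energy_theta(self, theta: Mapping[str, float]) -> float:
        K_mod = self.model_cumulants(theta)
        return float(np.sum((K_mod - self._K) ** 2 / self._var) / self._K.size)

    def fit(
        self,
        seed: int = 0,
        n_live: int = 100,
        max_replacements: int = 1500,
        E_min: float = 2.0,
        inner_iterations: int = 20,
        energy_stop: Optional[float] = None,
    ) -> FitResult:
        pars = self._parameters()
        orderings = (("eps1", "eps2"),) if self.n_species == 2 else ()
        spec = FitSpec(
            parameters=tuple(pars),
            n_live=n_live,
            E_min=E_min,
            inner_iterations=inner_iterations,
            max_replacements=max_replacements,
            seed=seed,
            energy_kind="EK",
            orderings=orderings,
            energy_stop=energy_stop,
        )
        names = [p.name for p in pars]

        def fn(vec: np.ndarray) -> float:
            return self.energy_theta(dict(zip(names, vec)))

        res = nested_sample(fn, spec)
        derived = {}
        for i in range(1, self.n_species + 1):
            derived[f"eps{i}_per_bin"] = res.params[f"eps{i}"] * self.T_ref
            if res.params.get("r"):
                derived[f"tau_d{i}_us"] = (
                    res.params["r"] ** 2 / (4.0 * res.params[f"D{i}"]) * 1e6
                )
        res.meta["derived"] = derived
        res.meta["T_ref"] = self.T_ref
        return res
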