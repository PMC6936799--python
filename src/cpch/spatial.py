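"""Spatial cPCH for raster-scanned images.

In a raster scan the laser visits pixels in a fixed temporal order, so a
spatial offset between two pixels maps to a time lag, and the scanning
motion acts like a directed flow: the correlation between the photon counts
of two pixels carries the same diffusion information as temporal cPCH plus a
displacement-dependent suppression (the basis of RICS).  This module maps
pixel offsets to lags, evaluates the flow-corrected model cumulants, and
builds empirical pixel-pair histograms and moments from image stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .theory import (
    CpchModel,
    InvalidParameterError,
    diffusion_factor,
    flow_factor_displacement,
    shape_factor,
)
from .moments import (
    CumulantTable,
    default_orders,
    factorial_cumulants_from_raw,
    required_raw_orders,
)
from . import empirical as _empirical

__all__ = [
    "ScanGeometry",
    "offset_to_tau",
    "spatial_cumulants_model",
    "build_spatial_hist",
    "spatial_cumulant_table",
    "spatial_model_table",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan timing and pixel geometry.

    Pixel sizes in um, times in s.  ``pixels_per_line`` (L_y) is the number
    of pixels the laser visits per line; ``lines`` the number of lines per
    frame.
    """

    delta_x: float
    delta_y: float
    tau_pixel: float
    tau_line: float
    tau_frame: float
    pixels_per_line: int
    lines: int

    def __post_init__(self):
        if min(self.delta_x, self.delta_y, self.tau_pixel) <= 0:
            raise InvalidParameterError("pixel size and dwell time must be positive")
        if self.tau_line < 0 or self.tau_frame < 0:
            raise InvalidParameterError("retrace times must be >= 0")
        if self.pixels_per_line < 1 or self.lines < 1:
            raise InvalidParameterError("image must have at least one pixel")

    @property
    def image_extent(self) -> Tuple[float, float]:
        """Scanned region size (X, Y) in um."""
        return (self.pixels_per_line * self.delta_x, self.lines * self.delta_y)

    @property
    def frame_time(self) -> float:
        return self.lines * (self.pixels_per_line * self.tau_pixel + self.tau_line) + self.tau_frame


def offset_to_tau(d_x: int, d_y: int, geom: ScanGeometry) -> float:
    """Lag time between two pixels separated by (d_x, d_y) in a raster scan.

    tau = tau_p (d_x + L_y d_y) + tau_L d_y: the dwell time to advance d_x
    pixels in the line, plus full-line scan and line-retrace time for each of
    the d_y intervening lines.  Only forward (causal) offsets are allowed:
    d_y >= 0 and tau >= 0.
    """
    if abs(d_x) >= geom.pixels_per_line:
        raise InvalidParameterError("|d_x| must be smaller than the line length")
    tau = geom.tau_pixel * (d_x + geom.pixels_per_line * d_y) + geom.tau_line * d_y
    if d_y < 0 or tau < 0:
        raise InvalidParameterError("only forward offsets (d_y >= 0, tau >= 0) are allowed")
    return tau


def spatial_cumulants_model(
    m: int,
    n: int,
    d_x: int,
    d_y: int,
    model: CpchModel,
    geom: ScanGeometry,
    T: Optional[float] = None,
) -> float:
    """Model factorial cumulant (K)_{m,n} for a pixel offset (d_x, d_y).

    The lag is tau = offset_to_tau(d_x, d_y) and the scanning displacement
    entering the flow factor is (d_x delta_x, d_y delta_y).  The counting
    bin is the pixel dwell time (T = tau_p) unless overridden.
    """
    if T is None:
        T = geom.tau_pixel
    tau = offset_to_tau(d_x, d_y, geom)
    o = model.optical
    g = shape_factor(m, n, o)
    total = 0.0
    for sp in model.species:
        D = sp.resolve_D(o)
        kappa = float(diffusion_factor(m, n, tau, D, o))
        S = flow_factor_displacement(
            m, n, tau, D, d_x * geom.delta_x, d_y * geom.delta_y, o
        )
        total += sp.N * (sp.eps_A * T) ** m * (sp.eps_B * T) ** n * g * kappa * S
    if m + n == 1:
        total += (model.lambda_A if m == 1 else model.lambda_B) * T
    return total


def spatial_model_table(
    model: CpchModel,
    geom: ScanGeometry,
    offsets: Sequence[Tuple[int, int]],
    orders=None,
) -> CumulantTable:
    """Theoretical factorial-cumulant table over pixel offsets."""
    orders = list(orders) if orders is not None else default_orders(4)
    records = []
    for d_x, d_y in offsets:
        tau = offset_to_tau(d_x, d_y, geom)
        for m, n in orders:
            v = spatial_cumulants_model(m, n, d_x, d_y, model, geom)
            records.append(
                {
                    "m": m,
                    "n": n,
                    "tau_s": tau,
                    "T_s": geom.tau_pixel,
                    "value": v,
                    "variance": np.nan,
                    "N_d": np.nan,
                    "d_x": d_x,
                    "d_y": d_y,
                }
            )
    df = pd.DataFrame.from_records(records)
    table = CumulantTable(df[CumulantTable._COLUMNS].copy(), kind="fK")
    table.data["d_x"] = df["d_x"].values
    table.data["d_y"] = df["d_y"].values
    return table


def _offset_views(stack: np.ndarray, d_x: int, d_y: int):
    """Paired pixel views for an offset, frames kept separate (no cross-frame
    pairs) and pairs crossing the image edge discarded."""
    if stack.ndim == 2:
        stack = stack[None, :, :]
    F, H, W = stack.shape
    if d_x >= W or d_y >= H or d_x <= -W or d_y < 0:
        raise InvalidParameterError("offset larger than image or non-causal")
    if d_x >= 0:
        a = stack[:, : H - d_y, : W - d_x]
        b = stack[:, d_y:, d_x:]
    else:
        a = stack[:, : H - d_y, -d_x:]
        b = stack[:, d_y:, : W + d_x]
    return a.reshape(-1), b.reshape(-1)


def build_spatial_hist(
    stack: np.ndarray, d_x: int, d_y: int, geom: Optional[ScanGeometry] = None
) -> "_empirical.CpchHistogram":
    """Empirical cPCH histogram of pixel pairs at offset (d_x, d_y).

    Pairs one pixel with the pixel (d_y lines, d_x columns) later in the
    scan, within each frame; accumulates over frames.  d = (0, 0) pairs each
    pixel with itself, giving a diagonal-only histogram.
    """
    a, b = _offset_views(np.asarray(stack), d_x, d_y)
    tau = offset_to_tau(d_x, d_y, geom) if geom is not None else float("nan")
    T = geom.tau_pixel if geom is not None else float("nan")
    return _empirical.histogram_from_pairs(a, b, tau=tau, T=T)


def spatial_cumulant_table(
    stack: np.ndarray,
    geom: ScanGeometry,
    offsets: Sequence[Tuple[int, int]],
    max_order: int = 4,
    orders=None,
    first_cumulant_inflation=None,
    variance_mode: str = "iid",
    n_batches: int = 64,
) -> CumulantTable:
    """Empirical factorial cumulants (with variances) over pixel offsets.

    ``first_cumulant_inflation`` ("auto", a number, or None) corrects the
    variance of the first-order cumulants for pixel-to-pixel correlation
    along the scan, which the independent-pixel delta method ignores;
    ``variance_mode="batch"`` uses batch-means variances for every order
    instead (contiguous blocks of the scan-ordered pixel pairs; see the
    empirical module).
    """
    orders = list(orders) if orders is not None else default_orders(max_order)
    raw_orders = required_raw_orders(orders)
    records = []
    stack = np.asarray(stack)
    if first_cumulant_inflation == "auto" and variance_mode != "batch":
        flat = stack.reshape(-1).astype(float)
        max_dx = max((abs(d) for d, _ in offsets), default=16)
        inflation = _empirical.long_run_variance_inflation(
            flat, min(8 * max(max_dx, 16), flat.size // 10)
        )
    else:
        inflation = first_cumulant_inflation if variance_mode != "batch" else None
    max_m = max(a for a, b in raw_orders)
    max_n = max(b for a, b in raw_orders)
    for d_x, d_y in offsets:
        a, b = _offset_views(stack, d_x, d_y)
        fa, fb = a.astype(float), b.astype(float)
        N_d = a.size
        if variance_mode == "batch":
            pow_a = {k: fa**k for k in range(1, max_m + 1)}
            pow_b = pow_a if (d_x, d_y) == (0, 0) else {k: fb**k for k in range(1, max_n + 1)}
            raw, batch, N_d = _empirical._batch_raw_moments(pow_a, pow_b, raw_orders, n_batches)
            values = {o: _empirical._poly_eval_cached(o, raw) for o in orders}
            variances = {o: _empirical._batch_variance(raw, batch, o) for o in orders}
        else:
            raw = _empirical.raw_moments_from_pairs(fa, fb, raw_orders)
            values, variances = factorial_cumulants_from_raw(raw, orders, N_d)
        tau = offset_to_tau(d_x, d_y, geom)
        for (m, n) in orders:
            var = variances[(m, n)]
            if variance_mode != "batch" and inflation is not None and m + n == 1:
                var *= inflation
            records.append(
                {
                    "m": m,
                    "n": n,
                    "tau_s": tau,
                    "T_s": geom.tau_pixel,
                    "value": values[(m, n)],
                    "variance": var,
                    "N_d": N_d,
                    "d_x": d_x,
                    "d_y": d_y,
                }
            )
    df = pd.DataFrame.from_records(records)
    table = CumulantTable(df[CumulantTable._COLUMNS].copy(), kind="fK")
    table.data["d_x"] = df["d_x"].values
    table.data["d_y"] = df["d_y"].values
    return table
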