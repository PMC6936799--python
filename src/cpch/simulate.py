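"""Brownian-dynamics synthetic data with known ground truth.

Molecules diffuse in a periodic box with the laser focus (or the raster-scan
position) inside it.  Time is discretised in steps of ``dt``: at each step
every molecule first emits photons in each detection channel from a Poisson
distribution whose mean is the 3D Gaussian illumination profile evaluated at
the molecule's current position, and then takes an isotropic Gaussian step
with per-axis variance 2 D dt, wrapping at the box boundaries.  The number
of molecules is constant.  For images, the laser follows the raster schedule
(pixel dwell, line retrace, frame retrace), with retrace intervals advanced
in dwell-sized diffusion steps without photon collection.

Default box for point measurements is 4 x 4 x 8 um with the focus at the
centre; for an X x Y um image it is 4X x 4Y x 8 um with the scanned region
centred in the box.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import numba

from .theory import (
    CpchModel,
    InvalidParameterError,
    OpticalConfig,
    SpeciesParams,
    observation_volume,
)
from .spatial import ScanGeometry

__all__ = [
    "SimBox",
    "GroundTruth",
    "BinnedTrace",
    "simulate_trace",
    "simulate_image_stack",
    "to_arrival_times",
    "make_fixture",
    "PRESETS",
]


@dataclass(frozen=True)
class SimBox:
    """Periodic simulation box (um), much larger than the observation volume."""

    x: float = 4.0
    y: float = 4.0
    z: float = 8.0

    @property
    def volume(self) -> float:
        return self.x * self.y * self.z

    @classmethod
    def for_image(cls, extent_x: float, extent_y: float) -> "SimBox":
        return cls(x=4.0 * extent_x, y=4.0 * extent_y, z=8.0)


@dataclass
class GroundTruth:
    """A simulation's exact inputs: model, box, absolute molecule numbers."""

    model: CpchModel
    box: SimBox
    n_molecules: Tuple[int, ...]
    dt: float
    duration: float
    seed: int

    @property
    def effective_N(self) -> Tuple[float, ...]:
        """Mean occupancies actually realised after integer rounding."""
        v = observation_volume(self.model.optical) / self.box.volume
        return tuple(n * v for n in self.n_molecules)

    def to_json(self) -> str:
        o = self.model.optical
        payload = {
            "optical": {"r_A": o.r_A, "z_A": o.z_A, "r_B": o.r_B, "z_B": o.z_B},
            "species": [
                {"N": sp.N, "eps_A": sp.eps_A, "eps_B": sp.eps_B, "D": sp.resolve_D(o)}
                for sp in self.model.species
            ],
            "lambda_A": self.model.lambda_A,
            "lambda_B": self.model.lambda_B,
            "flow": self.model.flow,
            "box": asdict(self.box),
            "n_molecules": list(self.n_molecules),
            "dt": self.dt,
            "duration": self.duration,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        optical = OpticalConfig(**d["optical"])
        species = tuple(SpeciesParams(**sp) for sp in d["species"])
        model = CpchModel(
            optical,
            species,
            lambda_A=d.get("lambda_A", 0.0),
            lambda_B=d.get("lambda_B", 0.0),
            flow=tuple(d["flow"]) if d.get("flow") else None,
        )
        return cls(
            model=model,
            box=SimBox(**d["box"]),
            n_molecules=tuple(d["n_molecules"]),
            dt=d["dt"],
            duration=d["duration"],
            seed=d["seed"],
        )


@dataclass
class BinnedTrace:
    """Photon counts per dt-bin per channel, with its ground truth."""

    counts: np.ndarray  # (n_channels, n_bins) int32
    dt: float
    truth: Optional[GroundTruth] = None

    @property
    def duration(self) -> float:
        return self.counts.shape[1] * self.dt

    def channel(self, i: int = 0) -> np.ndarray:
        return self.counts[i]


def _molecule_counts(model: CpchModel, box: SimBox) -> Tuple[int, ...]:
    v_ab = observation_volume(model.optical)
    return tuple(int(round(sp.N * box.volume / v_ab)) for sp in model.species)


_CHUNK = 8192


@numba.njit(cache=True)
def _trace_kernel(
    n_steps,
    n_mol,
    species_of_mol,
    eps_a_bin,
    eps_b_bin,
    sigma_step,
    hx,
    hy,
    hz,
    inv_r2_a,
    inv_z2_a,
    inv_r2_b,
    inv_z2_b,
    rho2_cut,
    z2_cut,
    two_channels,
    seed,
    x0,
    y0,
    z0,
    use_x0,
    counts_a,
    counts_b,
):
    for i in range(n_mol):
        np.random.seed((seed + 7919 * (i + 1)) % 2147483647)
        sp = species_of_mol[i]
        if use_x0:
            x = x0[i]
            y = y0[i]
            z = z0[i]
        else:
            x = (np.random.random() - 0.5) * 2.0 * hx
            y = (np.random.random() - 0.5) * 2.0 * hy
            z = (np.random.random() - 0.5) * 2.0 * hz
        ea = eps_a_bin[sp]
        eb = eps_b_bin[sp]
        sg = sigma_step[sp]
        t = 0
        while t < n_steps:
            nc = min(_CHUNK, n_steps - t)
            zbuf = np.random.standard_normal(3 * nc)
            for j in range(nc):
                rho2 = x * x + y * y
                if rho2 < rho2_cut and z * z < z2_cut:
                    ia = ea * math.exp(-2.0 * rho2 * inv_r2_a - 2.0 * z * z * inv_z2_a)
                    if ia > 1e-12:
                        c = np.random.poisson(ia)
                        if c > 0:
                            counts_a[t + j] += c
                    if two_channels:
                        ib = eb * math.exp(-2.0 * rho2 * inv_r2_b - 2.0 * z * z * inv_z2_b)
                        if ib > 1e-12:
                            c = np.random.poisson(ib)
                            if c > 0:
                                counts_b[t + j] += c
                # sg = 0 (immobile species) leaves the position untouched
                x += sg * zbuf[3 * j]
                y += sg * zbuf[3 * j + 1]
                z += sg * zbuf[3 * j + 2]
                if x > hx:
                    x -= 2.0 * hx
                elif x < -hx:
                    x += 2.0 * hx
                if y > hy:
                    y -= 2.0 * hy
                elif y < -hy:
                    y += 2.0 * hy
                if z > hz:
                    z -= 2.0 * hz
                elif z < -hz:
                    z += 2.0 * hz
            t += nc


def simulate_trace(
    model: CpchModel,
    duration: float,
    dt: float,
    seed: int = 0,
    channels: int = 1,
    box: Optional[SimBox] = None,
    positions0: Optional[np.ndarray] = None,
    n_molecules: Optional[Sequence[int]] = None,
) -> BinnedTrace:
    """Simulate a binned photon-count trace for a point measurement.

    Brightnesses are counts/s; the Poisson mean per dt-bin for a molecule at
    beam centre is eps * dt.  Molecule numbers default to
    round(N_i V_box / V_AB); pass ``n_molecules`` (with ``positions0`` if
    desired) to override, e.g. to pin a single molecule at the focus.
    Emission uses the position at the start of the step; positions are then
    advanced by one diffusion step.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidParameterError("duration and dt must be positive")
    box = box or SimBox()
    o = model.optical
    n_steps = int(round(duration / dt))
    n_per_species = (
        tuple(int(k) for k in n_molecules)
        if n_molecules is not None
        else _molecule_counts(model, box)
    )
    for sp in model.species:
        td = sp.resolve_tau_d(o, "A")
        if dt > td:
            import warnings

            warnings.warn(f"dt={dt} exceeds a diffusion time {td}; trace will under-resolve")

    species_of_mol = np.repeat(
        np.arange(len(n_per_species), dtype=np.int64), np.array(n_per_species, dtype=np.int64)
    )
    n_mol = int(species_of_mol.size)
    eps_a_bin = np.array([sp.eps_A * dt for sp in model.species])
    eps_b_bin = np.array([sp.eps_B * dt for sp in model.species])
    sigma_step = np.array([math.sqrt(2.0 * sp.resolve_D(o) * dt) for sp in model.species])
    counts_a = np.zeros(n_steps, dtype=np.int32)
    counts_b = np.zeros(n_steps, dtype=np.int32)
    rmax = max(o.r_A, o.r_B)
    zmax = max(o.z_A, o.z_B)
    if positions0 is not None:
        pos = np.asarray(positions0, dtype=np.float64)
        x0, y0, z0 = pos[:, 0].copy(), pos[:, 1].copy(), pos[:, 2].copy()
        use_x0 = True
    else:
        x0 = y0 = z0 = np.zeros(1)
        use_x0 = False
    _trace_kernel(
        n_steps,
        n_mol,
        species_of_mol,
        eps_a_bin,
        eps_b_bin,
        sigma_step,
        box.x / 2.0,
        box.y / 2.0,
        box.z / 2.0,
        1.0 / o.r_A**2,
        1.0 / o.z_A**2,
        1.0 / o.r_B**2,
        1.0 / o.z_B**2,
        10.5 * rmax**2,
        10.5 * zmax**2,
        channels == 2,
        int(seed) % 2147483647,
        x0,
        y0,
        z0,
        use_x0,
        counts_a,
        counts_b,
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 91]))
    if model.lambda_A > 0:
        counts_a += rng.poisson(model.lambda_A * dt, size=n_steps).astype(np.int32)
    if channels == 2 and model.lambda_B > 0:
        counts_b += rng.poisson(model.lambda_B * dt, size=n_steps).astype(np.int32)
    counts = np.stack([counts_a, counts_b][:channels])
    truth = GroundTruth(
        model=model,
        box=box,
        n_molecules=n_per_species,
        dt=dt,
        duration=duration,
        seed=int(seed),
    )
    return BinnedTrace(counts=counts, dt=dt, truth=truth)


@numba.njit(cache=True)
def _image_kernel(
    n_steps,
    n_mol,
    species_of_mol,
    eps_bin,
    sigma_step,
    hx,
    hy,
    hz,
    inv_r2,
    inv_z2,
    rho2_cut,
    z2_cut,
    laser_x,
    laser_y,
    pix_index,
    seed,
    x0,
    y0,
    z0,
    use_x0,
    counts_flat,
):
    for i in range(n_mol):
        np.random.seed((seed + 7919 * (i + 1)) % 2147483647)
        sp = species_of_mol[i]
        if use_x0:
            x = x0[i]
            y = y0[i]
            z = z0[i]
        else:
            x = (np.random.random() - 0.5) * 2.0 * hx
            y = (np.random.random() - 0.5) * 2.0 * hy
            z = (np.random.random() - 0.5) * 2.0 * hz
        e = eps_bin[sp]
        sg = sigma_step[sp]
        t = 0
        while t < n_steps:
            nc = min(_CHUNK, n_steps - t)
            zbuf = np.random.standard_normal(3 * nc)
            for j in range(nc):
                p = pix_index[t + j]
                if p >= 0:
                    dx = x - laser_x[t + j]
                    dy = y - laser_y[t + j]
                    rho2 = dx * dx + dy * dy
                    if rho2 < rho2_cut and z * z < z2_cut:
                        inten = e * math.exp(-2.0 * rho2 * inv_r2 - 2.0 * z * z * inv_z2)
                        if inten > 1e-12:
                            c = np.random.poisson(inten)
                            if c > 0:
                                counts_flat[p] += c
                x += sg * zbuf[3 * j]
                y += sg * zbuf[3 * j + 1]
                z += sg * zbuf[3 * j + 2]
                if x > hx:
                    x -= 2.0 * hx
                elif x < -hx:
                    x += 2.0 * hx
                if y > hy:
                    y -= 2.0 * hy
                elif y < -hy:
                    y += 2.0 * hy
                if z > hz:
                    z -= 2.0 * hz
                elif z < -hz:
                    z += 2.0 * hz
            t += nc


def _raster_schedule(geom: ScanGeometry, frames: int):
    """Laser position and target pixel per dt step (dt = dwell time).

    Retrace intervals are covered by dwell-sized steps with no collection
    (pixel index -1); residual retrace time shorter than one dwell is
    rounded to the nearest whole number of steps.
    """
    W, H = geom.pixels_per_line, geom.lines
    X, Y = geom.image_extent
    n_line_retrace = int(round(geom.tau_line / geom.tau_pixel))
    n_frame_retrace = int(round(geom.tau_frame / geom.tau_pixel))
    per_frame = H * (W + n_line_retrace) + n_frame_retrace
    n_steps = frames * per_frame
    laser_x = np.zeros(n_steps)
    laser_y = np.zeros(n_steps)
    pix = np.full(n_steps, -1, dtype=np.int64)
    xs = -X / 2.0 + (np.arange(W) + 0.5) * geom.delta_x
    t = 0
    for f in range(frames):
        base = f * H * W
        for j in range(H):
            yj = -Y / 2.0 + (j + 0.5) * geom.delta_y
            laser_x[t : t + W] = xs
            laser_y[t : t + W] = yj
            pix[t : t + W] = base + j * W + np.arange(W)
            t += W + n_line_retrace
        t += n_frame_retrace
    return laser_x, laser_y, pix, n_steps


def simulate_image_stack(
    model: CpchModel,
    geom: ScanGeometry,
    frames: int,
    seed: int = 0,
    box: Optional[SimBox] = None,
    positions0: Optional[np.ndarray] = None,
    n_molecules: Optional[Sequence[int]] = None,
) -> Tuple[np.ndarray, GroundTruth]:
    """Simulate a raster-scanned photon-counting image stack.

    Returns (stack, truth) with stack of shape (frames, lines,
    pixels_per_line), uint16 photon counts.  At each pixel dwell, photons
    from all molecules are drawn with the PSF centred at the pixel; molecule
    positions advance by one diffusion step per dwell, including during line
    and frame retrace.
    """
    X, Y = geom.image_extent
    box = box or SimBox.for_image(X, Y)
    if X > box.x or Y > box.y:
        raise InvalidParameterError("image extent exceeds the simulation box footprint")
    o = model.optical
    if not o.identical_channels:
        raise InvalidParameterError("image simulation supports a single channel")
    laser_x, laser_y, pix, n_steps = _raster_schedule(geom, frames)
    n_per_species = (
        tuple(int(k) for k in n_molecules)
        if n_molecules is not None
        else _molecule_counts(model, box)
    )
    species_of_mol = np.repeat(
        np.arange(len(n_per_species), dtype=np.int64), np.array(n_per_species, dtype=np.int64)
    )
    eps_bin = np.array([sp.eps_A * geom.tau_pixel for sp in model.species])
    sigma_step = np.array(
        [math.sqrt(2.0 * sp.resolve_D(o) * geom.tau_pixel) for sp in model.species]
    )
    counts_flat = np.zeros(frames * geom.lines * geom.pixels_per_line, dtype=np.int32)
    _image_kernel(
        n_steps,
        int(species_of_mol.size),
        species_of_mol,
        eps_bin,
        sigma_step,
        box.x / 2.0,
        box.y / 2.0,
        box.z / 2.0,
        1.0 / o.r_A**2,
        1.0 / o.z_A**2,
        10.5 * o.r_A**2,
        10.5 * o.z_A**2,
        laser_x,
        laser_y,
        pix,
        int(seed) % 2147483647,
        *(
            (positions0[:, 0].copy(), positions0[:, 1].copy(), positions0[:, 2].copy(), True)
            if positions0 is not None
            else (np.zeros(1), np.zeros(1), np.zeros(1), False)
        ),
        counts_flat,
    )
    if model.lambda_A > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 92]))
        counts_flat += rng.poisson(
            model.lambda_A * geom.tau_pixel, size=counts_flat.size
        ).astype(np.int32)
    stack = counts_flat.reshape(frames, geom.lines, geom.pixels_per_line).astype(np.uint16)
    truth = GroundTruth(
        model=model,
        box=box,
        n_molecules=n_per_species,
        dt=geom.tau_pixel,
        duration=frames * geom.frame_time,
        seed=int(seed),
    )
    return stack, truth


def to_arrival_times(trace: BinnedTrace, sampling_time: float = 50e-9, seed: int = 0):
    """Emit a trace in arrival-time mode.

    Each bin's photons are placed uniformly within the bin on the detector
    clock (default 50 ns).  Adequate for cPCH, which only uses bin-level
    counts.  Returns one :class:`~cpch.empirical.ArrivalTrace` per channel.
    """
    from .empirical import ArrivalTrace

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 93]))
    ticks_per_bin = int(round(trace.dt / sampling_time))
    out = []
    for ch in range(trace.counts.shape[0]):
        c = trace.counts[ch]
        bins = np.repeat(np.arange(c.size, dtype=np.int64), c)
        offsets = rng.integers(0, ticks_per_bin, size=bins.size)
        times = np.sort(bins * ticks_per_bin + offsets + 1)
        out.append(
            ArrivalTrace(
                times=times,
                sampling_time=sampling_time,
                duration=trace.duration,
                channel=ch,
            )
        )
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------
# The point-measurement protocols state tau_d and s but not the beam waist r,
# which only sets the simulation scale (molecule count in the fixed box); the
# values below keep one-CPU runs tractable.  See docs/methods.md.


def _table1_model() -> CpchModel:
    T = 10e-6
    optical = OpticalConfig.from_structure_factor(r=0.45, s=1.928)
    sp = SpeciesParams.from_counts_per_bin(N=1.0, eps_A_bin=0.24448, T=T, tau_d=175.7e-6)
    return CpchModel(optical, (sp,))


def _fig4a_model() -> CpchModel:
    optical = OpticalConfig.from_structure_factor(r=0.6, s=1.928)
    sp1 = SpeciesParams(N=8.0, eps_A=48895.0, tau_d=87.85e-6)
    sp2 = SpeciesParams(N=2.0, eps_A=146686.0, tau_d=439.24e-6)
    return CpchModel(optical, (sp1, sp2))


def _fig4b_model() -> CpchModel:
    optical = OpticalConfig.from_structure_factor(r=0.6, s=1.928)
    sp1 = SpeciesParams(N=8.0, eps_A=48895.0, tau_d=21.96e-6)
    sp2 = SpeciesParams(N=5.0, eps_A=146686.0, tau_d=25.16e-6)
    return CpchModel(optical, (sp1, sp2))


def _table2_setup():
    optical = OpticalConfig.from_structure_factor(r=0.2651, s=1.93)
    sp = SpeciesParams.from_counts_per_bin(N=0.6, eps_A_bin=1.1, T=10e-6, D=100.0)
    model = CpchModel(optical, (sp,))
    geom = ScanGeometry(
        delta_x=0.0117,
        delta_y=0.0117,
        tau_pixel=10e-6,
        tau_line=1e-3,
        tau_frame=5e-3,
        pixels_per_line=256,
        lines=256,
    )
    return model, geom


def _fig3b_setup():
    model, geom = _table2_setup()
    o = model.optical
    slow = SpeciesParams(N=0.6, eps_A=1.1 / 10e-6, D=0.1)
    fast = SpeciesParams(N=0.6, eps_A=1.1 / 10e-6, D=200.0)
    return CpchModel(o, (slow, fast)), geom


def _dim_pair_model() -> CpchModel:
    # two dim species, brightness ratio 2, diffusion-time ratio 4
    optical = OpticalConfig.from_structure_factor(r=0.45, s=1.928)
    sp1 = SpeciesParams(N=1.0, eps_A=17780.0, tau_d=10.98e-6)
    sp2 = SpeciesParams(N=1.0, eps_A=35560.0, tau_d=43.92e-6)
    return CpchModel(optical, (sp1, sp2))


def _ligand_receptor_model(L: float = 5.0, R1: float = 2.0, R11: float = 1.0) -> CpchModel:
    """Three fluorescent species: free ligand L, singly (R1, 1x brightness)
    and doubly (R11, 2x brightness) bound receptor; receptor diffuses much
    slower than ligand.  Equilibrium chemistry is up to the caller."""
    optical = OpticalConfig.from_structure_factor(r=0.2651, s=1.93)
    eps = 1.0 / 10e-6
    ligand = SpeciesParams(N=L, eps_A=eps, D=100.0)
    single = SpeciesParams(N=R1, eps_A=eps, D=2.0)
    double = SpeciesParams(N=R11, eps_A=2 * eps, D=2.0)
    return CpchModel(optical, (ligand, single, double))


PRESETS = {
    "table1_single": {"kind": "trace", "model": _table1_model, "duration": 60.0, "dt": 10e-6},
    "fig4a_two_species": {"kind": "trace", "model": _fig4a_model, "duration": 30.0, "dt": 10e-6},
    "fig4b_brightness_only": {
        "kind": "trace",
        "model": _fig4b_model,
        "duration": 30.0,
        "dt": 10e-6,
    },
    "dim_pair_fig5c": {"kind": "trace", "model": _dim_pair_model, "duration": 30.0, "dt": 3.2e-6},
    "table2_spatial": {"kind": "image", "setup": _table2_setup, "frames": 5},
    "fig3b_mixture": {"kind": "image", "setup": _fig3b_setup, "frames": 2},
    "ligand_receptor_fig6-like": {
        "kind": "trace",
        "model": _ligand_receptor_model,
        "duration": 10.0,
        "dt": 10e-6,
    },
}


def make_fixture(preset_name: str, seed: int, out_dir, duration: Optional[float] = None):
    """Simulate a named preset and write trace/stack + ground-truth JSON.

    Returns the list of files written.  Same seed => byte-identical outputs.
    """
    from pathlib import Path
    from . import io as _io

    if preset_name not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}"
        )
    cfg = PRESETS[preset_name]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if cfg["kind"] == "trace":
        model = cfg["model"]()
        trace = simulate_trace(model, duration or cfg["duration"], cfg["dt"], seed=seed)
        path = out_dir / f"{preset_name}_seed{seed}.h5"
        _io.write_trace_h5(path, trace)
        written.append(path)
        truth_path = out_dir / f"{preset_name}_seed{seed}_truth.json"
        truth_path.write_text(trace.truth.to_json())
        written.append(truth_path)
    else:
        model, geom = cfg["setup"]()
        stack, truth = simulate_image_stack(model, geom, cfg["frames"], seed=seed)
        path = out_dir / f"{preset_name}_seed{seed}.tif"
        _io.write_stack_tiff(path, stack)
        written.append(path)
        truth_path = out_dir / f"{preset_name}_seed{seed}_truth.json"
        truth_path.write_text(truth.to_json())
        written.append(truth_path)
    return written
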