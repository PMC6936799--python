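"""File formats: traces and histograms in HDF5, image stacks in TIFF,
model configuration in TOML/JSON with explicit units."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import h5py
import numpy as np
import tifffile

from .theory import CpchModel, InvalidParameterError, OpticalConfig, SpeciesParams

__all__ = [
    "write_trace_h5",
    "read_trace_h5",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_histograms_h5",
    "read_histograms_h5",
    "write_pmf_h5",
    "read_pmf_h5",
    "write_table_h5",
    "read_table_h5",
    "read_model_config",
    "write_model_config",
    "convert_tttr",
]

# explicit unit strings accepted in config files, mapped to internal units
_LENGTH_UNITS = {"um": 1.0, "nm": 1e-3}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9}
_RATE_UNITS = {"counts_per_s": 1.0}


def write_trace_h5(path, trace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=trace.counts, compression=None)
        f.attrs["dt_s"] = trace.dt
        if trace.truth is not None:
            f.attrs["truth_json"] = trace.truth.to_json()


def read_trace_h5(path):
    from .simulate import BinnedTrace, GroundTruth

    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        dt = float(f.attrs["dt_s"])
        truth = None
        if "truth_json" in f.attrs:
            truth = GroundTruth.from_json(f.attrs["truth_json"])
    return BinnedTrace(counts=counts, dt=dt, truth=truth)


def write_stack_tiff(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_histograms_h5(path, hists) -> None:
    """One group per (tau, T) with the joint count histogram."""
    with h5py.File(path, "w") as f:
        for i, h in enumerate(hists):
            g = f.create_group(f"hist_{i:04d}")
            g.create_dataset("counts", data=h.counts)
            g.attrs["tau_s"] = h.tau
            g.attrs["T_s"] = h.T
            g.attrs["total_pairs"] = h.total_pairs


def read_histograms_h5(path):
    from .empirical import CpchHistogram

    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                CpchHistogram(
                    counts=g["counts"][...],
                    tau=float(g.attrs["tau_s"]),
                    T=float(g.attrs["T_s"]),
                    total_pairs=int(g.attrs["total_pairs"]),
                )
            )
    return out


def write_pmf_h5(path, pmf, model_hash: str = "") -> None:
    """Store a joint PMF with its (tau, T, model hash) attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("pmf", data=np.asarray(pmf.values))
        d.attrs["tau_s"] = pmf.tau
        d.attrs["T_s"] = pmf.T
        d.attrs["model_hash"] = model_hash or (pmf.meta or "")


def read_pmf_h5(path):
    from .distributions import JointPMF

    with h5py.File(path, "r") as f:
        d = f["pmf"]
        return JointPMF(
            values=d[...],
            tau=float(d.attrs["tau_s"]),
            T=float(d.attrs["T_s"]),
            meta=str(d.attrs.get("model_hash", "")),
        )


def write_table_h5(path, table) -> None:
    """CumulantTable to HDF5: one dataset per column plus the kind attr."""
    with h5py.File(path, "w") as f:
        for col in table.data.columns:
            f.create_dataset(col, data=table.data[col].to_numpy())
        f.attrs["kind"] = table.kind


def read_table_h5(path):
    import pandas as pd

    from .moments import CumulantTable

    with h5py.File(path, "r") as f:
        data = {k: f[k][...] for k in f.keys()}
        kind = str(f.attrs["kind"])
    return CumulantTable(pd.DataFrame(data), kind=kind)


def convert_tttr(path):
    """Stub for vendor time-tagged (TTTR) formats.

    Not implemented: supply arrival times as a plain list of integer
    detector ticks instead (CSV, one event per line, or an HDF5 uint64
    dataset) plus the sampling time in seconds; see
    :class:`cpch.empirical.ArrivalTrace`.
    """
    raise NotImplementedError(convert_tttr.__doc__)


def _quantity(entry, units: Dict[str, float], what: str) -> float:
    """Parse {'value': x, 'unit': 'us'} or [x, 'us']; bare numbers rejected."""
    if isinstance(entry, dict):
        value, unit = entry.get("value"), entry.get("unit")
    elif isinstance(entry, (list, tuple)) and len(entry) == 2:
        value, unit = entry
    else:
        raise InvalidParameterError(
            f"{what}: give a (value, unit) pair with an explicit unit, not a bare number"
        )
    if unit not in units:
        raise InvalidParameterError(f"{what}: unknown unit {unit!r}; allowed: {sorted(units)}")
    return float(value) * units[unit]


def read_model_config(path) -> CpchModel:
    """Model file (JSON or TOML) with [optical], [species.*], [background].

    All dimensional fields are (value, unit) pairs with explicit units, e.g.
    ``r_A = [0.25, "um"]``, ``tau_d = [50, "us"]``, ``eps_A = [24448,
    "counts_per_s"]``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    od = data["optical"]
    optical = OpticalConfig(
        r_A=_quantity(od["r_A"], _LENGTH_UNITS, "optical.r_A"),
        z_A=_quantity(od["z_A"], _LENGTH_UNITS, "optical.z_A"),
        r_B=_quantity(od["r_B"], _LENGTH_UNITS, "optical.r_B") if "r_B" in od else None,
        z_B=_quantity(od["z_B"], _LENGTH_UNITS, "optical.z_B") if "z_B" in od else None,
    )
    species = []
    sp_section = data["species"]
    items = sp_section.items() if isinstance(sp_section, dict) else enumerate(sp_section)
    for _, sd in items:
        kwargs = dict(N=float(sd["N"]))
        kwargs["eps_A"] = _quantity(sd["eps_A"], _RATE_UNITS, "species.eps_A")
        if "eps_B" in sd:
            kwargs["eps_B"] = _quantity(sd["eps_B"], _RATE_UNITS, "species.eps_B")
        if "tau_d" in sd:
            kwargs["tau_d"] = _quantity(sd["tau_d"], _TIME_UNITS, "species.tau_d")
        if "D" in sd:
            kwargs["D"] = float(sd["D"]["value"] if isinstance(sd["D"], dict) else sd["D"][0])
        species.append(SpeciesParams(**kwargs))
    bg = data.get("background", {})
    lam_A = _quantity(bg["lambda_A"], _RATE_UNITS, "background.lambda_A") if "lambda_A" in bg else 0.0
    lam_B = _quantity(bg["lambda_B"], _RATE_UNITS, "background.lambda_B") if "lambda_B" in bg else 0.0
    flow = None
    if "flow" in data:
        flow = (float(data["flow"]["v_x"][0]), float(data["flow"]["v_y"][0]))
    return CpchModel(optical, tuple(species), lambda_A=lam_A, lambda_B=lam_B, flow=flow)


def write_model_config(path, model: CpchModel) -> None:
    """Write a model as JSON with explicit units (readable back)."""
    o = model.optical
    data = {
        "optical": {
            "r_A": [o.r_A, "um"],
            "z_A": [o.z_A, "um"],
            "r_B": [o.r_B, "um"],
            "z_B": [o.z_B, "um"],
        },
        "species": [
            {
                "N": sp.N,
                "eps_A": [sp.eps_A, "counts_per_s"],
                "eps_B": [sp.eps_B, "counts_per_s"],
                "D": [sp.resolve_D(o), "um^2/s"],
            }
            for sp in model.species
        ],
        "background": {
            "lambda_A": [model.lambda_A, "counts_per_s"],
            "lambda_B": [model.lambda_B, "counts_per_s"],
        },
    }
    if model.flow is not None:
        data["flow"] = {"v_x": [model.flow[0], "um/s"], "v_y": [model.flow[1], "um/s"]}
    Path(path).write_text(json.dumps(data, indent=1))
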