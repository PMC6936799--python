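"""Diagnostic plots: FCS curves and cumulant fits (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_fcs", "plot_cumulant_fit"]


def plot_fcs(curve, ax=None, label=None):
    """Plot an FCS curve G(tau) on a log-time axis, with error bars if known."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if curve.variance is not None and np.any(np.isfinite(curve.variance)):
        ax.errorbar(curve.tau, curve.G, yerr=np.sqrt(curve.variance), fmt="o", ms=3, label=label)
    else:
        ax.plot(curve.tau, curve.G, "-", label=label)
    ax.set_xscale("log")
    ax.set_xlabel(r"$\tau$ (s)")
    ax.set_ylabel(r"$G(\tau)$")
    return ax


def plot_cumulant_fit(empirical_table, model_table, orders=((1, 1), (2, 1), (2, 2)), ax=None):
    """Empirical factorial cumulants (points, with error bars) vs model (lines)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for m, n in orders:
        emp = empirical_table.select(m=m, n=n).sort_values("tau_s")
        mod = model_table.select(m=m, n=n).sort_values("tau_s")
        line = ax.errorbar(
            emp.tau_s, emp.value, yerr=np.sqrt(emp.variance), fmt="x", ms=4,
            label=f"(K)$_{{{m},{n}}}$",
        )
        ax.plot(mod.tau_s, mod.value, "--", color=line.lines[0].get_color())
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$\tau$ (s)")
    ax.set_ylabel("factorial cumulant")
    ax.legend()
    return ax
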