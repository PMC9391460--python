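"""Overlay plots for fitted dose-response and melt curves (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_dose_response_fit", "plot_melt_fit", "plot_species_distribution"]


def plot_dose_response_fit(data, result, model_curve, ax=None, **curve_kwargs):
    """Data points (with error bars when present) and the fitted curve.

    ``model_curve`` is a callable c -> signal evaluated on a dense log grid,
    e.g. ``lambda c: quadratic_isotherm(c, **...)`` built from
    ``result.params``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if data.signal_err is not None:
        ax.errorbar(data.conc, data.signal, yerr=data.signal_err, fmt="o",
                    capsize=2, label="data")
    else:
        ax.plot(data.conc, data.signal, "o", label="data")
    grid = np.geomspace(data.conc[0], data.conc[-1], 300)
    ax.plot(grid, model_curve(grid), "-",
            label=f"{result.model_name} fit", **curve_kwargs)
    ax.set_xscale("log")
    ax.set_xlabel("titrant (uM)")
    ax.set_ylabel("signal")
    ax.legend()
    return ax


def plot_melt_fit(curve, fit, ax=None):
    """Melt curve with the fitted transition midpoints marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.temperature, curve.signal, ".", label="data")
    for tm, name in ((fit.tm1, "Tm1"), (fit.tm2, "Tm2")):
        ax.axvline(tm, linestyle="--", alpha=0.6)
        ax.annotate(f"{name} = {tm:.1f} C", (tm, ax.get_ylim()[1]),
                    rotation=90, va="top", fontsize=8)
    ax.set_xlabel("temperature (C)")
    ax.set_ylabel("signal")
    ax.legend()
    return ax


def plot_species_distribution(model, protein_total_monomer, ligand_grid,
                              ax=None):
    """Species concentrations versus total ligand for a coupled-equilibrium
    model (log-x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = model.species_table(protein_total_monomer, ligand_grid)
    for col in ("T", "D", "DL", "DLL", "L_free"):
        ax.plot(table["ligand_total_uM"], table[col], label=col)
    ax.set_xscale("log")
    ax.set_xlabel("total ligand (uM)")
    ax.set_ylabel("concentration (uM)")
    ax.legend()
    return ax
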