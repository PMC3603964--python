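"""Figure analogues: water-fraction contours, axis profiles, node series."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_results"]


def _contour_water(result, ax):
    t, T, f = result.frames[-1]
    pts, val = f["centroid"] * 1e6, f["x_vw"] * f["phi_liq"]
    sc = ax.scatter(pts[:, 1], pts[:, 0], c=val, s=18, cmap="viridis")
    ax.set_xlabel("z (um)")
    ax.set_ylabel("rho (um)")
    ax.set_title(f"water volume fraction at T = {T - 273.15:.1f} C")
    return sc


def _axis_profiles(result, ax, n_profiles=5):
    ks = np.linspace(0, len(result.frames) - 1, n_profiles).astype(int)
    for k in ks:
        t, T, f = result.frames[k]
        on_axis = np.abs(f["centroid"][:, 0]) < 4e-6
        z = f["centroid"][on_axis, 1] * 1e6
        v = (f["x_vw"] * f["phi_liq"])[on_axis]
        order = np.argsort(z)
        ax.plot(z[order], v[order], label=f"{T - 273.15:.1f} C")
    ax.set_xlabel("z (um)")
    ax.set_ylabel("water volume fraction")
    ax.legend(fontsize=7)


def _node_series(result, ax, column="X", ylabel="node ice volume fraction"):
    T = result.temperatures - 273.15
    for lab in result.node_labels():
        ax.plot(T, result.trace(lab, column), label=lab)
    ax.set_xlabel("temperature (C)")
    ax.set_ylabel(ylabel)
    ax.invert_xaxis()
    ax.legend(fontsize=7, ncol=3)


def plot_results(result, which: str, outdir=".") -> list:
    """Render one figure analogue; returns the written file paths.

    ``which``: "contour" (water-fraction map), "profiles" (axis profiles
    vs temperature), "node_ice" (per-node ice growth), "node_water"
    (per-node water concentration).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result is None or (result.node_traces is None and not result.frames):
        warnings.warn("empty result; nothing to plot")
        return []
    fig, ax = plt.subplots(figsize=(5.5, 4), dpi=110)
    if which == "contour":
        sc = _contour_water(result, ax)
        fig.colorbar(sc, ax=ax)
    elif which == "profiles":
        _axis_profiles(result, ax)
    elif which == "node_ice":
        _node_series(result, ax)
    elif which == "node_water":
        _node_series(result, ax, column="cw",
                     ylabel="node water concentration (mol/m^3)")
    else:
        plt.close(fig)
        raise ValueError(f"unknown figure id {which!r}")
    path = outdir / f"{which}.png"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return [path]
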