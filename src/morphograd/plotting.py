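"""Space-time heatmaps and profile-series plots."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .containers import SpaceTimeField

__all__ = ["plot_heatmap", "plot_profiles"]


def plot_heatmap(fld: SpaceTimeField, path: Union[str, Path], n_x: int = 300) -> None:
    """Space-time plot: x horizontal, t vertical, colour = concentration.

    Positions beyond the tissue edge at a given time are masked; a dashed
    line marks the transcription-zone boundary x = w when params are known.
    """
    xs = np.linspace(0.0, max(p.L for p in fld.profiles), n_x)
    grid = np.full((len(fld), n_x), np.nan)
    for i, p in enumerate(fld.profiles):
        inside = xs <= p.L
        grid[i, inside] = p.interp(xs[inside])
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(xs, fld.times, grid, shading="auto", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="concentration c")
    if fld.params is not None:
        ax.axvline(fld.params.w, color="w", linestyle="--", linewidth=1)
    ax.set_xlabel("position x")
    ax.set_ylabel("time t")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profiles(fld: SpaceTimeField, path: Union[str, Path]) -> None:
    """Concentration vs position, one curve per time (late times darker)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("plasma")
    for i, p in enumerate(fld.profiles):
        shade = 0.15 + 0.7 * i / max(len(fld) - 1, 1)
        ax.plot(p.x, p.c, color=cmap(shade), label=f"t = {p.t:g}")
    if fld.params is not None:
        ax.axvline(fld.params.w, color="k", linestyle="--", linewidth=1)
    ax.set_xlabel("position x")
    ax.set_ylabel("concentration c")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
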