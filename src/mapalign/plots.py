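"""Figure helpers for the CLI (termination zones, sweeps, energy fields)."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import (SweepResult, TerminationZone, SNAPSHOT_BAND_CENTERS,
                       density_1d, v1_azimuth_band_mask)
from .energies import EnergyField


def zone_panels(zones: List[TerminationZone]):
    """Combined SC map of all termination zones plus per-zone thumbnails."""
    n = len(zones)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows),
                             squeeze=False)
    for ax, z in zip(axes.ravel(), zones):
        xs, ys = z.sc_density.support
        ax.imshow(z.sc_density.values, origin="lower",
                  extent=(xs[0], xs[-1], ys[0], ys[-1]), cmap="magma")
        ax.plot(*z.seed_center, "c+", ms=10)
        ax.set_title(f"seed {z.seed_center}", fontsize=8)
        ax.set_xticks([]); ax.set_yticks([])
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    return fig


def profile_panel(state):
    """Five sampled azimuth density profiles (colored by V1 band)."""
    fig, ax = plt.subplots(figsize=(5, 3))
    cmap = plt.get_cmap("viridis")
    for i, c in enumerate(SNAPSHOT_BAND_CENTERS):
        hw = max(0.04, 0.75 * state.grid.spacing)
        mask = v1_azimuth_band_mask(state.grid, c, hw)
        prof = density_1d(state, axis="azimuth", layer="sc", v1_mask=mask)
        ax.plot(prof.support, prof.values, color=cmap(i / 4),
                label=f"V1 x={c:g}")
    ax.set_xlabel("SC azimuth (A-P)")
    ax.set_ylabel("normalized density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def convergence_panel(trace: Sequence[Tuple[int, float]]):
    fig, ax = plt.subplots(figsize=(5, 3))
    steps, dist = zip(*trace)
    ax.semilogx(steps, dist, "o-")
    ax.set_xlabel("step")
    ax.set_ylabel("profile distance")
    fig.tight_layout()
    return fig


def sweep_panel(res: SweepResult):
    """Density-vs-drive heat map plus selected profile samples."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    mat = np.asarray(res.profiles)
    ax1.imshow(mat.T, origin="lower", aspect="auto", cmap="magma",
               extent=(0, len(res.values), 0, 1))
    ax1.set_xticks(np.arange(len(res.values)) + 0.5)
    ax1.set_xticklabels([f"{v:g}" for v in res.values], fontsize=7)
    ax1.set_xlabel(res.parameter_name)
    ax1.set_ylabel("SC azimuth")
    for i in np.linspace(0, len(res.values) - 1, min(4, len(res.values))).astype(int):
        ax2.plot(res.support, res.profiles[i],
                 label=f"{res.parameter_name}={res.values[i]:g}")
    ax2.set_xlabel("SC azimuth")
    ax2.set_ylabel("normalized density")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    return fig


def field_panels(fields: List[EnergyField]):
    """3x3 grid of per-connection energy heat maps."""
    fig, axes = plt.subplots(3, 3, figsize=(9, 9))
    for ax, f in zip(axes.ravel(), fields):
        ax.imshow(f.as_matrix(), origin="lower", extent=(0, 1, 0, 1),
                  cmap="viridis")
        ax.set_title(f"V1 source {f.source}", fontsize=8)
        ax.set_xticks([]); ax.set_yticks([])
    fig.tight_layout()
    return fig
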