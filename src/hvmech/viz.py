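"""Minimal rendering of profiles and membrane maps to image files."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .structure import DensityProfile, MembraneMap

__all__ = ["plot_profile", "plot_map"]


def plot_profile(profile: DensityProfile, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.z_centers, profile.values, lw=1.2)
    ax.set_xlabel("z (nm)")
    ax.set_ylabel(f"{profile.weight_kind} density (nm$^{{-3}}$)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_map(mmap: MembraneMap, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    nx, ny = mmap.values.shape
    im = ax.imshow(
        mmap.values.T,
        origin="lower",
        extent=(0, nx * mmap.grid_edge, 0, ny * mmap.grid_edge),
        aspect="equal",
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label=mmap.kind)
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
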