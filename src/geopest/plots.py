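"""Figure export: variogram curves, kriging maps, vertical box plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kriging import KrigingSurface
from .samples import InstarGroup, SamplePoint, coords_array
from .variogram import EmpiricalVariogram, VariogramModel
from .vertical import vertical_matrix
from .samples import HEIGHT_CLASSES

__all__ = ["plot_variogram", "plot_surface", "plot_vertical_boxes"]


def plot_variogram(
    emp: EmpiricalVariogram,
    model: VariogramModel | None,
    path: str | Path,
    title: str = "",
) -> None:
    """Lag vs. semivariance scatter with the fitted curve overlaid."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(emp.lag_centers, emp.gamma, "o", color="k", label="empirical")
    if model is not None:
        h = np.linspace(0, emp.max_lag, 200)
        ax.plot(h, model.gamma(h), "-", color="tab:red", label=model.family)
    ax.set_xlabel("lag h (m)")
    ax.set_ylabel(r"semivariance $\gamma(h)$")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_surface(
    surface: KrigingSurface,
    points: Sequence[SamplePoint] | None,
    path: str | Path,
    title: str = "",
) -> None:
    """Filled-contour kriging map with sample locations overlaid."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    cs = ax.contourf(
        surface.grid_x, surface.grid_y, surface.estimates, levels=12, cmap="YlOrRd"
    )
    fig.colorbar(cs, ax=ax, label="predicted count")
    if points is not None:
        xy = coords_array(points)
        ax.plot(xy[:, 0], xy[:, 1], "k.", ms=3)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vertical_boxes(
    points: Sequence[SamplePoint], group: InstarGroup, path: str | Path
) -> None:
    """Per-height-class box plot of per-plant counts for one group."""
    mat = vertical_matrix(points, group)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.boxplot([mat[:, j] for j in range(mat.shape[1])], tick_labels=HEIGHT_CLASSES)
    ax.plot(range(1, mat.shape[1] + 1), mat.mean(axis=0), "o", color="tab:red")
    ax.set_xlabel("height class")
    ax.set_ylabel("larvae per plant")
    ax.set_title(f"vertical distribution ({group.value})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
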