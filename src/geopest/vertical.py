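"""Vertical (height-class) distribution summaries of larval counts.

Counts per plant are recorded in five 20-cm strata (0-20 up to 81-100
cm). For each instar group the per-class mean, median, quartiles and
standard deviation over plants are computed, plus the modal class (the
class with the largest mean count; ties go to the lower class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .samples import HEIGHT_CLASSES, InstarGroup, SamplePoint

__all__ = ["VerticalSummary", "summarize_vertical", "vertical_matrix"]


@dataclass
class VerticalSummary:
    """Per-height-class statistics of per-plant counts for one group."""

    group: InstarGroup
    classes: tuple[str, ...]
    mean: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    sd: np.ndarray
    modal_class: str


def vertical_matrix(points: Sequence[SamplePoint], group: InstarGroup) -> np.ndarray:
    """(n_plants, 5) matrix of height-class counts for ``group``.

    ``AVG`` averages the three observed groups' class counts per plant.
    Raises if any plant lacks height-class records for the group.
    """
    rows = []
    n_tall = 0
    for p in points:
        hcc = p.height_class_counts or {}
        if group is InstarGroup.AVG:
            mats = [hcc[g] for g in hcc]
            if not mats:
                raise ValueError(f"no vertical records for sample {p.id!r}")
            rows.append(np.mean([np.asarray(m, dtype=float) for m in mats], axis=0))
        else:
            if group not in hcc:
                raise ValueError(
                    f"no vertical records for sample {p.id!r}, group {group.value}"
                )
            rows.append(np.asarray(hcc[group], dtype=float))
        if p.plant_height is not None and p.plant_height > 100.0:
            n_tall += 1
    if n_tall:
        warnings.warn(
            f"{n_tall} plant(s) taller than 100 cm; counts above 100 cm "
            "are carried in the top class",
            stacklevel=2,
        )
    return np.array(rows)


def summarize_vertical(
    points: Sequence[SamplePoint], group: InstarGroup
) -> VerticalSummary:
    """Summarise the vertical placement of one instar group.

    Statistics are over all plants, zeros included. Quartiles use
    linear interpolation; the standard deviation is the sample (n-1)
    form, defined as 0 for a single plant.
    """
    mat = vertical_matrix(points, group)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if n > 1 else np.zeros(mat.shape[1])
    modal_idx = int(np.argmax(mean))  # argmax takes the first (lower) class on ties
    return VerticalSummary(
        group=group,
        classes=HEIGHT_CLASSES,
        mean=mean,
        median=np.median(mat, axis=0),
        q1=np.quantile(mat, 0.25, axis=0),
        q3=np.quantile(mat, 0.75, axis=0),
        sd=sd,
        modal_class=HEIGHT_CLASSES[modal_idx],
    )
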