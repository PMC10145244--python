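"""Sample-point data model, validation and delimited-text I/O.

A survey dataset is a list of :class:`SamplePoint` objects, one per host
plant: planar coordinates in metres, larval counts per instar group
(1st+2nd pooled, 3rd, 4th), plant morphology covariates, and optional
counts per 20-cm height class. All downstream stages (variogram
estimation, kriging, GLMs, vertical summaries) consume this container.

Coordinates are planar metres internally. Longitude/latitude input is
projected with a local equirectangular projection about the data
centroid, which is accurate to well under a metre at sub-kilometre
extents such as a single field site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InstarGroup",
    "SamplePoint",
    "SurveyDesign",
    "SampleValidationError",
    "HEIGHT_CLASSES",
    "HEIGHT_CLASS_MIDPOINTS",
    "HEIGHT_CLASS_BOUNDS",
    "validate_samples",
    "project_lonlat",
    "coords_array",
    "values_array",
    "read_samples_csv",
    "write_samples_csv",
]

#: Labels of the five vertical strata on the host plant (cm above ground).
HEIGHT_CLASSES: tuple[str, ...] = (
    "0-20 cm",
    "21-40 cm",
    "41-60 cm",
    "61-80 cm",
    "81-100 cm",
)

#: Class midpoints in cm, used as the continuous "distribution height" covariate.
HEIGHT_CLASS_MIDPOINTS: tuple[float, ...] = (10.0, 30.0, 50.0, 70.0, 90.0)

#: (lower, upper) bounds of each height class in cm.
HEIGHT_CLASS_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 20.0),
    (21.0, 40.0),
    (41.0, 60.0),
    (61.0, 80.0),
    (81.0, 100.0),
)

_EARTH_RADIUS_M = 6_371_008.8


class InstarGroup(str, Enum):
    """Larval instar groups analysed by the pipeline.

    First and second instars are morphologically indistinguishable in
    the field and are pooled (``I12``). ``AVG`` denotes the per-plant
    mean count over the three observed groups; it is a derived series,
    never stored on a sample point directly.
    """

    I12 = "i12"
    I3 = "i3"
    I4 = "i4"
    AVG = "avg"


#: Groups that carry observed counts (``AVG`` is derived from these).
OBSERVED_GROUPS: tuple[InstarGroup, ...] = (
    InstarGroup.I12,
    InstarGroup.I3,
    InstarGroup.I4,
)


class SampleValidationError(ValueError):
    """Raised when survey data violate a structural invariant."""


@dataclass
class SamplePoint:
    """One georeferenced host plant with its larval counts.

    Parameters
    ----------
    id : str
        Unique sample-point identifier.
    x, y : float
        Planar coordinates in metres.
    counts : mapping of InstarGroup to int
        Total larvae per observed instar group on this plant.
    plant_height, crown_width : float, optional
        Morphology in cm.
    ground_diameter : float, optional
        Morphology in mm.
    height_class_counts : mapping of InstarGroup to 5-sequence of int, optional
        Larvae per 20-cm height class; must sum to ``counts[group]``.
    """

    id: str
    x: float
    y: float
    counts: dict[InstarGroup, int] = field(default_factory=dict)
    plant_height: float | None = None
    crown_width: float | None = None
    ground_diameter: float | None = None
    height_class_counts: dict[InstarGroup, tuple[int, ...]] | None = None

    def count(self, group: InstarGroup) -> float:
        """Count for ``group``; ``AVG`` is the mean over observed groups."""
        if group is InstarGroup.AVG:
            vals = [self.counts[g] for g in OBSERVED_GROUPS if g in self.counts]
            if not vals:
                raise KeyError("no observed counts to average")
            return float(np.mean(vals))
        return float(self.counts[group])

    def total_count(self) -> int:
        return int(sum(self.counts.get(g, 0) for g in OBSERVED_GROUPS))


@dataclass
class SurveyDesign:
    """Checkerboard field-sampling design.

    Defaults follow a 63-point survey of 5 m x 5 m quadrats at 10 m
    spacing inside an extent of roughly 6.4 ha.
    """

    n_points: int = 63
    spacing: float = 10.0
    quadrat_side: float = 5.0
    extent: tuple[float, float] = (250.0, 250.0)

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")


def validate_samples(points: Sequence[SamplePoint]) -> list[SamplePoint]:
    """Validate a survey dataset and return it unchanged.

    Checks uniqueness of ids, finiteness and non-coincidence of
    coordinates, non-negative integer counts, strictly positive
    morphology where present, and height-class/total consistency.
    Idempotent: validating an already-valid list is the identity.

    Raises
    ------
    SampleValidationError
        On the first violated invariant, with a message naming it.
    """
    if not points:
        raise SampleValidationError("no samples")
    seen_ids: set[str] = set()
    for p in points:
        if p.id in seen_ids:
            raise SampleValidationError(f"duplicate sample id: {p.id!r}")
        seen_ids.add(p.id)
        if not (math.isfinite(p.x) and math.isfinite(p.y)):
            raise SampleValidationError(f"non-finite coordinates for sample {p.id!r}")
        for g, c in p.counts.items():
            if c < 0 or int(c) != c:
                raise SampleValidationError(
                    f"invalid count for sample {p.id!r}, group {g.value}: {c}"
                )
        for name, val, unit in (
            ("plant_height", p.plant_height, "cm"),
            ("crown_width", p.crown_width, "cm"),
            ("ground_diameter", p.ground_diameter, "mm"),
        ):
            if val is not None and not (val > 0 and math.isfinite(val)):
                raise SampleValidationError(
                    f"non-positive {name} for sample {p.id!r}: {val} {unit}"
                )
        if p.height_class_counts is not None:
            for g, hc in p.height_class_counts.items():
                hc = tuple(hc)
                if len(hc) != len(HEIGHT_CLASSES):
                    raise SampleValidationError(
                        f"height-class vector of length {len(hc)} for sample {p.id!r}"
                    )
                if any(c < 0 or int(c) != c for c in hc):
                    raise SampleValidationError(
                        f"invalid count in height classes of sample {p.id!r}"
                    )
                if g in p.counts and sum(hc) != p.counts[g]:
                    raise SampleValidationError(
                        f"height-class counts do not sum to total for sample "
                        f"{p.id!r}, group {g.value}: {sum(hc)} != {p.counts[g]}"
                    )
    xy = coords_array(points)
    if len(points) > 1:
        from scipy.spatial.distance import pdist

        if pdist(xy).min() < 1e-9:
            raise SampleValidationError("coincident coordinates")
    return list(points)


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray, origin: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to local planar metres.

    Equirectangular projection about ``origin`` (default: the centroid).
    Adequate for extents well below a kilometre.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if origin is None:
        origin = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = origin
    x = _EARTH_RADIUS_M * np.radians(lon - lon0) * math.cos(math.radians(lat0))
    y = _EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def coords_array(points: Sequence[SamplePoint]) -> np.ndarray:
    """(n, 2) array of planar coordinates in metres."""
    return np.array([[p.x, p.y] for p in points], dtype=float)


def values_array(points: Sequence[SamplePoint], group: InstarGroup) -> np.ndarray:
    """Count series for ``group`` (the kriged variable Z(x_i))."""
    return np.array([p.count(group) for p in points], dtype=float)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_CLASS_SLUGS = ("0_20", "21_40", "41_60", "61_80", "81_100")


def _columns() -> list[str]:
    cols = ["id", "x", "y"]
    cols += [f"count_{g.value}" for g in OBSERVED_GROUPS]
    cols += ["plant_height", "crown_width", "ground_diameter"]
    for g in OBSERVED_GROUPS:
        cols += [f"{g.value}_h{s}" for s in _CLASS_SLUGS]
    return cols


def write_samples_csv(points: Sequence[SamplePoint], path: str | Path) -> None:
    """Write sample points to CSV (one row per plant, header required)."""
    rows = []
    for p in points:
        row: dict[str, object] = {"id": p.id, "x": repr(p.x), "y": repr(p.y)}
        for g in OBSERVED_GROUPS:
            row[f"count_{g.value}"] = p.counts.get(g, "")
        row["plant_height"] = "" if p.plant_height is None else repr(p.plant_height)
        row["crown_width"] = "" if p.crown_width is None else repr(p.crown_width)
        row["ground_diameter"] = (
            "" if p.ground_diameter is None else repr(p.ground_diameter)
        )
        for g in OBSERVED_GROUPS:
            hc = (p.height_class_counts or {}).get(g)
            for s, c in zip(_CLASS_SLUGS, hc if hc is not None else [""] * 5):
                row[f"{g.value}_h{s}"] = c
        rows.append(row)
    pd.DataFrame(rows, columns=_columns()).to_csv(path, index=False)


def read_samples_csv(path: str | Path) -> list[SamplePoint]:
    """Read sample points written by :func:`write_samples_csv`.

    Lossless round-trip: floats are serialized with ``repr`` on write.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if "id" not in df.columns or "x" not in df.columns or "y" not in df.columns:
        raise SampleValidationError("missing required columns id, x, y")
    points: list[SamplePoint] = []
    for _, r in df.iterrows():
        counts: dict[InstarGroup, int] = {}
        for g in OBSERVED_GROUPS:
            v = r.get(f"count_{g.value}")
            if v is not None and not pd.isna(v):
                counts[g] = int(v)
        hcc: dict[InstarGroup, tuple[int, ...]] = {}
        for g in OBSERVED_GROUPS:
            vals = [r.get(f"{g.value}_h{s}") for s in _CLASS_SLUGS]
            if all(v is not None and not pd.isna(v) for v in vals):
                hcc[g] = tuple(int(v) for v in vals)

        def _opt(col: str) -> float | None:
            v = r.get(col)
            return None if v is None or pd.isna(v) else float(v)

        points.append(
            SamplePoint(
                id=str(r["id"]),
                x=float(r["x"]),
                y=float(r["y"]),
                counts=counts,
                plant_height=_opt("plant_height"),
                crown_width=_opt("crown_width"),
                ground_diameter=_opt("ground_diameter"),
                height_class_counts=hcc or None,
            )
        )
    return points
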