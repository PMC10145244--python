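"""Report and raster writers: delimited-text tables, Esri ASCII grids
and GeoJSON point export."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kriging import CrossValidation, KrigingSurface
from .regression import GlmResult, VifReport
from .samples import SamplePoint, OBSERVED_GROUPS
from .structure import SpatialStructure
from .variogram import EmpiricalVariogram, VariogramModel
from .vertical import VerticalSummary

__all__ = [
    "write_empirical_variogram",
    "write_fitted_models",
    "write_cross_validation",
    "write_structure_report",
    "write_glm_report",
    "write_vif_report",
    "write_vertical_summary",
    "write_esri_ascii",
    "write_geojson_points",
]


def write_empirical_variogram(emp: EmpiricalVariogram, path: str | Path) -> None:
    pd.DataFrame(
        {"lag_m": emp.lag_centers, "gamma": emp.gamma, "n_pairs": emp.n_pairs}
    ).to_csv(path, index=False)


def write_fitted_models(models: Mapping[str, VariogramModel], path: str | Path) -> None:
    rows = [
        {
            "family": fam,
            "nugget": m.nugget,
            "sill": m.sill,
            "range_m": m.range,
            "structural": m.structural,
        }
        for fam, m in models.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cross_validation(
    cvs: Mapping[str, CrossValidation], selected: str, path: str | Path
) -> None:
    rows = [
        {
            "family": fam,
            "beta0": cv.beta0,
            "beta1": cv.beta1,
            "r2": cv.r2,
            "rmse": cv.rmse,
            "me": cv.me,
            "selected": fam == selected,
        }
        for fam, cv in cvs.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_structure_report(
    structures: Sequence[SpatialStructure], path: str | Path
) -> None:
    """One row per instar group, mirroring the classic model-parameter table."""
    rows = [
        {
            "group": s.group.value,
            "model": s.family,
            "range_m": s.range,
            "nugget": s.nugget,
            "sill": s.sill,
            "lsd": s.lsd,
            "dependence": s.dependence_class,
            "distribution": s.distribution,
        }
        for s in structures
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_glm_report(result: GlmResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "term": result.terms,
            "df": result.df,
            "chi_square": result.wald_chisq,
            "estimate": result.estimates,
            "std_error": result.std_errors,
            "p": result.p_values,
        }
    ).to_csv(path, index=False)


def write_vif_report(report: VifReport, path: str | Path) -> None:
    rows = [
        {"term": t, "vif": v, "status": "dropped"} for t, v in report.dropped
    ] + [
        {"term": t, "vif": report.final_vifs.get(t, float("nan")), "status": "retained"}
        for t in report.retained
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vertical_summary(summary: VerticalSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "height_class": summary.classes,
            "mean": summary.mean,
            "median": summary.median,
            "q1": summary.q1,
            "q3": summary.q3,
            "sd": summary.sd,
            "modal": [c == summary.modal_class for c in summary.classes],
        }
    ).to_csv(path, index=False)


def write_esri_ascii(
    surface: KrigingSurface,
    path: str | Path,
    what: str = "estimates",
    nodata: float = -9999.0,
) -> None:
    """Write a kriging surface as an Esri ASCII grid (.asc).

    Rows are written north-to-south as the format requires.
    """
    grid = getattr(surface, what)
    cellsize = float(surface.grid_x[1] - surface.grid_x[0])
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {surface.grid_x[0] - cellsize / 2:.6f}\n"
        f"yllcorner {surface.grid_y[0] - cellsize / 2:.6f}\n"
        f"cellsize {cellsize:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(
        " ".join(f"{v:.6f}" for v in row) for row in np.flipud(grid)
    )
    Path(path).write_text(header + body + "\n")


def write_geojson_points(points: Sequence[SamplePoint], path: str | Path) -> None:
    features = []
    for p in points:
        props: dict = {"id": p.id}
        for g in OBSERVED_GROUPS:
            if g in p.counts:
                props[f"count_{g.value}"] = p.counts[g]
        for name in ("plant_height", "crown_width", "ground_diameter"):
            v = getattr(p, name)
            if v is not None:
                props[name] = v
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
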