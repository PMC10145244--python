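"""End-to-end analysis orchestration.

Runs the full survey analysis: validation, per-group empirical
variograms, candidate-model fitting, leave-one-out cross-validation and
model selection, spatial-dependence (LSD) classification, kriging
surfaces, vertical-distribution summaries and the morphology Poisson
GLM with VIF screening. All outputs are plain-text reports plus plots,
listed (with content hashes) in a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .io import (
    write_cross_validation,
    write_empirical_variogram,
    write_esri_ascii,
    write_fitted_models,
    write_geojson_points,
    write_glm_report,
    write_structure_report,
    write_vertical_summary,
    write_vif_report,
)
from .kriging import krige_grid, loo_cross_validate, select_model
from .plots import plot_surface, plot_variogram, plot_vertical_boxes
from .regression import DEFAULT_TERMS, PoissonCountGLM, to_long_format
from .samples import (
    InstarGroup,
    SamplePoint,
    read_samples_csv,
    validate_samples,
    write_samples_csv,
)
from .structure import build_structure
from .synthetic import SimulationConfig, simulate_survey
from .variogram import (
    DEFAULT_CANDIDATE_FAMILIES,
    empirical_variogram,
    fit_variogram,
)
from .vertical import summarize_vertical

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("geopest")

DEFAULT_GROUPS = (InstarGroup.I12, InstarGroup.I3, InstarGroup.I4, InstarGroup.AVG)


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    Exactly one of ``input_csv`` or ``simulation`` must be given.
    """

    output_dir: str | Path
    input_csv: str | Path | None = None
    simulation: SimulationConfig | None = None
    groups: Sequence[InstarGroup] = DEFAULT_GROUPS
    families: Sequence[str] = DEFAULT_CANDIDATE_FAMILIES
    lag_width: float = 10.0
    max_lag: float | None = None
    lsd_convention: str = "structural"
    vif_threshold: float = 5.0
    resolution: float = 2.0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("specify exactly one of input_csv or simulation")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all reports; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(fn, *args, name: str) -> Path:
        path = out / name
        fn(*args, path)
        written.append(path)
        return path

    log.info(
        "defaults in effect: lag_width=%s m, max_lag=%s, lsd_convention=%s, "
        "vif_threshold=%s, resolution=%s m, families=%s",
        config.lag_width,
        config.max_lag if config.max_lag is not None else "auto (half max distance)",
        config.lsd_convention,
        config.vif_threshold,
        config.resolution,
        list(config.families),
    )

    # --- load or simulate -------------------------------------------------
    @_stage("input")
    def _load() -> list[SamplePoint]:
        if config.simulation is not None:
            log.info("simulating survey (seed=%s)", config.simulation.seed)
            pts = simulate_survey(config.simulation)
            write_samples_csv(pts, out / "samples.csv")
            written.append(out / "samples.csv")
            return pts
        log.info("reading %s", config.input_csv)
        return read_samples_csv(config.input_csv)

    points = _load()

    @_stage("validate")
    def _validate() -> list[SamplePoint]:
        return validate_samples(points)

    points = _validate()
    emit(write_geojson_points, points, name="samples.geojson")

    selected_models: dict[str, str] = {}
    # --- per-group geostatistics -----------------------------------------
    structures = []
    for group in config.groups:
        tag = group.value

        @_stage(f"variogram[{tag}]")
        def _vario(group=group):
            emp = empirical_variogram(
                points, group, max_lag=config.max_lag, lag_width=config.lag_width
            )
            models = {f: fit_variogram(emp, f) for f in config.families}
            return emp, models

        emp, models = _vario()
        emit(write_empirical_variogram, emp, name=f"variogram_{tag}.csv")
        emit(write_fitted_models, models, name=f"models_{tag}.csv")

        @_stage(f"cross_validation[{tag}]")
        def _cv(group=group, models=models):
            cvs = {f: loo_cross_validate(points, group, m) for f, m in models.items()}
            return cvs, select_model(cvs)

        cvs, best = _cv()
        selected_models[tag] = best
        log.info("group %s: selected %s model", tag, best)
        emit(write_cross_validation, cvs, best, name=f"cross_validation_{tag}.csv")

        @_stage(f"structure[{tag}]")
        def _structure(group=group, models=models, emp=emp, best=best):
            return build_structure(group, models[best], emp, config.lsd_convention)

        structures.append(_structure())

        @_stage(f"kriging[{tag}]")
        def _krige(group=group, models=models, best=best):
            return krige_grid(points, group, models[best], resolution=config.resolution)

        surface = _krige()
        emit(write_esri_ascii, surface, name=f"surface_{tag}.asc")
        emit(
            lambda s, p: write_esri_ascii(s, p, what="variances"),
            surface,
            name=f"variance_{tag}.asc",
        )

        if config.make_plots:
            emit(plot_variogram, emp, models[best], name=f"variogram_{tag}.png")
            emit(plot_surface, surface, points, name=f"surface_{tag}.png")

    emit(write_structure_report, structures, name="structure_report.csv")

    # --- vertical distribution -------------------------------------------
    has_vertical = all(p.height_class_counts for p in points)
    if has_vertical:
        for group in config.groups:

            @_stage(f"vertical[{group.value}]")
            def _vert(group=group):
                return summarize_vertical(points, group)

            summary = _vert()
            emit(write_vertical_summary, summary, name=f"vertical_{group.value}.csv")
            if config.make_plots:
                emit(plot_vertical_boxes, points, group, name=f"vertical_{group.value}.png")

        # --- regression ---------------------------------------------------
        @_stage("regression")
        def _glm():
            data = to_long_format(points)
            est = PoissonCountGLM(
                terms=DEFAULT_TERMS, vif_threshold=config.vif_threshold
            ).fit(data.drop(columns=["count"]), data["count"])
            return est

        est = _glm()
        emit(write_glm_report, est.result_, name="glm_report.csv")
        if est.vif_report_ is not None:
            emit(write_vif_report, est.vif_report_, name="vif_report.csv")
    else:
        log.info("no height-class records; skipping vertical and GLM stages")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "geopest_version": __version__,
        "input": str(config.input_csv) if config.input_csv else "simulated",
        "seed": config.simulation.seed if config.simulation else None,
        "groups": [g.value for g in config.groups],
        "families": list(config.families),
        "lag_width": config.lag_width,
        "max_lag": config.max_lag,
        "lsd_convention": config.lsd_convention,
        "vif_threshold": config.vif_threshold,
        "resolution": config.resolution,
        "selected_models": selected_models,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
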