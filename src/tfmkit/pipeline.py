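"""End-to-end orchestration: detect → track → reconstruct → measure → compare.

A :class:`PipelineConfig` (YAML-backed, schema-validated, unknown keys
rejected) lists per-cell image pairs, masks and group labels plus all
analysis parameters; :func:`run_pipeline` executes the stages per cell and
writes the per-cell measurement table, per-cell field CSVs and traction-
magnitude maps, the group comparison report and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .beads import (BeadImagePair, DetectionParams, TrackingParams,
                    detect_beads, drift_correct, grid_displacements,
                    track_displacements)
from .fields import (read_image, read_mask, write_field_tiff,
                     write_gridded_csv, write_scattered_csv)
from .metrics import CellRegion, measure_cells, measurements_frame
from .stats import (ComparisonResult, GroupSample, group_summary,
                    mann_whitney_u, render_comparison_text, significance_stars)
from .substrate import RegularizationSetting, SubstrateModel, reconstruct_traction

__all__ = ["PipelineConfig", "CellInput", "analyze_pair", "run_pipeline",
           "render_report", "config_hash", "load_config"]

log = logging.getLogger(__name__)


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SubstrateSection(_StrictModel):
    young_modulus: float = 12_000.0   # Pa
    poisson_ratio: float = 0.5
    pixel_size: float = 0.16          # µm/px

    def build(self) -> SubstrateModel:
        return SubstrateModel(self.young_modulus, self.poisson_ratio, self.pixel_size)


class DetectionSection(_StrictModel):
    dog_sigma_small: float = 1.5
    dog_sigma_large: float = 2.0
    quality_level: float = 0.05
    min_distance: float = 5.0

    def build(self) -> DetectionParams:
        return DetectionParams(self.dog_sigma_small, self.dog_sigma_large,
                               self.quality_level, self.min_distance)


class TrackingSection(_StrictModel):
    window: int = 61
    pyramid_levels: int = 3
    max_residual: float | None = None     # None = no residual cut
    max_displacement: float = 30.0
    fb_check: bool = True

    def build(self) -> TrackingParams:
        return TrackingParams(
            window=self.window, pyramid_levels=self.pyramid_levels,
            max_residual=np.inf if self.max_residual is None else self.max_residual,
            max_displacement=self.max_displacement, fb_check=self.fb_check)


class CellInput(_StrictModel):
    cell_id: str
    group: str
    loaded: str
    relaxed: str
    mask: str


class PipelineConfig(_StrictModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    substrate: SubstrateSection = Field(default_factory=SubstrateSection)
    detection: DetectionSection = Field(default_factory=DetectionSection)
    tracking: TrackingSection = Field(default_factory=TrackingSection)
    grid_spacing: float = 13.0
    regularization: float = 2.47e-5
    drift_correction: bool = True
    compare_on: str = "max_traction_pa"
    output_dir: str = "tfm_output"
    seed: int = 0
    cells: list[CellInput] = Field(default_factory=list)

    @field_validator("grid_spacing")
    @classmethod
    def _spacing_ok(cls, v):
        if v < 1:
            raise ValueError("grid_spacing must be >= 1 px")
        return v


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(config: PipelineConfig) -> str:
    """SHA-256 over the canonical JSON dump; changes iff any value changes."""
    dump = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(dump.encode()).hexdigest()


def analyze_pair(loaded: np.ndarray, relaxed: np.ndarray, mask: np.ndarray,
                 substrate: SubstrateModel,
                 detection: DetectionParams | None = None,
                 tracking: TrackingParams | None = None,
                 grid_spacing: float = 13.0,
                 reg: RegularizationSetting | None = None,
                 drift_correction: bool = True,
                 cell_id: str = "cell", group: str = "") -> dict:
    """Run the full single-cell analysis chain on in-memory images.

    detect → track → (drift-correct) → grid → reconstruct → measure.
    Returns a dict with the per-cell measurement and every intermediate
    (anchors, scattered/gridded displacement, traction field).
    """
    pair = BeadImagePair(loaded, relaxed, substrate.pixel_size)
    anchors = detect_beads(relaxed, detection)
    if len(anchors) == 0:
        raise ValueError(f"cell {cell_id}: no beads detected")
    scattered = track_displacements(pair, anchors, tracking)
    if drift_correction:
        scattered = drift_correct(scattered, mask)
    gridded = grid_displacements(scattered, grid_spacing)
    disp_um = gridded.in_unit("um", substrate.pixel_size)
    traction = reconstruct_traction(disp_um, substrate, reg)
    region = CellRegion(mask, cell_id, group)
    measurement = measure_cells(traction, disp_um, [region], substrate)
    if not measurement:
        raise ValueError(f"cell {cell_id}: no grid node inside the mask")
    return {"measurement": measurement[0], "anchors": anchors,
            "scattered": scattered, "disp_um": disp_um, "traction": traction}


def _process_cell(cell: CellInput, config: PipelineConfig, out_dir: Path) -> dict:
    sub = config.substrate.build()
    loaded = read_image(cell.loaded)
    relaxed = read_image(cell.relaxed)
    mask = read_mask(cell.mask)

    t0 = time.perf_counter()
    res = analyze_pair(
        loaded, relaxed, mask, sub,
        detection=config.detection.build(), tracking=config.tracking.build(),
        grid_spacing=config.grid_spacing,
        reg=RegularizationSetting(config.regularization),
        drift_correction=config.drift_correction,
        cell_id=cell.cell_id, group=cell.group)
    anchors = res["anchors"]
    scattered = res["scattered"]
    disp_um = res["disp_um"]
    traction = res["traction"]
    measurement = [res["measurement"]]

    cell_dir = out_dir / "cells" / cell.cell_id
    cell_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "beads_csv": str(cell_dir / "bead_displacements.csv"),
        "field_csv": str(cell_dir / "fields.csv"),
        "traction_tiff": str(cell_dir / "traction_magnitude.tif"),
    }
    write_scattered_csv(outputs["beads_csv"], scattered)
    write_gridded_csv(outputs["field_csv"], disp_um, traction, sub.pixel_size)
    write_field_tiff(outputs["traction_tiff"], traction.magnitude)
    log.info("cell %s: %d beads, %d tracked, %.2f s", cell.cell_id,
             len(anchors), scattered.n_tracked, time.perf_counter() - t0)
    return {"measurement": measurement[0], "outputs": outputs,
            "n_beads": len(anchors), "n_tracked": scattered.n_tracked}


def render_report(measurements: pd.DataFrame,
                  comparisons: dict[str, ComparisonResult] | None) -> str:
    """Plain-text summary: per-group mean ± SEM and n, then each comparison."""
    if measurements.empty:
        raise ValueError("empty measurement table")
    lines = []
    groups = list(dict.fromkeys(measurements["group"]))
    for quantity in ("max_traction_pa", "mean_traction_pa", "strain_energy_j"):
        lines.append(quantity)
        for gname in groups:
            vals = measurements.loc[measurements["group"] == gname, quantity]
            m, sem, n = group_summary(GroupSample(gname, vals.to_numpy()))
            lines.append(f"  {gname}: {m:.6g} ± {sem:.3g} (mean ± SEM, n = {n})")
        if comparisons and quantity in comparisons:
            r = comparisons[quantity]
            lines.append(
                f"  {r.statistic_name} = {r.statistic_value:.6g}, "
                f"p = {r.p_value:.4g} ({r.method}) {significance_stars(r.p_value)}")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis chain for every configured cell.

    Fails fast (before any processing) if a referenced input file is
    missing. A cell whose stages fail is skipped and recorded in the
    manifest; the remaining cells are still processed. Outputs (CSV tables,
    traction maps, comparison report, manifest) are written under
    ``config.output_dir``; re-running with identical config and inputs
    reproduces the CSV outputs byte for byte.
    """
    if not config.cells:
        raise ValueError("config lists no cells")
    for cell in config.cells:
        for path in (cell.loaded, cell.relaxed, cell.mask):
            if not Path(path).is_file():
                raise FileNotFoundError(f"input file not found: {path}")

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results, failures, manifest_cells = [], [], []
    for cell in config.cells:
        try:
            res = _process_cell(cell, config, out_dir)
        except Exception as exc:  # isolate per-cell failures
            log.warning("cell %s failed: %s", cell.cell_id, exc)
            failures.append({"cell_id": cell.cell_id, "error": str(exc)})
            continue
        results.append(res)
        manifest_cells.append({
            "cell_id": cell.cell_id, "group": cell.group,
            "inputs": {"loaded": cell.loaded, "relaxed": cell.relaxed,
                       "mask": cell.mask},
            "outputs": res["outputs"],
            "n_beads": res["n_beads"], "n_tracked": res["n_tracked"],
        })

    measurements = measurements_frame([r["measurement"] for r in results])
    if not measurements.empty:
        measurements = measurements.sort_values("cell_id", kind="stable")
    table_path = out_dir / "cell_measurements.csv"
    measurements.to_csv(table_path, index=False, float_format="%.9g")

    comparisons: dict[str, ComparisonResult] = {}
    groups = list(dict.fromkeys(measurements["group"])) if not measurements.empty else []
    if len(groups) == 2:
        rows = []
        for quantity in ("max_traction_pa", "mean_traction_pa", "strain_energy_j"):
            a = GroupSample(groups[0], measurements.loc[
                measurements["group"] == groups[0], quantity].to_numpy())
            b = GroupSample(groups[1], measurements.loc[
                measurements["group"] == groups[1], quantity].to_numpy())
            r = mann_whitney_u(a, b)
            comparisons[quantity] = r
            ma, sa, na = group_summary(a)
            mb, sb, nb = group_summary(b)
            rows.append({
                "quantity": quantity,
                "group_a": groups[0], "mean_a": ma, "sem_a": sa, "n_a": na,
                "group_b": groups[1], "mean_b": mb, "sem_b": sb, "n_b": nb,
                "statistic": r.statistic_value, "p_value": r.p_value,
                "method": r.method, "stars": significance_stars(r.p_value),
            })
        pd.DataFrame(rows).to_csv(out_dir / "comparison.csv", index=False,
                                  float_format="%.9g")
    if not measurements.empty:
        (out_dir / "report.txt").write_text(
            render_report(measurements, comparisons or None) + "\n")

    manifest = {
        "software": {"name": "tfmkit", "version": __version__},
        "config_hash": config_hash(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "cells": manifest_cells,
        "failures": failures,
        "outputs": {"measurements": str(table_path)},
        "partial": bool(failures),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {"measurements": measurements, "comparisons": comparisons,
            "manifest": manifest}
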