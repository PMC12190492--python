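"""Synthetic traction-force-microscopy scenes with known ground truth.

The generator emulates a bead-TFM experiment end to end: an adhesion-like
traction pattern on a ~12 kPa incompressible substrate, the forward-model
displacement field it produces, ~100 nm beads rendered as diffraction-
limited Gaussian spots at subpixel positions, camera shot and read noise,
and a cell mask. Two-group cohorts (disease-like vs control-like traction
magnitudes) make every pipeline stage and the group comparison testable
without any real microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
import yaml
from scipy.interpolate import RegularGridInterpolator

from .fields import GriddedDisplacementField, TractionField, write_gridded_csv
from .metrics import CellMeasurement, CellRegion, strain_energy, traction_in_region
from .substrate import SubstrateModel, forward_displacement

__all__ = [
    "TractionPattern",
    "SceneConfig",
    "SyntheticScene",
    "make_traction_pattern",
    "render_beads",
    "generate_scene",
    "generate_cohort",
    "write_scene",
    "write_cohort",
]

_PATTERN_KINDS = ("circular_patch", "inward_dipole", "multi_adhesion_ring")


@dataclass(frozen=True)
class TractionPattern:
    """Parametric ground-truth traction pattern.

    ``circular_patch``: one uniformly loaded disk pushing along
    ``orientation`` (nonzero net force — useful for solver fixtures).
    ``inward_dipole``: two disks pulling toward their midpoint; zero net
    force by antisymmetric construction.
    ``multi_adhesion_ring``: ``n_patches`` disks evenly spaced on a circle,
    each pulling toward the center — a cartoon of focal-adhesion hotspots
    at the cell rim; zero net force by symmetry.

    ``magnitude`` is the plateau traction inside each disk (Pa), ``radius``
    the disk radius in px, ``center`` the pattern center in px. ``extent``
    is the center-to-patch distance for dipole/ring patterns (px). Each
    disk carries a cosine-tapered rim of width ``edge_width`` px (plateau
    of radius ``radius − edge_width`` at full magnitude): adhesion-scale
    tractions are not step functions, and a rim resolvable by the bead
    field keeps the synthetic truth within what bead-sampled displacement
    data can represent. ``edge_width=0`` gives hard-edged disks.
    """

    kind: str = "multi_adhesion_ring"
    magnitude: float = 1000.0
    radius: float = 24.0
    center: tuple[float, float] | None = None
    extent: float = 48.0
    orientation: float = 0.0
    n_patches: int = 6
    edge_width: float = 12.0

    def __post_init__(self):
        if self.kind not in _PATTERN_KINDS:
            raise ValueError(f"kind must be one of {_PATTERN_KINDS}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 <= self.edge_width < self.radius:
            raise ValueError("edge_width must lie in [0, radius)")
        if self.kind == "inward_dipole":
            object.__setattr__(self, "n_patches", 2)


def _disk_profile(X, Y, cx, cy, radius, edge_width):
    """Radial profile: 1 on the plateau, cosine taper over the rim, 0 outside."""
    r = np.hypot(X - cx, Y - cy)
    if edge_width <= 0:
        return (r <= radius).astype(float)
    r0 = radius - edge_width
    rim = np.cos(np.pi * (r - r0) / (2.0 * edge_width)) ** 2
    return np.where(r <= r0, 1.0, np.where(r <= radius, rim, 0.0))


def make_traction_pattern(pattern: TractionPattern, grid_shape: tuple[int, int],
                          grid_spacing: float,
                          image_shape: tuple[int, int] | None = None) -> TractionField:
    """Rasterize a traction pattern onto a regular grid (deterministic).

    ``grid_shape`` is (rows, cols) of nodes, ``grid_spacing`` px per node.
    Zero-net-force patterns cancel exactly: opposing patches are built from
    point-reflected copies of one disk so their node sets are congruent.
    Raises if any patch extends beyond the grid.
    """
    nr, nc = grid_shape
    x = np.arange(nc) * grid_spacing
    y = np.arange(nr) * grid_spacing
    X, Y = np.meshgrid(x, y)
    width, height = x[-1], y[-1]
    cx, cy = pattern.center if pattern.center is not None else (width / 2.0, height / 2.0)

    tx = np.zeros(grid_shape)
    ty = np.zeros(grid_shape)
    if pattern.kind == "circular_patch":
        patches = [(cx, cy, np.cos(pattern.orientation), np.sin(pattern.orientation))]
    else:
        n = pattern.n_patches
        angles = pattern.orientation + 2.0 * np.pi * np.arange(n) / n
        patches = [(cx + pattern.extent * np.cos(a), cy + pattern.extent * np.sin(a),
                    -np.cos(a), -np.sin(a)) for a in angles]  # pulling inward

    for px, py, dx, dy in patches:
        if (px - pattern.radius < 0 or px + pattern.radius > width or
                py - pattern.radius < 0 or py + pattern.radius > height):
            raise ValueError("traction patch extends beyond the grid bounds")
        prof = _disk_profile(X, Y, px, py, pattern.radius, pattern.edge_width)
        tx += pattern.magnitude * dx * prof
        ty += pattern.magnitude * dy * prof
    return TractionField(tx, ty, grid_spacing)


@dataclass(frozen=True)
class SceneConfig:
    """Synthetic-scene parameters.

    Defaults emulate the imaging conditions the generator stands in for:
    100 nm beads as Gaussian spots of σ ≈ 1.3 px (diffraction-limited at
    40×, 0.16 µm/px), ~60 beads per 100×100 px (mean spacing comparable to
    the 8 px analysis grid), Poisson shot noise plus Gaussian read noise of
    2 % of the bead peak, and a ~12 kPa incompressible substrate. Traction
    magnitudes default to the regime where bead displacements are 0.5–2 px.
    """

    image_shape: tuple[int, int] = (256, 256)
    bead_density: float = 60.0          # beads per 100x100 px
    psf_sigma: float = 1.3              # px
    bead_intensity: float = 1000.0
    background_level: float = 100.0
    noise_gaussian_sigma: float = 20.0  # read noise, intensity units
    noise_poisson_scale: float = 1.0    # photons per intensity unit; 0 = off
    substrate: SubstrateModel = field(default_factory=SubstrateModel)
    pattern: TractionPattern = field(default_factory=TractionPattern)
    grid_spacing: float = 8.0
    mask_margin: float = 20.0           # mask radius beyond outermost patch, px
    seed: int = 0

    def __post_init__(self):
        if self.bead_density <= 0 or self.bead_intensity <= 0:
            raise ValueError("bead density and intensity must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")

    @property
    def noiseless(self) -> "SceneConfig":
        return replace(self, noise_gaussian_sigma=0.0, noise_poisson_scale=0.0)


@dataclass
class SyntheticScene:
    """One synthetic acquisition with full ground truth attached."""

    config: SceneConfig
    truth_traction: TractionField
    truth_displacement: GriddedDisplacementField   # µm
    bead_positions_relaxed: np.ndarray             # (N, 2) x, y px
    bead_positions_loaded: np.ndarray
    relaxed: np.ndarray
    loaded: np.ndarray
    mask: np.ndarray
    truth_metrics: CellMeasurement


def render_beads(positions: np.ndarray, config: SceneConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render beads as Gaussian spots and apply the camera noise model.

    Each bead adds an isotropic Gaussian of σ = ``psf_sigma`` and peak
    ``bead_intensity`` at its subpixel position on a uniform background;
    Poisson shot noise (if ``noise_poisson_scale > 0``) and Gaussian read
    noise are then applied with the scene RNG.
    """
    h, w = config.image_shape
    img = np.full((h, w), float(config.background_level))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    reach = int(np.ceil(4 * config.psf_sigma))
    if positions.size:
        for x, y in positions:
            r0, r1 = int(np.floor(y)) - reach, int(np.floor(y)) + reach + 1
            c0, c1 = int(np.floor(x)) - reach, int(np.floor(x)) + reach + 1
            r0, r1 = max(r0, 0), min(r1, h)
            c0, c1 = max(c0, 0), min(c1, w)
            if r0 >= r1 or c0 >= c1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            img[r0:r1, c0:c1] += config.bead_intensity * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * config.psf_sigma ** 2))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.noise_poisson_scale > 0:
        img = rng.poisson(img * config.noise_poisson_scale) / config.noise_poisson_scale
    if config.noise_gaussian_sigma > 0:
        img = img + rng.normal(0.0, config.noise_gaussian_sigma, img.shape)
    return np.clip(img, 0.0, None)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate one fully synthetic TFM acquisition.

    Ground-truth displacement comes from the elastic forward model; relaxed
    bead positions are sampled uniformly at ``bead_density``; loaded
    positions are the relaxed ones displaced by bilinear interpolation of
    the truth field, exactly (all noise lives in the rendered images).
    Fixed ``config.seed`` reproduces the scene bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    g = config.grid_spacing
    grid_shape = (int(np.ceil(h / g)), int(np.ceil(w / g)))
    truth_traction = make_traction_pattern(config.pattern, grid_shape, g)
    truth_disp = forward_displacement(truth_traction, config.substrate)

    n_beads = int(round(config.bead_density * h * w / 1e4))
    positions = np.column_stack([
        rng.uniform(2.0, w - 2.0, n_beads),
        rng.uniform(2.0, h - 2.0, n_beads),
    ])

    gx = np.arange(grid_shape[1]) * g
    gy = np.arange(grid_shape[0]) * g
    ps = config.substrate.pixel_size
    disp_at = np.column_stack([
        RegularGridInterpolator((gy, gx), comp / ps, bounds_error=False,
                                fill_value=None)(positions[:, ::-1])
        for comp in (truth_disp.u_x, truth_disp.u_y)
    ])
    loaded_positions = positions + disp_at

    relaxed_img = render_beads(positions, config, rng)
    loaded_img = render_beads(loaded_positions, config, rng)

    pattern = config.pattern
    cx, cy = pattern.center if pattern.center is not None else \
        ((grid_shape[1] - 1) * g / 2.0, (grid_shape[0] - 1) * g / 2.0)
    reach = pattern.radius + config.mask_margin
    if pattern.kind != "circular_patch":
        reach += pattern.extent
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - cx) ** 2 + (yy - cy) ** 2 <= reach ** 2).astype(np.uint8)

    region = CellRegion(mask, cell_id=f"scene-{config.seed}")
    tmax, tmean = traction_in_region(truth_traction, region)
    energy = strain_energy(truth_traction, truth_disp, config.substrate)
    truth = CellMeasurement(region.cell_id, "", tmax, tmean, energy,
                            n_grid_nodes=int(mask.sum()))
    return SyntheticScene(config, truth_traction, truth_disp, positions,
                          loaded_positions, relaxed_img, loaded_img, mask, truth)


def generate_cohort(n_cells_per_group: int,
                    magnitudes: dict[str, tuple[float, float]] | None = None,
                    config: SceneConfig | None = None,
                    seed: int = 0) -> dict[str, list[SyntheticScene]]:
    """Generate a two-group cohort of synthetic cells.

    ``magnitudes`` maps each group label to ``(mean_pa, cv)``; per-cell
    pattern magnitudes are drawn from N(mean, cv·mean) truncated at 10 % of
    the mean. Defaults emulate a disease-like vs control-like design
    (1000 vs 600 Pa, CV 20 %). Scenes are independently seeded from the
    master seed, so a fixed seed reproduces the whole cohort.
    """
    if n_cells_per_group < 1:
        raise ValueError("need at least one cell per group")
    if magnitudes is None:
        magnitudes = {"DMD": (1000.0, 0.2), "WT": (600.0, 0.2)}
    if config is None:
        config = SceneConfig()
    master = np.random.default_rng(seed)
    cohort: dict[str, list[SyntheticScene]] = {}
    for label, (mean, cv) in magnitudes.items():
        scenes = []
        for _ in range(n_cells_per_group):
            mag = float(np.clip(master.normal(mean, cv * mean), 0.1 * mean, None))
            scene_seed = int(master.integers(0, 2 ** 31 - 1))
            cfg = replace(config, seed=scene_seed,
                          pattern=replace(config.pattern, magnitude=mag))
            scene = generate_scene(cfg)
            scene.truth_metrics.group = label
            scene.truth_metrics.cell_id = f"{label}-{len(scenes):03d}"
            scenes.append(scene)
        cohort[label] = scenes
    return cohort


def write_scene(scene: SyntheticScene, out_dir) -> dict[str, str]:
    """Export one scene: TIFF image pair, PNG mask, ground-truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "loaded": str(out / "loaded.tif"),
        "relaxed": str(out / "relaxed.tif"),
        "mask": str(out / "mask.png"),
        "truth_fields": str(out / "truth_fields.csv"),
        "truth_beads": str(out / "truth_beads.csv"),
    }
    tifffile.imwrite(paths["loaded"], np.clip(scene.loaded, 0, 65535).astype(np.uint16))
    tifffile.imwrite(paths["relaxed"], np.clip(scene.relaxed, 0, 65535).astype(np.uint16))
    iio.imwrite(paths["mask"], (scene.mask * 255).astype(np.uint8))
    write_gridded_csv(paths["truth_fields"], scene.truth_displacement,
                      scene.truth_traction, scene.config.substrate.pixel_size)
    pd.DataFrame({
        "x_relaxed": scene.bead_positions_relaxed[:, 0],
        "y_relaxed": scene.bead_positions_relaxed[:, 1],
        "x_loaded": scene.bead_positions_loaded[:, 0],
        "y_loaded": scene.bead_positions_loaded[:, 1],
    }).to_csv(paths["truth_beads"], index=False, float_format="%.9g")
    return paths


def write_cohort(cohort: dict[str, list[SyntheticScene]], out_dir) -> dict[str, str]:
    """Export a cohort: per-scene directories, manifest CSV, pipeline config.

    Writes each scene under ``<out_dir>/<cell_id>/``, a ``cohort.csv``
    manifest (scene path, group, truth metrics) and a ready-to-run
    ``pipeline_config.yaml`` listing every cell for the analysis pipeline.
    Returns the manifest and config paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cells = [], []
    substrate = None
    for label, scenes in cohort.items():
        for scene in scenes:
            cid = scene.truth_metrics.cell_id
            paths = write_scene(scene, out / cid)
            tm = scene.truth_metrics
            rows.append({
                "cell_id": cid, "group": label, "scene_dir": str(out / cid),
                "truth_max_traction_pa": tm.max_traction,
                "truth_mean_traction_pa": tm.mean_traction,
                "truth_strain_energy_j": tm.strain_energy,
            })
            cells.append({"cell_id": cid, "group": label,
                          "loaded": paths["loaded"], "relaxed": paths["relaxed"],
                          "mask": paths["mask"]})
            substrate = scene.config.substrate
    manifest_path = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False, float_format="%.9g")
    config = {
        "substrate": {"young_modulus": substrate.young_modulus,
                      "poisson_ratio": substrate.poisson_ratio,
                      "pixel_size": substrate.pixel_size},
        "output_dir": str(out / "analysis"),
        "cells": cells,
    }
    config_path = out / "pipeline_config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return {"manifest": str(manifest_path), "config": str(config_path)}
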