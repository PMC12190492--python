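"""Per-cell contractility readouts.

Two scalar readouts per cell, following standard traction-force-microscopy
practice: the maximum (and mean) traction magnitude over grid nodes inside
the cell region, and the strain energy the cell stores in the gel,

    U = ½ Σ_nodes (T · u) ΔA ,

summed over the full field of view with ΔA the physical area per grid node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import GriddedDisplacementField, TractionField
from .substrate import SubstrateModel

__all__ = [
    "CellRegion",
    "CellMeasurement",
    "strain_energy",
    "traction_in_region",
    "measure_cells",
    "measurements_frame",
]

log = logging.getLogger(__name__)


@dataclass
class CellRegion:
    """Binary cell mask aligned to the bead images, plus identifiers."""

    mask: np.ndarray
    cell_id: str
    group: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask) > 0
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError(f"mask for cell {self.cell_id!r} has no nonzero pixel")


@dataclass
class CellMeasurement:
    cell_id: str
    group: str
    max_traction: float      # Pa
    mean_traction: float     # Pa
    strain_energy: float     # J
    n_grid_nodes: int

    def __post_init__(self):
        if self.max_traction < self.mean_traction:
            raise ValueError("max_traction must be >= mean_traction")


def strain_energy(traction: TractionField, disp: GriddedDisplacementField,
                  substrate: SubstrateModel) -> float:
    """Strain energy stored in the gel over the full field of view, in J.

    ``½ Σ (t_x u_x + t_y u_y) ΔA`` with tractions in Pa, displacements
    converted to µm, and ΔA = (grid_spacing · pixel_size)² µm²;
    1 Pa·µm·µm² = 1e-18 J.
    """
    if traction.shape != disp.shape or traction.grid_spacing != disp.grid_spacing:
        raise ValueError("traction and displacement grids do not match")
    d = disp.in_unit("um", substrate.pixel_size)
    da_um2 = (traction.grid_spacing * substrate.pixel_size) ** 2
    dot = traction.t_x * d.u_x + traction.t_y * d.u_y
    return float(0.5 * dot.sum() * da_um2 * 1e-18)


def traction_in_region(traction: TractionField, region: CellRegion) -> tuple[float, float]:
    """Max and mean traction magnitude (Pa) over grid nodes inside the mask.

    Grid nodes are mapped to mask pixels by nearest pixel; nodes falling
    outside the mask image are ignored. Raises if no node overlaps the mask.
    """
    X, Y = traction.node_positions_px()
    cols = np.round(X).astype(int)
    rows = np.round(Y).astype(int)
    h, w = region.mask.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    sel = np.zeros_like(inside)
    sel[inside] = region.mask[rows[inside], cols[inside]]
    if not sel.any():
        raise ValueError(
            f"cell {region.cell_id!r}: no traction grid node overlaps the mask")
    mag = traction.magnitude[sel]
    return float(mag.max()), float(mag.mean())


def measure_cells(traction: TractionField, disp: GriddedDisplacementField,
                  regions: list[CellRegion], substrate: SubstrateModel) -> list[CellMeasurement]:
    """Tabulate per-cell readouts for every region on one reconstructed field.

    Strain energy is computed once over the full field of view (it is a
    property of the acquisition, not of the mask); the region only selects
    nodes for the traction statistics. A failing region is logged and
    skipped; the remaining cells are still measured.
    """
    out: list[CellMeasurement] = []
    if not regions:
        return out
    energy = strain_energy(traction, disp, substrate)
    for region in regions:
        try:
            tmax, tmean = traction_in_region(traction, region)
            n_nodes = int(_nodes_in_mask(traction, region))
            out.append(CellMeasurement(region.cell_id, region.group,
                                       tmax, tmean, energy, n_nodes))
        except ValueError as exc:
            log.warning("skipping cell %s: %s", region.cell_id, exc)
    return out


def _nodes_in_mask(traction: TractionField, region: CellRegion) -> int:
    X, Y = traction.node_positions_px()
    cols = np.round(X).astype(int)
    rows = np.round(Y).astype(int)
    h, w = region.mask.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    sel = np.zeros_like(inside)
    sel[inside] = region.mask[rows[inside], cols[inside]]
    return sel.sum()


def measurements_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    """Per-cell results as a DataFrame with the package's standard columns."""
    return pd.DataFrame(
        [{
            "cell_id": m.cell_id,
            "group": m.group,
            "max_traction_pa": m.max_traction,
            "mean_traction_pa": m.mean_traction,
            "strain_energy_j": m.strain_energy,
            "n_grid_nodes": m.n_grid_nodes,
        } for m in measurements]
    )
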