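"""Vector-field containers and their plain-text / TIFF serialization.

Coordinate conventions used throughout the package:

* images are 2D arrays indexed ``[row, col]``, origin top-left;
* positions are continuous ``(x, y)`` pairs with ``x = column`` and
  ``y = row``, 0-based;
* regular grids are defined by ``grid_origin`` (the ``(x, y)`` pixel
  position of node ``[0, 0]``) and ``grid_spacing`` (pixels between
  adjacent nodes along either axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

__all__ = [
    "GriddedDisplacementField",
    "TractionField",
    "ScatteredDisplacementField",
    "read_image",
    "read_mask",
    "write_gridded_csv",
    "read_gridded_csv",
    "write_scattered_csv",
    "read_scattered_csv",
    "write_field_tiff",
]

_VALID_UNITS = ("px", "um")


def _as_2d_float(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2D array, got ndim={a.ndim}")
    return a


@dataclass
class GriddedDisplacementField:
    """Substrate displacement sampled on a regular grid.

    ``u_x``/``u_y`` hold the displacement components per node, in the unit
    recorded by ``unit`` (``"px"`` or ``"um"``).
    """

    u_x: np.ndarray
    u_y: np.ndarray
    grid_spacing: float
    grid_origin: tuple[float, float] = (0.0, 0.0)
    unit: str = "um"

    def __post_init__(self):
        self.u_x = _as_2d_float(self.u_x, "u_x")
        self.u_y = _as_2d_float(self.u_y, "u_y")
        if self.u_x.shape != self.u_y.shape:
            raise ValueError(
                f"u_x {self.u_x.shape} and u_y {self.u_y.shape} differ in shape"
            )
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1 pixel")
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape

    def node_positions_px(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel positions ``(X, Y)`` of every node (arrays shaped like the grid)."""
        nr, nc = self.shape
        x0, y0 = self.grid_origin
        x = x0 + np.arange(nc) * self.grid_spacing
        y = y0 + np.arange(nr) * self.grid_spacing
        return np.meshgrid(x, y)

    def in_unit(self, unit: str, pixel_size: float) -> "GriddedDisplacementField":
        """Return a copy converted to ``unit`` using ``pixel_size`` (µm/px)."""
        if unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}")
        if unit == self.unit:
            factor = 1.0
        elif unit == "um":  # px -> um
            factor = pixel_size
        else:  # um -> px
            factor = 1.0 / pixel_size
        return GriddedDisplacementField(
            self.u_x * factor, self.u_y * factor,
            self.grid_spacing, self.grid_origin, unit,
        )


@dataclass
class TractionField:
    """In-plane traction stress (Pa) on a regular grid."""

    t_x: np.ndarray
    t_y: np.ndarray
    grid_spacing: float
    grid_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.t_x = _as_2d_float(self.t_x, "t_x")
        self.t_y = _as_2d_float(self.t_y, "t_y")
        if self.t_x.shape != self.t_y.shape:
            raise ValueError("t_x and t_y differ in shape")
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1 pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.t_x.shape

    @property
    def magnitude(self) -> np.ndarray:
        """Per-node traction magnitude |T| in Pa."""
        return np.hypot(self.t_x, self.t_y)

    def node_positions_px(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.shape
        x0, y0 = self.grid_origin
        x = x0 + np.arange(nc) * self.grid_spacing
        y = y0 + np.arange(nr) * self.grid_spacing
        return np.meshgrid(x, y)


@dataclass
class ScatteredDisplacementField:
    """Bead-anchored displacement vectors.

    ``anchors`` are bead positions in the traction-free (relaxed) image,
    ``vectors`` the per-bead displacement (loaded minus relaxed, px).
    Lost beads have ``status == False`` and NaN vectors.
    """

    anchors: np.ndarray          # (N, 2) as (x, y)
    vectors: np.ndarray          # (N, 2) as (dx, dy), NaN where lost
    status: np.ndarray           # (N,) bool
    image_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.anchors = np.atleast_2d(np.asarray(self.anchors, dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.status = np.asarray(self.status, dtype=bool).ravel()
        if not (len(self.anchors) == len(self.vectors) == len(self.status)):
            raise ValueError("anchors, vectors and status must have equal length")
        # lost beads carry no vector
        self.vectors = self.vectors.copy()
        self.vectors[~self.status] = np.nan

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def n_tracked(self) -> int:
        return int(self.status.sum())

    @property
    def tracked_anchors(self) -> np.ndarray:
        return self.anchors[self.status]

    @property
    def tracked_vectors(self) -> np.ndarray:
        return self.vectors[self.status]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a single-plane grayscale image (TIFF/PNG) as float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse trivial channel axes
        img = img.mean(axis=-1) if img.shape[-1] <= 4 else img[0]
    if img.ndim != 2:
        raise ValueError(f"{path} is not a single-plane grayscale image")
    return img.astype(float)


def read_mask(path) -> np.ndarray:
    """Read a binary region mask (TIFF or PNG); nonzero pixels are inside."""
    return read_image(path) > 0


_FLOAT_FMT = "%.9g"


def write_gridded_csv(path, disp: GriddedDisplacementField | None,
                      traction: TractionField | None, pixel_size: float) -> None:
    """Write grid fields to CSV: row, col, x_um, y_um[, ux, uy][, tx, ty, tmag].

    Displacement components are written in µm regardless of the field's
    internal unit. Row order is (row, col) lexicographic, byte-stable.
    """
    ref = disp if disp is not None else traction
    if ref is None:
        raise ValueError("need at least one of disp, traction")
    nr, nc = ref.shape
    X, Y = ref.node_positions_px()
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    data = {
        "row": rows.ravel(), "col": cols.ravel(),
        "x_um": (X * pixel_size).ravel(), "y_um": (Y * pixel_size).ravel(),
    }
    if disp is not None:
        d = disp.in_unit("um", pixel_size)
        data["ux"] = d.u_x.ravel()
        data["uy"] = d.u_y.ravel()
    if traction is not None:
        if traction.shape != (nr, nc):
            raise ValueError("displacement and traction grids differ in shape")
        data["tx"] = traction.t_x.ravel()
        data["ty"] = traction.t_y.ravel()
        data["tmag"] = traction.magnitude.ravel()
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gridded_csv(path, pixel_size: float, grid_spacing: float,
                     grid_origin=(0.0, 0.0)):
    """Read fields written by :func:`write_gridded_csv`.

    Returns ``(disp, traction)``; either may be None if its columns are absent.
    """
    df = pd.read_csv(path)
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1
    df = df.sort_values(["row", "col"])

    def grid(col):
        return df[col].to_numpy().reshape(nr, nc)

    disp = None
    if "ux" in df.columns:
        disp = GriddedDisplacementField(grid("ux"), grid("uy"),
                                        grid_spacing, grid_origin, unit="um")
    traction = None
    if "tx" in df.columns:
        traction = TractionField(grid("tx"), grid("ty"), grid_spacing, grid_origin)
    return disp, traction


def write_scattered_csv(path, field: ScatteredDisplacementField) -> None:
    """Write a scattered field to CSV with columns x, y, dx, dy, status."""
    pd.DataFrame({
        "x": field.anchors[:, 0], "y": field.anchors[:, 1],
        "dx": field.vectors[:, 0], "dy": field.vectors[:, 1],
        "status": field.status.astype(int),
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_scattered_csv(path, image_shape=None) -> ScatteredDisplacementField:
    df = pd.read_csv(path)
    return ScatteredDisplacementField(
        df[["x", "y"]].to_numpy(), df[["dx", "dy"]].to_numpy(),
        df["status"].to_numpy() > 0, image_shape,
    )


def write_field_tiff(path, *channels: np.ndarray) -> None:
    """Write one or more same-shape 2D arrays as a 32-bit float TIFF stack."""
    stack = np.stack([np.asarray(c, dtype=np.float32) for c in channels])
    tifffile.imwrite(path, stack if len(channels) > 1 else stack[0])
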