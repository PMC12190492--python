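"""Elastic half-space forward and inverse solvers (Fourier-space Boussinesq).

The substrate is modelled as a linear elastic, semi-infinite half-space with
Young's modulus *E* and Poisson ratio *ν*. A tangential traction field T(x)
applied at the surface produces a surface displacement field u(x) given, in
Fourier space, by per-wavevector multiplication with the 2×2 Boussinesq
Green's tensor

    G̃(k) = 2(1+ν) / (E |k|³) · [ (1−ν)|k|² + ν ky²,  −ν kx ky
                                  −ν kx ky,           (1−ν)|k|² + ν kx² ]

Traction reconstruction inverts this relation per wavevector with Tikhonov
(ridge) regularization, the standard regularized Fourier-transform traction
cytometry (FTTC) scheme.

Unit conventions: internally the solvers work in "E·pixel" units — lengths
and wavevectors in pixels, tractions divided by E — so the regularization
parameter λ is applied to the E-nondimensionalized normal equations with
displacements expressed in pixels. Physical units (µm displacements, Pa
tractions) are converted at the boundaries of each function. ν = 0.5
(incompressible gel) causes no singularity anywhere in the tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import GriddedDisplacementField, TractionField

__all__ = [
    "SubstrateModel",
    "RegularizationSetting",
    "InvalidFrequencyError",
    "greens_tensor_fourier",
    "forward_displacement",
    "reconstruct_traction",
]


class InvalidFrequencyError(ValueError):
    """Raised when the Green's tensor is evaluated at the zero wavevector."""


@dataclass(frozen=True)
class SubstrateModel:
    """Elastic half-space parameters plus imaging optics.

    Parameters
    ----------
    young_modulus : float
        Young's modulus E of the gel, Pa. Default 12 000 Pa (~12 kPa PDMS,
        the stiffness regime of muscle tissue).
    poisson_ratio : float
        Poisson ratio ν in [0, 0.5]; 0.5 = incompressible (default).
    pixel_size : float
        Physical size of one camera pixel, µm/px. Default 0.16 µm/px
        (typical 40× objective).
    """

    young_modulus: float = 12_000.0
    poisson_ratio: float = 0.5
    pixel_size: float = 0.16

    def __post_init__(self):
        if not self.young_modulus > 0:
            raise ValueError("young_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class RegularizationSetting:
    """Tikhonov regularization strength λ, in pixel-normalized units.

    λ is added to the diagonal of G̃ᵀG̃ with the Green's tensor
    nondimensionalized by E and displacements in pixels (see module
    docstring); this is the one place the λ-unit interpretation lives.
    Default 2.47e-5.
    """

    lam: float = 2.47e-5

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


def _greens_components(kx, ky, nu):
    """E-normalized Green's tensor components (units: px) for |k| > 0.

    ``kx``/``ky`` are angular spatial frequencies in rad/px; returns
    ``(gxx, gxy, gyy)`` of Ĝ = E·G̃ broadcast over the inputs. The caller
    is responsible for masking the zero mode.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k2 = kx * kx + ky * ky
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (k2 * np.sqrt(k2))
        gxx = pref * ((1.0 - nu) * k2 + nu * ky * ky)
        gyy = pref * ((1.0 - nu) * k2 + nu * kx * kx)
        gxy = -pref * nu * kx * ky
    return gxx, gxy, gyy


def greens_tensor_fourier(kx: float, ky: float, substrate: SubstrateModel) -> np.ndarray:
    """Fourier-space Boussinesq Green's tensor G̃(k) at one wavevector.

    Returns the symmetric positive-definite 2×2 tensor mapping a traction
    Fourier mode (Pa) to a displacement mode, in length units consistent
    with 1/k. Diverges as |k| → 0; the zero wavevector is rejected.
    """
    if kx == 0 and ky == 0:
        raise InvalidFrequencyError(
            "Green's tensor is undefined at the zero wavevector; "
            "the zero mode is handled by the field-level solvers"
        )
    gxx, gxy, gyy = _greens_components(kx, ky, substrate.poisson_ratio)
    return np.array([[gxx, gxy], [gxy, gyy]]) / substrate.young_modulus


def _wavevectors(shape, spacing):
    """Angular frequency grids (rad/px) for an FFT of the given grid shape."""
    nr, nc = shape
    ky = 2.0 * np.pi * np.fft.fftfreq(nr, d=spacing)
    kx = 2.0 * np.pi * np.fft.fftfreq(nc, d=spacing)
    return np.meshgrid(kx, ky)


def forward_displacement(traction: TractionField, substrate: SubstrateModel,
                         pad_factor: int = 2) -> GriddedDisplacementField:
    """Surface displacement produced by a traction field (forward model).

    Per-wavevector multiplication ũ(k) = G̃(k)·T̃(k) with ũ(0) = 0. The
    traction grid is zero-padded to ``pad_factor``× its linear size before
    the FFT so that the implicit periodic images are pushed away from the
    field of view (exact for compactly supported traction); ``pad_factor=1``
    gives the plain periodic solution. Output displacements are in µm on
    the same grid.
    """
    tx, ty = traction.t_x, traction.t_y
    if not (np.all(np.isfinite(tx)) and np.all(np.isfinite(ty))):
        raise ValueError("traction field contains non-finite values")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    nr, nc = traction.shape
    e = substrate.young_modulus
    npr, npc = pad_factor * nr, pad_factor * nc
    tpx = np.zeros((npr, npc))
    tpy = np.zeros((npr, npc))
    tpx[:nr, :nc] = tx / e
    tpy[:nr, :nc] = ty / e

    kx, ky = _wavevectors((npr, npc), traction.grid_spacing)
    gxx, gxy, gyy = _greens_components(kx, ky, substrate.poisson_ratio)
    zero = (kx == 0) & (ky == 0)
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0

    ftx = np.fft.fft2(tpx)
    fty = np.fft.fft2(tpy)
    ux = np.real(np.fft.ifft2(gxx * ftx + gxy * fty))[:nr, :nc]
    uy = np.real(np.fft.ifft2(gxy * ftx + gyy * fty))[:nr, :nc]
    # px -> µm
    ps = substrate.pixel_size
    return GriddedDisplacementField(ux * ps, uy * ps, traction.grid_spacing,
                                    traction.grid_origin, unit="um")


def _taper_window(nr, nc, width):
    """2D window: 1 in the interior, cosine ramp to 0 over ``width`` nodes."""
    def ramp(n):
        w = np.ones(n)
        if width > 0:
            t = 0.5 * (1.0 - np.cos(np.pi * np.arange(width) / width))
            w[:width] = t
            w[-width:] = t[::-1]
        return w
    return np.outer(ramp(nr), ramp(nc))


def reconstruct_traction(disp: GriddedDisplacementField, substrate: SubstrateModel,
                         reg: RegularizationSetting | None = None,
                         pad_factor: int = 2,
                         taper_width: int | None = None) -> TractionField:
    """Regularized FTTC traction reconstruction.

    Solves, per wavevector, the Tikhonov normal equations
    ``T̃(k) = (G̃ᵀG̃ + λI)⁻¹ G̃ᵀ ũ(k)`` with ``T̃(0) = 0`` (global force
    balance); the mean displacement is subtracted before inversion. With
    ``pad_factor > 1`` the displacement grid is cosine-tapered at its border
    (over ``taper_width`` nodes, default ``min(8, n // 8)``) and zero-padded
    to suppress wrap-around artifacts, then cropped back. ``pad_factor=1``
    disables padding and tapering, making the λ=0 inversion the exact
    per-wavevector inverse of :func:`forward_displacement` (pad_factor=1)
    on the same grid.
    """
    if reg is None:
        reg = RegularizationSetting()
    nr, nc = disp.shape
    if min(nr, nc) < 4:
        raise ValueError("displacement grid must be at least 4x4")
    ux = disp.u_x
    uy = disp.u_y
    if not (np.all(np.isfinite(ux)) and np.all(np.isfinite(uy))):
        raise ValueError("displacement field contains non-finite values")
    if disp.unit == "um":
        ux = ux / substrate.pixel_size
        uy = uy / substrate.pixel_size
    # enforce zero mode: remove mean displacement (rigid offset is unobservable)
    ux = ux - ux.mean()
    uy = uy - uy.mean()

    if pad_factor > 1:
        if taper_width is None:
            taper_width = int(min(8, min(nr, nc) // 8))
        win = _taper_window(nr, nc, taper_width)
        ux = ux * win
        uy = uy * win
        npr, npc = pad_factor * nr, pad_factor * nc
        upx = np.zeros((npr, npc))
        upy = np.zeros((npr, npc))
        upx[:nr, :nc] = ux
        upy[:nr, :nc] = uy
        ux, uy = upx, upy
    kx, ky = _wavevectors(ux.shape, disp.grid_spacing)
    gxx, gxy, gyy = _greens_components(kx, ky, substrate.poisson_ratio)
    zero = (kx == 0) & (ky == 0)
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0

    fux = np.fft.fft2(ux)
    fuy = np.fft.fft2(uy)
    lam = reg.lam
    # G is symmetric, so GᵀG has components:
    a = gxx * gxx + gxy * gxy + lam
    b = gxy * (gxx + gyy)
    c = gyy * gyy + gxy * gxy + lam
    det = a * c - b * b
    det[zero] = 1.0  # avoid 0/0; modes forced to zero below
    # rhs = Gᵀũ = Gũ
    rx = gxx * fux + gxy * fuy
    ry = gxy * fux + gyy * fuy
    ftx = (c * rx - b * ry) / det
    fty = (a * ry - b * rx) / det
    ftx[zero] = 0.0
    fty[zero] = 0.0
    tx = np.real(np.fft.ifft2(ftx))[:nr, :nc]
    ty = np.real(np.fft.ifft2(fty))[:nr, :nc]
    e = substrate.young_modulus
    return TractionField(tx * e, ty * e, disp.grid_spacing, disp.grid_origin)
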