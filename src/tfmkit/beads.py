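"""Bead detection and displacement tracking.

Fiducial beads are detected in the traction-free (relaxed) image —
difference-of-Gaussian band-pass, Shi–Tomasi minimum-eigenvalue corner
response, non-maximum suppression, quadratic subpixel refinement — and then
tracked into the traction-loaded image with a windowed pyramidal
Lucas–Kanade optical-flow tracker (default window 61 px). Displacement is
measured in the reference configuration of the relaxed gel, matching the
convention of Fourier-transform traction cytometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError
from skimage.feature import corner_shi_tomasi, peak_local_max

from .fields import GriddedDisplacementField, ScatteredDisplacementField

__all__ = [
    "BeadImagePair",
    "DetectionParams",
    "TrackingParams",
    "dog_filter",
    "detect_beads",
    "track_displacements",
    "drift_correct",
    "grid_displacements",
]


@dataclass
class BeadImagePair:
    """A traction-loaded / traction-free bead image pair.

    ``loaded`` is acquired with cells exerting force on the gel; ``relaxed``
    after cell release (the undeformed reference).
    """

    loaded: np.ndarray
    relaxed: np.ndarray
    pixel_size: float = 0.16  # µm/px

    def __post_init__(self):
        self.loaded = np.asarray(self.loaded, dtype=float)
        self.relaxed = np.asarray(self.relaxed, dtype=float)
        if self.loaded.ndim != 2 or self.relaxed.ndim != 2:
            raise ValueError("images must be 2D grayscale")
        if self.loaded.shape != self.relaxed.shape:
            raise ValueError(
                f"image shapes differ: loaded {self.loaded.shape} vs "
                f"relaxed {self.relaxed.shape}"
            )
        if np.any(self.loaded < 0) or np.any(self.relaxed < 0):
            raise ValueError("image intensities must be non-negative")


@dataclass
class DetectionParams:
    """Bead-detection parameters.

    The two DoG sigmas (defaults 1.5 / 2.0 px) band-pass the image around
    the bead spot size before the minimum-eigenvalue response is computed;
    ``quality_level`` is the detection threshold as a fraction of the
    strongest response, ``min_distance`` the non-maximum-suppression radius.
    """

    dog_sigma_small: float = 1.5
    dog_sigma_large: float = 2.0
    quality_level: float = 0.05
    min_distance: float = 5.0

    def __post_init__(self):
        if not 0 < self.dog_sigma_small < self.dog_sigma_large:
            raise ValueError("require 0 < dog_sigma_small < dog_sigma_large")
        if not 0 < self.quality_level < 1:
            raise ValueError("quality_level must be in (0, 1)")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")


@dataclass
class TrackingParams:
    """Lucas–Kanade tracking parameters.

    ``window`` is the (odd) side length of the tracking window in px
    (default 61, chosen for smooth displacement estimates); ``max_residual``
    is the largest acceptable RMS intensity mismatch between the template
    and the matched window (np.inf disables the cut); ``max_displacement``
    bounds plausible bead motion; ``fb_tolerance`` is the forward-backward
    consistency bound in px. ``weight_sigma`` (default ``window / 10``)
    Gaussian-weights the window so the estimate follows the central bead
    rather than the average motion of every bead in the support.
    """

    window: int = 61
    pyramid_levels: int = 3
    max_residual: float = np.inf
    max_displacement: float = 30.0
    fb_check: bool = True
    fb_tolerance: float = 1.0
    weight_sigma: float | None = None

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.weight_sigma is None:
            # concentrate the estimate on the tracked bead while keeping the
            # wide support for robustness; uniform weighting would average
            # the motion of every bead in the 61-px window
            self.weight_sigma = self.window / 10.0


def dog_filter(image: np.ndarray, sigma_small: float = 1.5,
               sigma_large: float = 2.0) -> np.ndarray:
    """Difference-of-Gaussian band-pass filter.

    Returns ``G(σ_small)∗image − G(σ_large)∗image``; suppresses both flat
    background and pixel noise, enhancing spot-like bead profiles.
    """
    if sigma_small <= 0 or sigma_large <= 0:
        raise ValueError("sigmas must be positive")
    if sigma_small >= sigma_large:
        raise ValueError("require sigma_small < sigma_large")
    image = np.asarray(image, dtype=float)
    return ndi.gaussian_filter(image, sigma_small) - ndi.gaussian_filter(image, sigma_large)


def _quadratic_subpixel(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """1D quadratic peak interpolation along each axis; clamped to ±0.5 px."""
    dy = dx = 0.0
    if 0 < r < resp.shape[0] - 1:
        denom = resp[r - 1, c] - 2 * resp[r, c] + resp[r + 1, c]
        if denom < 0:
            dy = float(np.clip(0.5 * (resp[r - 1, c] - resp[r + 1, c]) / denom, -0.5, 0.5))
    if 0 < c < resp.shape[1] - 1:
        denom = resp[r, c - 1] - 2 * resp[r, c] + resp[r, c + 1]
        if denom < 0:
            dx = float(np.clip(0.5 * (resp[r, c - 1] - resp[r, c + 1]) / denom, -0.5, 0.5))
    return dx, dy


def detect_beads(image: np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Detect bead centers with subpixel precision.

    DoG-filters the image, computes the structure-tensor minimum-eigenvalue
    (Shi–Tomasi) response, thresholds at ``quality_level`` × max response,
    applies non-maximum suppression of radius ``min_distance`` and refines
    each peak by quadratic interpolation. Returns an (N, 2) array of
    ``(x, y)`` positions sorted by decreasing response; an image without
    structure yields an empty array.
    """
    if params is None:
        params = DetectionParams()
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    if np.ptp(image) == 0:
        return np.empty((0, 2))
    filt = dog_filter(image, params.dog_sigma_small, params.dog_sigma_large)
    resp = corner_shi_tomasi(filt, sigma=1)
    rmax = resp.max()
    if rmax <= 0:
        return np.empty((0, 2))
    peaks = peak_local_max(
        resp,
        min_distance=int(round(params.min_distance)),
        threshold_abs=params.quality_level * rmax,
        exclude_border=True,
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    order = np.argsort(resp[peaks[:, 0], peaks[:, 1]])[::-1]
    peaks = peaks[order]
    out = np.empty((len(peaks), 2))
    nr, nc = filt.shape
    for i, (r, c) in enumerate(peaks):
        # re-center on the band-passed intensity peak (the corner response
        # can sit one pixel off the spot apex), then refine quadratically
        # on the smoother DoG profile
        r0, r1 = max(r - 1, 0), min(r + 2, nr)
        c0, c1 = max(c - 1, 0), min(c + 2, nc)
        dr, dc = np.unravel_index(np.argmax(filt[r0:r1, c0:c1]), (r1 - r0, c1 - c0))
        r, c = r0 + dr, c0 + dc
        dx, dy = _quadratic_subpixel(filt, r, c)
        out[i] = (c + dx, r + dy)
    return out


# ---------------------------------------------------------------------------
# Lucas–Kanade tracking
# ---------------------------------------------------------------------------

def _build_pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(image, dtype=float)]
    for _ in range(levels - 1):
        sm = ndi.gaussian_filter(pyr[-1], 1.0)
        pyr.append(sm[::2, ::2].copy())
    return pyr


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndi.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_level(tmpl: np.ndarray, target: np.ndarray, grad: tuple[np.ndarray, np.ndarray],
              p: np.ndarray, d0: np.ndarray, hw: int, weight_sigma: float,
              max_iter: int = 25, tol: float = 5e-3):
    """Iterative translation-only LK at one pyramid level.

    ``p`` is the anchor (x, y) in level coordinates, ``d0`` the initial
    displacement guess; the normal equations are Gaussian-weighted
    (σ = ``weight_sigma``) around the window center. Returns
    (d, residual_rms, converged).
    """
    off = np.arange(-hw, hw + 1, dtype=float)
    xs0, ys0 = np.meshgrid(off, off)
    wgt = np.exp(-(xs0 ** 2 + ys0 ** 2) / (2.0 * weight_sigma ** 2)).ravel()
    xs0 = xs0.ravel() + p[0]
    ys0 = ys0.ravel() + p[1]
    T = _sample(tmpl, ys0, xs0)
    gy, gx = grad
    d = np.array(d0, dtype=float)
    wsum = wgt.sum()
    e = T  # placeholder
    for _ in range(max_iter):
        ys = ys0 + d[1]
        xs = xs0 + d[0]
        I = _sample(target, ys, xs)
        Ix = _sample(gx, ys, xs)
        Iy = _sample(gy, ys, xs)
        e = T - I
        wIx = wgt * Ix
        wIy = wgt * Iy
        gxx = wIx @ Ix
        gxy = wIx @ Iy
        gyy = wIy @ Iy
        det = gxx * gyy - gxy * gxy
        if det <= 1e-12 * max(gxx * gyy, 1e-300):
            return d, float(np.sqrt((wgt * e * e).sum() / wsum)), False
        bx = wIx @ e
        by = wIy @ e
        step = np.array([(gyy * bx - gxy * by) / det, (gxx * by - gxy * bx) / det])
        d += step
        if np.hypot(*step) < tol:
            break
    return d, float(np.sqrt((wgt * e * e).sum() / wsum)), True


def _track_points(pyr_src: list, pyr_dst: list, grads_dst: list,
                  anchors: np.ndarray, params: TrackingParams,
                  init: np.ndarray | None = None):
    hw = (params.window - 1) // 2
    levels = len(pyr_src)
    n = len(anchors)
    vectors = np.zeros((n, 2))
    residuals = np.zeros(n)
    status = np.ones(n, dtype=bool)
    for i, a in enumerate(anchors):
        d = np.zeros(2) if init is None else np.array(init[i], dtype=float)
        converged = True
        for lev in range(levels - 1, -1, -1):
            s = 2.0 ** lev
            d_l, res, converged = _lk_level(
                pyr_src[lev], pyr_dst[lev], grads_dst[lev],
                np.asarray(a, dtype=float) / s, d / s, hw,
                max(params.weight_sigma / s, 1.0),
            )
            d = d_l * s
        vectors[i] = d
        residuals[i] = res
        if np.hypot(*d) > params.max_displacement or res > params.max_residual:
            status[i] = False
    return vectors, residuals, status


def track_displacements(pair: BeadImagePair, anchors: np.ndarray,
                        params: TrackingParams | None = None) -> ScatteredDisplacementField:
    """Track anchors from the relaxed image into the loaded image.

    Pyramidal window-based Lucas–Kanade flow; each vector is the bead
    position in the loaded image minus its position in the relaxed image.
    Beads failing the residual, displacement-magnitude, or forward-backward
    consistency criteria are flagged lost (their vectors are NaN).
    """
    if params is None:
        params = TrackingParams()
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    if anchors.size == 0:
        raise ValueError("no anchors to track")
    levels = params.pyramid_levels
    pyr_rel = _build_pyramid(pair.relaxed, levels)
    pyr_load = _build_pyramid(pair.loaded, levels)
    grads_load = [np.gradient(p) for p in pyr_load]

    vectors, residuals, status = _track_points(
        pyr_rel, pyr_load, grads_load, anchors, params)

    if params.fb_check:
        tracked = np.nonzero(status)[0]
        if len(tracked):
            grads_rel = [np.gradient(p) for p in pyr_rel]
            back, _, bstat = _track_points(
                pyr_load, pyr_rel, grads_rel,
                anchors[tracked] + vectors[tracked], params,
                init=-vectors[tracked],
            )
            fb_err = np.hypot(*(vectors[tracked] + back).T)
            status[tracked] &= bstat & (fb_err <= params.fb_tolerance)

    return ScatteredDisplacementField(anchors, vectors, status,
                                      image_shape=pair.relaxed.shape)


def drift_correct(field: ScatteredDisplacementField,
                  cell_mask: np.ndarray | None = None,
                  min_reference: int = 5) -> ScatteredDisplacementField:
    """Remove rigid stage drift between the two acquisitions.

    Subtracts the median vector of tracked beads outside the cell region
    (all tracked beads when no mask is given). With fewer than
    ``min_reference`` reference beads a warning is issued and the field is
    returned unchanged.
    """
    ref = field.status.copy()
    if cell_mask is not None:
        mask = np.asarray(cell_mask) > 0
        cols = np.clip(np.round(field.anchors[:, 0]).astype(int), 0, mask.shape[1] - 1)
        rows = np.clip(np.round(field.anchors[:, 1]).astype(int), 0, mask.shape[0] - 1)
        ref &= ~mask[rows, cols]
    if ref.sum() < min_reference:
        warnings.warn(
            f"only {int(ref.sum())} reference beads (< {min_reference}); "
            "drift correction skipped", stacklevel=2)
        return ScatteredDisplacementField(
            field.anchors.copy(), field.vectors.copy(), field.status.copy(),
            field.image_shape)
    drift = np.nanmedian(field.vectors[ref], axis=0)
    return ScatteredDisplacementField(
        field.anchors.copy(), field.vectors - drift, field.status.copy(),
        field.image_shape)


def grid_displacements(field: ScatteredDisplacementField, spacing: float = 13.0,
                       image_shape: tuple[int, int] | None = None) -> GriddedDisplacementField:
    """Interpolate a scattered bead field onto a regular grid (unit px).

    Linear interpolation of each component inside the convex hull of the
    tracked beads; nodes outside the hull are filled by nearest-neighbour
    extrapolation. The grid starts at the image origin with the given node
    spacing. Degenerate (collinear) bead sets raise ``ValueError``.

    The default spacing (13 px) matches the mean bead spacing at typical
    seeding density (~60 beads per 100×100 px): gridding finer than the
    bead spacing manufactures sub-data-resolution structure from the
    triangulation, which the traction inversion then amplifies.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1 px")
    if image_shape is None:
        image_shape = field.image_shape
    if image_shape is None:
        raise ValueError("image_shape required when the field does not carry one")
    pts = field.tracked_anchors
    vec = field.tracked_vectors
    if len(pts) < 4:
        raise ValueError(f"need >= 4 tracked beads, have {len(pts)}")
    h, w = image_shape
    gx = np.arange(0.0, w, spacing)
    gy = np.arange(0.0, h, spacing)
    X, Y = np.meshgrid(gx, gy)
    out = []
    for comp in range(2):
        try:
            lin = LinearNDInterpolator(pts, vec[:, comp])
        except QhullError as exc:
            raise ValueError("degenerate (collinear) bead positions") from exc
        vals = lin(X, Y)
        nan = np.isnan(vals)
        if nan.any():
            near = NearestNDInterpolator(pts, vec[:, comp])
            vals[nan] = near(X[nan], Y[nan])
        out.append(vals)
    return GriddedDisplacementField(out[0], out[1], spacing, (0.0, 0.0), unit="px")
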