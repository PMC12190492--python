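"""Elastic half-space solvers: Green's tensor, forward model, inversion."""

import numpy as np
import pytest

from tfmkit.fields import GriddedDisplacementField, TractionField
from tfmkit.substrate import (InvalidFrequencyError, RegularizationSetting,
                              SubstrateModel, forward_displacement,
                              greens_tensor_fourier, reconstruct_traction)
from tfmkit.synthetic import TractionPattern, make_traction_pattern


def boussinesq_convolution(traction: TractionField, substrate: SubstrateModel):
    """Direct real-space convolution with the Boussinesq surface kernel.

    Independent oracle for the FFT forward solver: G_ij(r) =
    (1+ν)/(πE r³)·[(1−ν)r²δ_ij + ν r_i r_j], with the singular self-cell
    integrated analytically over a square cell (∫ dA/r = 4h·asinh(1)).
    Returns displacement components in grid (pixel) length units.
    """
    e, nu = substrate.young_modulus, substrate.poisson_ratio
    h = traction.grid_spacing
    nr, nc = traction.shape
    X, Y = traction.node_positions_px()
    pos = np.column_stack([X.ravel(), Y.ravel()])
    tv = np.column_stack([traction.t_x.ravel(), traction.t_y.ravel()])
    u = np.zeros_like(tv)
    self_coeff = (1 + nu) * (1 - nu / 2) * 4 * np.arcsinh(1.0) * h / (np.pi * e)
    area = h * h
    for s in np.nonzero(np.abs(tv).sum(axis=1))[0]:
        d = pos - pos[s]
        r2 = d[:, 0] ** 2 + d[:, 1] ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            pref = (1 + nu) / (np.pi * e * r2 * np.sqrt(r2))
            gxx = pref * ((1 - nu) * r2 + nu * d[:, 0] ** 2)
            gyy = pref * ((1 - nu) * r2 + nu * d[:, 1] ** 2)
            gxy = pref * nu * d[:, 0] * d[:, 1]
        zero = r2 == 0
        gxx[zero] = gyy[zero] = gxy[zero] = 0.0
        u[:, 0] += (gxx * tv[s, 0] + gxy * tv[s, 1]) * area
        u[:, 1] += (gxy * tv[s, 0] + gyy * tv[s, 1]) * area
        u[s] += self_coeff * tv[s]
    return u[:, 0].reshape(nr, nc), u[:, 1].reshape(nr, nc)


class TestGreensTensor:
    @pytest.mark.parametrize("kx,ky,expected", [
        (1.0, 0.0, [[1.5, 0.0], [0.0, 3.0]]),
        (0.0, 1.0, [[3.0, 0.0], [0.0, 1.5]]),
        (1.0, 1.0, np.array([[1.5, -0.5], [-0.5, 1.5]]) * 3.0 / 2 ** 1.5),
    ])
    def test_closed_form_incompressible(self, unit_substrate, kx, ky, expected):
        g = greens_tensor_fourier(kx, ky, unit_substrate)
        assert np.allclose(g, expected, atol=1e-12, rtol=0)

    def test_zero_wavevector_rejected(self, unit_substrate):
        with pytest.raises(InvalidFrequencyError):
            greens_tensor_fourier(0.0, 0.0, unit_substrate)

    def test_symmetric_positive_definite(self, substrate):
        rng = np.random.default_rng(7)
        for _ in range(50):
            kx, ky = rng.uniform(-3, 3, 2)
            if kx == 0 and ky == 0:
                continue
            g = greens_tensor_fourier(kx, ky, substrate)
            assert np.allclose(g, g.T)
            assert np.all(np.linalg.eigvalsh(g) > 0)

    def test_scales_inversely_with_stiffness(self):
        soft = greens_tensor_fourier(1.0, 0.5, SubstrateModel(young_modulus=1000.0))
        stiff = greens_tensor_fourier(1.0, 0.5, SubstrateModel(young_modulus=2000.0))
        assert np.allclose(soft, 2.0 * stiff)


class TestSubstrateModel:
    @pytest.mark.parametrize("kwargs", [
        {"young_modulus": 0.0}, {"young_modulus": -1.0},
        {"poisson_ratio": -0.1}, {"poisson_ratio": 0.6},
        {"pixel_size": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SubstrateModel(**kwargs)


def _patch_field(n=64, spacing=1.0, magnitude=1000.0, radius=10):
    yy, xx = np.mgrid[0:n, 0:n]
    inside = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= radius ** 2
    return TractionField(np.where(inside, magnitude, 0.0), np.zeros((n, n)),
                         grid_spacing=spacing)


def _dipole_field(n=64, spacing=8.0, magnitude=1000.0):
    """Zero-net-force two-patch field (mean-free by construction)."""
    pattern = TractionPattern(kind="inward_dipole", magnitude=magnitude,
                              radius=40.0, extent=120.0, edge_width=16.0)
    return make_traction_pattern(pattern, (n, n), spacing)


class TestForwardDisplacement:
    def test_zero_traction_gives_zero_displacement(self, substrate):
        t = TractionField(np.zeros((16, 16)), np.zeros((16, 16)), 8.0)
        u = forward_displacement(t, substrate)
        assert np.all(u.u_x == 0) and np.all(u.u_y == 0)

    def test_linearity(self, substrate):
        t = _dipole_field()
        u1 = forward_displacement(t, substrate)
        t3 = TractionField(3.0 * t.t_x, 3.0 * t.t_y, t.grid_spacing)
        u3 = forward_displacement(t3, substrate)
        assert np.allclose(u3.u_x, 3.0 * u1.u_x, atol=1e-12)
        assert np.allclose(u3.u_y, 3.0 * u1.u_y, atol=1e-12)

    def test_translation_equivariance_periodic(self, substrate):
        t = _dipole_field()
        u = forward_displacement(t, substrate, pad_factor=1)
        shift = (5, -3)
        ts = TractionField(np.roll(t.t_x, shift, (0, 1)),
                           np.roll(t.t_y, shift, (0, 1)), t.grid_spacing)
        us = forward_displacement(ts, substrate, pad_factor=1)
        assert np.allclose(us.u_x, np.roll(u.u_x, shift, (0, 1)), atol=1e-10)
        assert np.allclose(us.u_y, np.roll(u.u_y, shift, (0, 1)), atol=1e-10)

    def test_non_finite_traction_rejected(self, substrate):
        t = TractionField(np.zeros((8, 8)), np.zeros((8, 8)), 8.0)
        t.t_x[2, 2] = np.nan
        with pytest.raises(ValueError):
            forward_displacement(t, substrate)

    def test_matches_realspace_convolution_oracle(self):
        """FFT solution vs direct Boussinesq convolution, central quarter.

        The FFT route suppresses the k=0 mode, so both fields are
        mean-aligned before comparison; relative RMS is taken over the
        central 32×32 of a 64×64 grid.
        """
        substrate = SubstrateModel(pixel_size=1.0)
        t = _patch_field()
        u = forward_displacement(t, substrate)  # µm == px here
        ox, oy = boussinesq_convolution(t, substrate)
        c = np.s_[16:48, 16:48]
        dx = (u.u_x - u.u_x.mean()) - (ox - ox.mean())
        dy = (u.u_y - u.u_y.mean()) - (oy - oy.mean())
        num = np.sqrt(np.mean(dx[c] ** 2 + dy[c] ** 2))
        den = np.sqrt(np.mean((ox[c] - ox.mean()) ** 2 + (oy[c] - oy.mean()) ** 2))
        assert num / den < 0.02


class TestReconstructTraction:
    def test_exact_inverse_at_lambda_zero(self, substrate):
        """Forward→inverse on the same periodic grid is the exact
        per-wavevector inverse for a zero-net-force traction field."""
        t = _dipole_field()
        u = forward_displacement(t, substrate, pad_factor=1)
        rec = reconstruct_traction(u, substrate, RegularizationSetting(0.0),
                                   pad_factor=1)
        rel = np.sqrt(np.mean((rec.t_x - t.t_x) ** 2 + (rec.t_y - t.t_y) ** 2)
                      / np.mean(t.t_x ** 2 + t.t_y ** 2))
        assert rel < 1e-8

    def test_ridge_shrinkage_monotone(self, substrate):
        rng = np.random.default_rng(12)
        t = _dipole_field()
        u = forward_displacement(t, substrate)
        noisy = GriddedDisplacementField(
            u.u_x + rng.normal(0, 0.05, u.shape) * substrate.pixel_size,
            u.u_y + rng.normal(0, 0.05, u.shape) * substrate.pixel_size,
            u.grid_spacing, unit="um")
        norms = []
        for lam in (0.0, 1e-6, 2.47e-5, 1e-3):
            rec = reconstruct_traction(noisy, substrate, RegularizationSetting(lam))
            norms.append(np.sqrt((rec.t_x ** 2 + rec.t_y ** 2).sum()))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_noisy_peak_recovery(self, substrate):
        """Patch recovery at the default analysis resolution with 0.05 px
        white displacement noise stays within 20 % of the 1000 Pa truth."""
        rng = np.random.default_rng(0)
        t = _patch_field(n=64, spacing=13.0)
        u = forward_displacement(t, substrate)
        noisy = GriddedDisplacementField(
            u.u_x + rng.normal(0, 0.05, u.shape) * substrate.pixel_size,
            u.u_y + rng.normal(0, 0.05, u.shape) * substrate.pixel_size,
            u.grid_spacing, unit="um")
        rec = reconstruct_traction(noisy, substrate)
        assert abs(rec.magnitude.max() - 1000.0) / 1000.0 < 0.20

    def test_reconstruction_has_zero_spatial_mean(self, substrate):
        t = _patch_field(spacing=8.0)
        u = forward_displacement(t, substrate)
        rec = reconstruct_traction(u, substrate, pad_factor=1)
        assert abs(rec.t_x.mean()) < 1e-9 * np.abs(rec.t_x).max()
        assert abs(rec.t_y.mean()) < 1e-9 * np.abs(rec.t_x).max()

    def test_small_grid_rejected(self, substrate):
        u = GriddedDisplacementField(np.zeros((3, 3)), np.zeros((3, 3)), 8.0)
        with pytest.raises(ValueError):
            reconstruct_traction(u, substrate)

    def test_non_finite_displacement_rejected(self, substrate):
        u = GriddedDisplacementField(np.zeros((8, 8)), np.zeros((8, 8)), 8.0)
        u.u_x[0, 0] = np.inf
        with pytest.raises(ValueError):
            reconstruct_traction(u, substrate)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            RegularizationSetting(-1.0)
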