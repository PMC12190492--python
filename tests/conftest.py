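"""Shared fixtures and helpers for the test suite.

All image fixtures are rendered programmatically; nothing is read from
disk except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from tfmkit.substrate import SubstrateModel


@pytest.fixture
def substrate() -> SubstrateModel:
    """The default gel: E = 12 kPa, ν = 0.5, 0.16 µm/px."""
    return SubstrateModel()


@pytest.fixture
def unit_substrate() -> SubstrateModel:
    """E = 1, ν = 0.5, 1 µm/px — convenient for closed-form checks."""
    return SubstrateModel(young_modulus=1.0, poisson_ratio=0.5, pixel_size=1.0)


def render_spots(positions, shape, sigma=1.5, amplitude=1000.0,
                 background=100.0) -> np.ndarray:
    """Render Gaussian spots at subpixel positions (noise-free)."""
    img = np.full(shape, float(background))
    reach = int(np.ceil(5 * sigma))
    for x, y in np.atleast_2d(positions):
        r0 = max(int(np.floor(y)) - reach, 0)
        r1 = min(int(np.floor(y)) + reach + 1, shape[0])
        c0 = max(int(np.floor(x)) - reach, 0)
        c1 = min(int(np.floor(x)) + reach + 1, shape[1])
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma ** 2))
    return img


def scattered_positions(n, shape, margin, rng) -> np.ndarray:
    """Uniformly scattered (x, y) positions with a border margin."""
    h, w = shape
    return np.column_stack([rng.uniform(margin, w - margin, n),
                            rng.uniform(margin, h - margin, n)])
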