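"""Shared fixtures: small phantoms and wave fields reused across tests.

Unit tests run on a reduced grid (3 slices, 48 x 64 in-plane) so the full
physics chain stays fast; the acceptance tests use the full acquisition
grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from mreh import (
    PhantomSpec,
    extract_harmonic,
    invert_subject,
    make_phantom,
    synthesize_wavefield,
)

SMALL_GRID = (3, 48, 64)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=SMALL_GRID,
        archetype="homogeneous_diffuse",
        target_cv_percent=0.0,
        background_sws_mps=1.84,
        vessel_count=0,
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_wavefield(small_phantom, small_spec):
    return synthesize_wavefield(small_phantom, small_spec, n_sources=6)


@pytest.fixture(scope="session")
def small_harmonic(small_wavefield):
    return extract_harmonic(small_wavefield)


@pytest.fixture(scope="session")
def small_elastogram(small_wavefield):
    return invert_subject(small_wavefield)


def plane_wave_harmonic(
    shape=(3, 78, 100),
    voxel_size_mm=(3.0, 3.0, 5.0),
    c_mps=1.5,
    f_hz=50.0,
    angle_deg=30.0,
    phi_rad=0.0,
):
    """Analytic (possibly damped) plane wave U = exp((ik - alpha) d.x).

    The independent closed-form oracle used against the inversion: the
    phase gradient magnitude is exactly 2*pi*f/c and the log-amplitude
    slope is alpha = k * tan(phi / 2).
    """
    ns, nr, nc = shape
    y = np.arange(nr) * voxel_size_mm[0] * 1e-3
    x = np.arange(nc) * voxel_size_mm[1] * 1e-3
    X, Y = np.meshgrid(x, y)
    th = np.deg2rad(angle_deg)
    proj = np.cos(th) * X + np.sin(th) * Y
    k = 2.0 * np.pi * f_hz / c_mps
    alpha = k * np.tan(phi_rad / 2.0)
    field = np.exp((1j * k - alpha) * proj)
    return np.broadcast_to(field, shape).copy()
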