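"""Shared fixtures: small synthetic inputs generated at test time."""

import numpy as np
import pytest

from psmap.datatypes import DetectorConfig, SimGrid
from psmap.analytic import analytic_spiral_movie, default_orbit_spec
from psmap.phase import compute_phase
from psmap.surrogate import surrogate_spiral


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_grid():
    return SimGrid.from_cm(3, 3)  # 120 x 120 cells at 0.25 mm


@pytest.fixture(scope="session")
def orbit_fixture(small_grid):
    """Moving-core analytic spiral + ground truth (the accuracy fixture)."""
    spec = default_orbit_spec(small_grid)
    movie, truth = analytic_spiral_movie(spec, small_grid, 400.0)
    phase = compute_phase(movie, tau_ms=2.0)
    return {"spec": spec, "movie": movie, "truth": truth, "phase": phase}


@pytest.fixture(scope="session")
def surrogate_movie(small_grid):
    """500 ms spiral from the two-variable surrogate, 1 ms frames."""
    return surrogate_spiral(small_grid, 500.0, seed=7)


@pytest.fixture(scope="session")
def surrogate_phase(surrogate_movie):
    return compute_phase(surrogate_movie, tau_ms=30.0)


def smooth_phase_frame(rng, shape=(24, 24), n_waves=4):
    """Random smooth phase field (superposed plane waves through a complex
    field), guaranteed spatially resolved."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    z = np.zeros(shape, dtype=complex)
    for _ in range(n_waves):
        kx, ky = rng.uniform(-0.3, 0.3, 2)
        amp = rng.uniform(0.3, 1.0)
        phi = rng.uniform(0, 2 * np.pi)
        z += amp * np.exp(1j * (kx * xx + ky * yy + phi))
    return np.angle(z)


@pytest.fixture
def ig_config():
    return DetectorConfig(method="iyer_gray")


@pytest.fixture
def lc_config():
    return DetectorConfig(method="location_centric")
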