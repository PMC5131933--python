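"""Analytic spiral fixtures: exactly known cores and their detectability."""

import numpy as np
import pytest

from psmap.datatypes import AnalyticSpiralSpec, DetectorConfig, SimGrid
from psmap.analytic import analytic_spiral_movie, score_against_truth
from psmap.compare import hausdorff
from psmap.detect import detect_movie
from psmap.phase import compute_phase


@pytest.fixture(scope="module")
def static_fixture():
    grid = SimGrid.from_cm(3, 3)
    mid = (grid.height_cells - 1) * grid.dx_mm / 2
    spec = AnalyticSpiralSpec(omega_rad_per_ms=np.pi / 30, k_rad_per_mm=0.4,
                              core_row_mm=mid, core_col_mm=mid)
    movie, truth = analytic_spiral_movie(spec, grid, 240.0)
    phase = compute_phase(movie, tau_ms=15.0)  # omega * tau = pi/2
    return grid, movie, truth, phase


def test_static_core_localized_by_line_integral_every_frame(static_fixture):
    _, _, truth, phase = static_fixture
    ig = detect_movie(phase, DetectorConfig(method="iyer_gray"))
    score = score_against_truth(ig, truth, lag_frames=0, tol_px=1.0)
    assert score["n_frames_scored"] == phase.n_frames
    assert score["fraction_within"] == 1.0


def test_static_core_gives_no_temporal_discontinuity(static_fixture):
    """A rigidly rotating spiral with a stationary core advances every
    pixel's phase smoothly, so the temporal-jump criterion is silent — the
    stated blind spot of the local criterion for non-moving cores."""
    _, _, _, phase = static_fixture
    lc = detect_movie(phase, DetectorConfig(method="location_centric"))
    assert lc.is_empty


def test_ground_truth_bookkeeping(static_fixture):
    grid, movie, truth, _ = static_fixture
    assert len(truth) == movie.n_frames
    assert (truth.points["chirality"] == 1).all()
    mid_mm = (grid.height_cells - 1) * grid.dx_mm / 2
    expected = int(np.round(mid_mm / grid.dx_mm))
    assert (truth.points["row"] == expected).all()


def test_no_singularity_when_core_outside_grid():
    """k = 0 with the core outside the sheet: the phase field encloses no
    singularity, so both detectors must stay silent everywhere."""
    grid = SimGrid(40, 40)
    spec = AnalyticSpiralSpec(omega_rad_per_ms=np.pi / 30, k_rad_per_mm=0.0,
                              core_row_mm=-20.0, core_col_mm=-20.0)
    movie, truth = analytic_spiral_movie(spec, grid, 120.0)
    assert truth.is_empty
    phase = compute_phase(movie, tau_ms=15.0)
    assert detect_movie(phase, DetectorConfig(method="iyer_gray")).is_empty
    assert detect_movie(phase, DetectorConfig(method="location_centric")).is_empty


class TestOrbitingCore:
    def test_line_integral_tracks_orbit_every_frame(self, orbit_fixture):
        ig = detect_movie(orbit_fixture["phase"],
                          DetectorConfig(method="iyer_gray"))
        score = score_against_truth(ig, orbit_fixture["truth"], lag_frames=1)
        assert score["n_frames_scored"] >= 0.99 * orbit_fixture["phase"].n_frames
        assert score["fraction_within"] >= 0.99

    def test_temporal_jump_fires_on_core_crossings(self, orbit_fixture):
        """The moving core sweeps pixels between frames; wherever the
        criterion fires it pins the instantaneous core position."""
        lc = detect_movie(orbit_fixture["phase"],
                          DetectorConfig(method="location_centric"))
        assert lc.points["frame"].nunique() >= 30
        score = score_against_truth(lc, orbit_fixture["truth"], lag_frames=1)
        assert score["fraction_within"] >= 0.99

    def test_detected_trajectory_matches_true_orbit(self, orbit_fixture):
        """Pooled detected trajectory vs the true core path, within the
        discretisation bound: each detection lies within one pixel
        (sqrt(2)*dx) of its frame's core pixel, which itself lies within half
        a pixel diagonal (sqrt(2)/2*dx) of the continuous orbit."""
        ig = detect_movie(orbit_fixture["phase"],
                          DetectorConfig(method="iyer_gray"))
        dx = orbit_fixture["movie"].dx_mm
        rep = hausdorff(ig, orbit_fixture["truth"], resolution_mm=None)
        assert rep.H_mm <= 1.5 * np.sqrt(2) * dx + 1e-9


def test_core_path_validation():
    t = np.array([0.0, 25.0, 50.0, 75.0])
    spec = AnalyticSpiralSpec(omega_rad_per_ms=0.1, core_row_mm=5.0,
                              core_col_mm=7.0, orbit_radius_mm=2.0,
                              orbit_period_ms=100.0)
    y, x = spec.core_at(t)
    assert y[0] == pytest.approx(5.0) and x[0] == pytest.approx(9.0)
    assert y[1] == pytest.approx(7.0) and x[1] == pytest.approx(7.0, abs=1e-9)
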