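"""Hausdorff metric, method comparison, sweeps and benchmark harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmap.compare import (EmptyPointSetError, benchmark, compare_methods,
                           hausdorff, sweep)
from psmap.datatypes import DetectorConfig, SimGrid
from psmap.detect import detect_movie
from psmap.surrogate import surrogate_spiral


def brute_force_hausdorff(A, B):
    """The defining double loop: h(A,B) = max_a min_b |a - b|, symmetrised."""
    def directed(P, Q):
        worst = 0.0
        for p in P:
            best = min(float(np.hypot(p[0] - q[0], p[1] - q[1])) for q in Q)
            worst = max(worst, best)
        return worst
    return max(directed(A, B), directed(B, A))


points_strategy = st.lists(
    st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=1,
    max_size=25, unique=True).map(lambda pts: np.asarray(pts, dtype=float))


class TestHausdorff:
    def test_identical_sets_give_zero(self):
        A = np.array([[0.0, 0.0], [3.0, 1.0]])
        assert hausdorff(A, A.copy()).H_mm == 0.0

    def test_three_four_five(self):
        rep = hausdorff(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]),
                        resolution_mm=None)
        assert rep.h_AB_mm == rep.h_BA_mm == rep.H_mm == pytest.approx(5.0)

    def test_directed_distances_are_asymmetric(self):
        A = np.array([[0.0, 0.0], [10.0, 0.0]])
        B = np.array([[0.0, 0.0]])
        rep = hausdorff(A, B, resolution_mm=None)
        assert rep.h_AB_mm == pytest.approx(10.0)
        assert rep.h_BA_mm == 0.0
        assert rep.H_mm == pytest.approx(10.0)

    def test_empty_set_is_an_error_not_nan(self):
        with pytest.raises(EmptyPointSetError):
            hausdorff(np.zeros((0, 2)), np.array([[1.0, 1.0]]))

    def test_matches_bruteforce_double_loop_exactly(self, rng):
        """The tree-accelerated implementation equals the defining double
        loop on 100 random point sets."""
        for _ in range(100):
            A = rng.uniform(0, 40, (rng.integers(1, 30), 2))
            B = rng.uniform(0, 40, (rng.integers(1, 30), 2))
            rep = hausdorff(A, B, resolution_mm=None)
            assert rep.H_mm == pytest.approx(brute_force_hausdorff(A, B),
                                             abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(points_strategy, points_strategy, points_strategy)
    def test_metric_axioms(self, A, B, C):
        """Symmetry, identity of indiscernibles and the triangle inequality
        on integer-valued point sets (snapping cannot merge them)."""
        h = lambda P, Q: hausdorff(P, Q, resolution_mm=None).H_mm
        assert h(A, B) == pytest.approx(h(B, A))
        assert (h(A, B) == 0) == (
            set(map(tuple, A.tolist())) == set(map(tuple, B.tolist())))
        assert h(A, C) <= h(A, B) + h(B, C) + 1e-9

    def test_snapping_perturbation_bound(self, rng):
        """Measuring at 0.5 mm instead of 0.25 mm changes H by at most
        0.5*sqrt(2) mm (each point moves by at most half a display diagonal)."""
        for _ in range(50):
            A = rng.uniform(0, 20, (rng.integers(2, 20), 2))
            B = rng.uniform(0, 20, (rng.integers(2, 20), 2))
            h_fine = hausdorff(A, B, resolution_mm=0.25).H_mm
            h_disp = hausdorff(A, B, resolution_mm=0.5).H_mm
            assert abs(h_fine - h_disp) <= 0.5 * np.sqrt(2) + 1e-9


class TestCompareMethods:
    def test_detector_against_itself_is_zero(self, orbit_fixture):
        ig = detect_movie(orbit_fixture["phase"],
                          DetectorConfig(method="iyer_gray"))
        assert hausdorff(ig, ig).H_mm == 0.0

    def test_methods_agree_on_orbiting_analytic_core(self, orbit_fixture):
        """Both detectors pin the same moving core: pooled trajectories agree
        to about one display pixel."""
        rep = compare_methods(orbit_fixture["movie"], tau_ms=2.0)
        assert rep.H_mm <= 2 * np.sqrt(2) * 0.5 + 1e-9

    def test_surrogate_detections_colocalize(self, surrogate_movie):
        """On the drifting surrogate rotor every temporal-jump detection
        lands on the line-integral trajectory (directed distance under the
        few-mm fibrillation scale).  The slowly drifting two-variable core
        fires the temporal-jump criterion only at pixel crossings, so the
        symmetric distance is validated on the ionic-model runs, whose cores
        meander fast enough for dense temporal-jump coverage."""
        rep = compare_methods(surrogate_movie, tau_ms=30.0,
                              window_ms=(150.0, 500.0))
        assert rep.m >= 5            # non-vacuous
        assert rep.h_BA_mm < 5.0     # LC -> IG

    def test_empty_detection_is_reported(self):
        grid = SimGrid(24, 24)
        quiet = surrogate_spiral(grid, 100.0, require_spiral=False)
        quiet.frames[:] = -80.0 + 0.01 * np.sin(
            np.arange(quiet.n_frames))[:, None, None]
        with pytest.raises(EmptyPointSetError):
            compare_methods(quiet, tau_ms=10.0)


class TestSweep:
    def test_single_value_sweep_equals_compare_methods(self, surrogate_movie):
        win = (150.0, 500.0)
        sw = sweep(surrogate_movie, "tau_ms", [30.0], window_ms=win)
        rep = compare_methods(surrogate_movie, 30.0, window_ms=win)
        assert sw.values == [30.0]
        assert sw.reports[0].H_mm == pytest.approx(rep.H_mm)

    def test_invalid_values_skipped_with_warning(self, surrogate_movie, caplog):
        with caplog.at_level("WARNING"):
            sw = sweep(surrogate_movie, "tau_ms", [30.0, 15.5],
                       window_ms=(150.0, 500.0))
        assert sw.values == [30.0]
        assert "skipped" in caplog.text

    def test_sample_interval_sweep_decimates(self, surrogate_movie):
        sw = sweep(surrogate_movie, "sample_interval_ms", [1.0, 5.0],
                   tau_ms=30.0, window_ms=(150.0, 500.0))
        assert len(sw.reports) == 2
        assert all(r.H_mm >= 0 for r in sw.reports)

    def test_unknown_parameter_rejected(self, surrogate_movie):
        with pytest.raises(ValueError):
            sweep(surrogate_movie, "voltage", [1])


class TestBenchmark:
    def test_local_criterion_is_faster(self, surrogate_movie):
        """The neighbour-free criterion beats the line integral in wall
        clock on equal inputs (direction only; factors are hardware-bound)."""
        res = benchmark(surrogate_movie, repeats=3)
        assert res["ratio"] > 1.0

    def test_tiny_movie_guard(self):
        grid = SimGrid(16, 16)
        movie = surrogate_spiral(grid, 12.0, require_spiral=False)
        res = benchmark(movie, tau_ms=5.0, repeats=3)
        assert np.isfinite(res["ratio"])

    def test_repeat_floor(self, surrogate_movie):
        with pytest.raises(ValueError):
            benchmark(surrogate_movie, repeats=2)
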