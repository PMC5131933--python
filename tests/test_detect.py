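"""Detector unit and property tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from psmap.datatypes import DetectorConfig, PhaseMovie
from psmap.detect import (LOOP_OFFSETS, detect_location_centric, detect_movie,
                          winding_map, winding_number, wrapped_diff)

from conftest import smooth_phase_frame

PI = np.pi


def _phase_movie(frames, dx=0.25, dt=1.0):
    return PhaseMovie(np.asarray(frames, dtype=float), tau_ms=2.0,
                      frame_interval_ms=dt, dx_mm=dx)


# --------------------------------------------------------------------------- #
# wrapped difference
# --------------------------------------------------------------------------- #

class TestWrappedDiff:
    def test_wraps_across_branch_cut(self):
        assert wrapped_diff(0.9 * PI, -0.9 * PI) == pytest.approx(-0.2 * PI)

    def test_zero_for_equal(self):
        assert wrapped_diff(1.2, 1.2) == 0.0

    def test_range_boundary_maps_to_plus_pi(self):
        assert wrapped_diff(PI, 0.0) == pytest.approx(PI)
        assert wrapped_diff(0.0, PI) == pytest.approx(PI)  # -pi folds to +pi

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(-PI, PI), st.floats(-PI, PI))
    def test_matches_bruteforce_k_search(self, a, b):
        """wrapped_diff equals minimizing |a - b - 2*pi*k| over k in {-1,0,1}
        (ties resolved towards +pi, the half-open range convention)."""
        cands = sorted((a - b - 2 * PI * k for k in (-1, 0, 1)),
                       key=lambda d: (round(abs(d), 12), -d))
        assert wrapped_diff(a, b) == pytest.approx(cands[0], abs=1e-9)


# --------------------------------------------------------------------------- #
# winding number
# --------------------------------------------------------------------------- #

def _winding_oracle(frame, r, c):
    """Accumulate unwrapped phase along the same 8-neighbour loop."""
    seq = [frame[r + dr, c + dc] for dr, dc in LOOP_OFFSETS]
    seq.append(seq[0])
    total = np.unwrap(np.asarray(seq))
    return int(round((total[-1] - total[0]) / (2 * PI)))


class TestWindingNumber:
    def test_analytic_vortex_is_plus_one(self):
        yy, xx = np.mgrid[0:9, 0:9]
        frame = np.arctan2(yy - 4.2, xx - 3.8)
        assert winding_number(frame, 4, 4) == 1
        assert winding_number(frame, 1, 1) == 0

    def test_uniform_frame_is_zero_everywhere(self):
        w = winding_map(np.full((8, 8), 0.7))
        assert not w.any()

    def test_border_pixel_rejected(self):
        with pytest.raises(ValueError):
            winding_number(np.zeros((5, 5)), 0, 2)

    def test_matches_unwrap_oracle_on_random_smooth_frames(self, rng):
        """Exact agreement with the loop-unwrapping oracle on 50 random
        smooth frames, at every interior pixel."""
        for _ in range(50):
            frame = smooth_phase_frame(rng, shape=(16, 16))
            w = winding_map(frame, warn_high_order=False)
            for r in range(1, 15):
                for c in range(1, 15):
                    assert w[r, c] == _winding_oracle(frame, r, c)

    def test_quantized_on_surrogate_frames(self, surrogate_phase):
        """Winding is in {-1, 0, +1} on well-resolved simulated phase maps."""
        for n in range(0, surrogate_phase.n_frames, 50):
            w = winding_map(surrogate_phase.frames[n])
            assert set(np.unique(w)) <= {-1, 0, 1}

    def test_topological_charge_of_multi_vortex_field(self):
        """Total winding over a frame equals the sum of inserted vortex
        charges when cores are away from the boundary."""
        yy, xx = np.mgrid[0:40, 0:40]
        th = (np.arctan2(yy - 12.3, xx - 11.7)
              - np.arctan2(yy - 27.6, xx - 28.2))   # +1 and -1 vortices
        th = np.angle(np.exp(1j * th))
        w = winding_map(th)
        assert w.sum() == 0
        assert w.max() == 1 and w.min() == -1


# --------------------------------------------------------------------------- #
# Iyer-Gray detector
# --------------------------------------------------------------------------- #

class TestIyerGray:
    def test_planar_wave_yields_empty_set(self, ig_config):
        yy = np.linspace(-PI + 0.1, PI - 0.1, 30)
        frames = np.tile(yy[None, :, None], (3, 1, 30)).transpose(0, 2, 1)
        ps = detect_movie(_phase_movie(frames), ig_config)
        assert ps.is_empty

    def test_single_cluster_contains_core(self, ig_config):
        """An isolated vortex produces one small connected cluster of flags
        around the true core."""
        yy, xx = np.mgrid[0:30, 0:30]
        frame = np.arctan2(yy - 14.6, xx - 15.4)
        ps = detect_movie(_phase_movie(np.stack([frame, frame])), ig_config)
        for _, grp in ps.points.groupby("frame"):
            mask = np.zeros((30, 30), bool)
            mask[grp["row"], grp["col"]] = True
            _, n_clusters = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n_clusters == 1
            assert len(grp) <= 8
            assert (np.maximum(np.abs(grp["row"] - 14.6),
                               np.abs(grp["col"] - 15.4)) <= 1.5).any()
            assert (grp["chirality"] == 1).all()

    def test_chirality_filter(self):
        yy, xx = np.mgrid[0:20, 0:20]
        frame = -np.arctan2(yy - 9.5, xx - 9.5)   # negative winding
        movie = _phase_movie(np.stack([frame, frame]))
        only_pos = DetectorConfig(method="iyer_gray",
                                  include_negative_winding=False)
        assert detect_movie(movie, only_pos).is_empty
        only_neg = DetectorConfig(method="iyer_gray",
                                  include_positive_winding=False)
        ps = detect_movie(movie, only_neg)
        assert not ps.is_empty and (ps.points["chirality"] == -1).all()


# --------------------------------------------------------------------------- #
# location-centric detector
# --------------------------------------------------------------------------- #

class TestLocationCentric:
    def test_negative_jump_below_threshold_flagged(self, lc_config):
        frames = np.full((2, 4, 4), 0.1)
        frames[0, 2, 2] = 0.9 * PI
        frames[1, 2, 2] = -0.9 * PI     # raw jump -1.8*pi < -pi
        ps = detect_movie(_phase_movie(frames), lc_config)
        assert len(ps) == 1
        rec = ps.points.iloc[0]
        assert (rec["frame"], rec["row"], rec["col"]) == (1, 2, 2)
        assert rec["chirality"] == 0

    def test_positive_jump_not_flagged(self, lc_config):
        """A +1.8*pi jump is a depolarisation upstroke (or wrap), not a PS."""
        frames = np.full((2, 4, 4), 0.1)
        frames[0, 2, 2] = -0.9 * PI
        frames[1, 2, 2] = 0.9 * PI
        assert detect_movie(_phase_movie(frames), lc_config).is_empty

    def test_raw_difference_not_wrapped(self, lc_config):
        """Wrapping the temporal difference would empty the criterion: the
        same -1.8*pi jump wraps to +0.2*pi, above any valid threshold."""
        assert wrapped_diff(-0.9 * PI, 0.9 * PI) == pytest.approx(0.2 * PI)
        frames = np.full((2, 3, 3), 0.0)
        frames[0, 1, 1] = 0.9 * PI
        frames[1, 1, 1] = -0.9 * PI
        ps = detect_movie(_phase_movie(frames),
                          DetectorConfig(method="location_centric",
                                         M_threshold=-0.5 * PI))
        assert len(ps) == 1

    def test_stamp_frame_choice(self):
        frames = np.full((3, 3, 3), 0.0)
        frames[1, 1, 1] = 0.95 * PI
        frames[2, 1, 1] = -0.95 * PI
        early = DetectorConfig(method="location_centric",
                               stamp_at_later_frame=False)
        ps = detect_movie(_phase_movie(frames), early)
        assert list(ps.points["frame"]) == [1]

    def test_last_frame_has_no_successor(self, lc_config):
        movie = _phase_movie(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            detect_location_centric(movie, 2, lc_config)

    def test_locality(self, rng, lc_config):
        """Detections at a pixel depend only on that pixel's phase series:
        scrambling every other pixel leaves them unchanged."""
        frames = rng.uniform(-PI, PI, (20, 8, 8))
        p = (4, 5)
        ps1 = detect_movie(_phase_movie(frames), lc_config)
        scrambled = rng.uniform(-PI, PI, frames.shape)
        scrambled[:, p[0], p[1]] = frames[:, p[0], p[1]]
        ps2 = detect_movie(_phase_movie(scrambled), lc_config)
        at_p1 = ps1.points[(ps1.points.row == p[0]) & (ps1.points.col == p[1])]
        at_p2 = ps2.points[(ps2.points.row == p[0]) & (ps2.points.col == p[1])]
        assert list(at_p1["frame"]) == list(at_p2["frame"])

    def test_degenerate_pixels_excluded(self, lc_config):
        frames = np.zeros((3, 4, 4))
        frames[:, 1, 1] = [0.9 * PI, -0.9 * PI, 0.9 * PI]
        movie = _phase_movie(frames)
        movie.degenerate[1, 1] = True
        assert detect_movie(movie, lc_config).is_empty


# --------------------------------------------------------------------------- #
# whole-movie plumbing
# --------------------------------------------------------------------------- #

class TestDetectMovie:
    def test_empty_activity_movie(self, ig_config, lc_config):
        movie = _phase_movie(np.zeros((5, 10, 10)))
        assert detect_movie(movie, ig_config).is_empty
        assert detect_movie(movie, lc_config).is_empty

    def test_counts_and_sorting_invariants(self, orbit_fixture, ig_config):
        ps = detect_movie(orbit_fixture["phase"], ig_config)
        pts = ps.points
        assert not pts.duplicated(["frame", "row", "col"]).any()
        assert (pts["frame"].diff().fillna(0) >= 0).all()
        assert (pts["x_mm"] == pts["col"] * 0.25).all()
        assert (pts["y_mm"] == pts["row"] * 0.25).all()

    def test_spatial_decimation_consistency(self, orbit_fixture, ig_config):
        """Detecting on the 0.25 mm grid then mapping to 0.5 mm agrees with
        detecting on the spatially decimated movie, within 1 display pixel."""
        from psmap.compare import hausdorff
        from psmap.phase import compute_phase

        fine = detect_movie(orbit_fixture["phase"], ig_config)
        coarse_movie = orbit_fixture["movie"].decimate_space(2)
        coarse_phase = compute_phase(coarse_movie, tau_ms=2.0)
        coarse = detect_movie(coarse_phase, ig_config)
        rep = hausdorff(fine, coarse, resolution_mm=0.5)
        assert rep.H_mm <= 0.5 * np.sqrt(2) + 1e-9
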