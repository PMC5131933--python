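"""Delay-embedding phase construction: oracles, closed forms, invariants."""

import numpy as np
import pytest

from psmap.datatypes import VoltageMovie
from psmap.phase import compute_phase, compute_vmean

PI = np.pi


def _movie(frames, dt=1.0, t0=0.0):
    return VoltageMovie(np.asarray(frames, dtype=float), 0.25, dt, t0)


def _cos_movie(omega, n_frames=64, offset=-40.0, dt=1.0):
    t = np.arange(n_frames) * dt
    trace = offset + np.cos(omega * t)
    return _movie(np.tile(trace[:, None, None], (1, 2, 2)), dt)


class TestVmean:
    def test_constant_movie_identity(self):
        vm = compute_vmean(_movie(np.full((10, 3, 3), -80.0)))
        assert np.allclose(vm.values, -80.0)

    def test_zero_mean_sinusoid_leaves_offset(self):
        """cos over an integer number of periods averages to the offset."""
        movie = _cos_movie(2 * PI / 16, n_frames=64, offset=-37.5)
        vm = compute_vmean(movie)
        assert np.allclose(vm.values, -37.5, atol=1e-12)

    def test_matches_bruteforce_summation(self, rng):
        frames = rng.normal(-60, 20, (40, 6, 5)).astype(np.float32)
        movie = _movie(frames)
        vm = compute_vmean(movie)
        brute = np.zeros((6, 5))
        for f in np.asarray(frames, dtype=np.float64):
            brute += f
        brute /= 40
        assert np.allclose(vm.values, brute, atol=1e-9)

    def test_window_selection(self, rng):
        frames = rng.normal(size=(30, 3, 3))
        movie = _movie(frames)
        vm = compute_vmean(movie, (10.0, 20.0))
        assert np.allclose(vm.values, frames[10:20].mean(axis=0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_vmean(_movie(np.zeros((10, 3, 3))), (40.0, 50.0))


class TestComputePhase:
    def test_quarter_period_delay_closed_form(self):
        """With V - Vmean = cos(w t) and w*tau = pi/2 the embedded phase is
        -w*t wrapped into (-pi, pi]; at t = 0 it is exactly 0."""
        omega = PI / 30
        movie = _cos_movie(omega, n_frames=200, offset=-40.0)
        ph = compute_phase(movie, tau_ms=15.0,
                           vmean=np.full((2, 2), -40.0))
        t = np.arange(ph.n_frames)
        expected = np.angle(np.exp(-1j * omega * t))
        got = ph.frames[:, 0, 0]
        assert np.allclose(np.angle(np.exp(1j * (got - expected))), 0, atol=1e-9)
        assert got[0] == 0.0

    def test_argument_order_flips_rotation_sense(self):
        """Swapping the arctangent arguments reverses the temporal rotation
        of the phase (chirality flip): the per-frame increment changes sign."""
        from psmap.detect import wrapped_diff

        omega = PI / 30
        movie = _cos_movie(omega, n_frames=120, offset=-40.0)
        vm = np.full((2, 2), -40.0)
        fwd = compute_phase(movie, 15.0, vmean=vm).frames[:, 0, 0]
        rev = compute_phase(movie, 15.0, vmean=vm,
                            delayed_first=False).frames[:, 0, 0]
        assert np.allclose(wrapped_diff(fwd[1:], fwd[:-1]), -omega, atol=1e-9)
        assert np.allclose(wrapped_diff(rev[1:], rev[:-1]), omega, atol=1e-9)

    def test_matches_elementwise_oracle(self, surrogate_movie):
        """Phase of simulated pixels equals a per-sample recomputation from
        raw voltage and the mean map."""
        ph = compute_phase(surrogate_movie, tau_ms=30.0)
        vm = compute_vmean(surrogate_movie).values
        tf = ph.tau_frames
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(0, ph.n_frames))
            r = int(rng.integers(0, surrogate_movie.shape[0]))
            c = int(rng.integers(0, surrogate_movie.shape[1]))
            if ph.degenerate[r, c]:
                continue
            # recompute at the movie's storage precision (float32 frames)
            vm32 = np.float32(vm[r, c])
            v_now = float(surrogate_movie.frames[n, r, c] - vm32)
            v_del = float(surrogate_movie.frames[n + tf, r, c] - vm32)
            expect = np.arctan2(v_del, v_now)
            if expect == -PI:
                expect = PI
            assert ph.frames[n, r, c] == pytest.approx(expect, abs=1e-5)

    def test_range_strictly_half_open(self, rng):
        frames = rng.normal(size=(50, 8, 8))
        ph = compute_phase(_movie(frames), tau_ms=3.0)
        assert (ph.frames > -PI).all() and (ph.frames <= PI).all()

    def test_shift_covariance(self, rng):
        """Adding a constant to V and to Vmean leaves the phase unchanged."""
        frames = rng.normal(size=(40, 5, 5))
        vm = compute_vmean(_movie(frames))
        a = compute_phase(_movie(frames), 4.0, vm)
        b = compute_phase(_movie(frames + 17.3), 4.0, vm.values + 17.3)
        assert np.allclose(np.angle(np.exp(1j * (a.frames - b.frames))), 0,
                           atol=1e-9)

    def test_flat_pixel_is_degenerate_zero_phase(self):
        frames = np.tile(np.cos(np.arange(40.0))[:, None, None], (1, 3, 3))
        frames[:, 1, 1] = -55.0
        movie = _movie(frames)
        vm = compute_vmean(movie)
        ph = compute_phase(movie, 2.0, vm)
        assert ph.degenerate[1, 1]
        assert not ph.degenerate[0, 0]
        assert (ph.frames[:, 1, 1] == 0.0).all()

    def test_misaligned_tau_rejected_without_interpolation(self):
        movie = _movie(np.zeros((30, 3, 3)), dt=2.0)
        with pytest.raises(ValueError, match="not aligned"):
            compute_phase(movie, tau_ms=5.0)

    def test_tau_longer_than_movie_rejected(self):
        with pytest.raises(ValueError):
            compute_phase(_movie(np.zeros((10, 3, 3))), tau_ms=10.0)

    def test_output_length_is_input_minus_delay(self):
        movie = _cos_movie(PI / 20, n_frames=50)
        ph = compute_phase(movie, tau_ms=30.0)
        assert ph.n_frames == 50 - 30
        assert ph.tau_frames == 30

    def test_mismatched_vmean_grid_rejected(self):
        with pytest.raises(ValueError):
            compute_phase(_movie(np.zeros((10, 4, 4))), 2.0,
                          vmean=np.zeros((3, 3)))
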