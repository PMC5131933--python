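"""Agreement metrics, parameter sweeps and runtime benchmarks for PS detectors.

The similarity between the PS trajectories of two detectors is the symmetric
Hausdorff distance between the spatially pooled point sets:

    H(A, B) = max(h(A, B), h(B, A)),   h(A, B) = max_{p in A} min_{q in B} |p - q|

with Euclidean distances in mm.  Points are snapped to the display resolution
(0.5 mm by default — twice the compute grid spacing) before measuring, the
resolution at which results are reported.
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datatypes import (DetectorConfig, HausdorffReport, PhaseMovie,
                        PSPointSet, SimConfig, SweepResult, VoltageMovie,
                        scenario_like)
from .detect import detect_movie
from .phase import compute_phase, compute_vmean

__all__ = ["hausdorff", "hausdorff_xy", "compare_methods", "sweep",
           "benchmark", "EmptyPointSetError", "DISPLAY_RESOLUTION_MM",
           "THRESHOLD_SWEEP_PLATEAU", "THRESHOLD_SWEEP_FULL"]

log = logging.getLogger(__name__)

#: reporting resolution: results are mapped from the 0.25 mm compute grid to
#: the 0.5 mm display grid before distances are measured
DISPLAY_RESOLUTION_MM = 0.5

#: location-centric threshold sweep (units of pi); the plateau region is
#: M <= -0.6*pi, where agreement between the detectors is flat
THRESHOLD_SWEEP_FULL = tuple(np.round(np.arange(-1.8, -0.19, 0.2), 10) * np.pi)
THRESHOLD_SWEEP_PLATEAU = tuple(m for m in THRESHOLD_SWEEP_FULL
                                if m <= -0.6 * np.pi + 1e-12)


class EmptyPointSetError(ValueError):
    """Hausdorff distance is undefined against an empty point set."""


def _as_xy(points, resolution_mm: float | None) -> np.ndarray:
    if isinstance(points, PSPointSet):
        return points.pooled_xy_mm(resolution_mm)
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an N x 2 array of (x, y) positions in mm")
    if resolution_mm is not None:
        xy = np.unique(np.round(xy / resolution_mm) * resolution_mm, axis=0)
    return xy


def hausdorff_xy(A: np.ndarray, B: np.ndarray) -> tuple[float, float]:
    """Directed Hausdorff distances (h(A,B), h(B,A)) between point arrays."""
    tree_a, tree_b = cKDTree(A), cKDTree(B)
    h_ab = float(tree_b.query(A, k=1)[0].max())
    h_ba = float(tree_a.query(B, k=1)[0].max())
    return h_ab, h_ba


def hausdorff(A, B, resolution_mm: float | None = DISPLAY_RESOLUTION_MM,
              ) -> HausdorffReport:
    """Symmetric Hausdorff distance between two PS point sets.

    Accepts :class:`PSPointSet` objects (pooled over frames) or raw N x 2
    (x, y) arrays in mm.  Points are first snapped to ``resolution_mm``
    (pass ``None`` to measure on the compute grid).  Raises
    :class:`EmptyPointSetError` if either set is empty — the distance to an
    empty set is undefined, never NaN.
    """
    xy_a = _as_xy(A, resolution_mm)
    xy_b = _as_xy(B, resolution_mm)
    if len(xy_a) == 0 or len(xy_b) == 0:
        raise EmptyPointSetError(
            f"Hausdorff distance undefined: |A| = {len(xy_a)}, |B| = {len(xy_b)}")
    h_ab, h_ba = hausdorff_xy(xy_a, xy_b)
    return HausdorffReport(
        h_AB_mm=h_ab, h_BA_mm=h_ba, H_mm=max(h_ab, h_ba),
        resolution_mm=resolution_mm if resolution_mm is not None else 0.0,
        n=len(xy_a), m=len(xy_b),
        counts_A=(A.counts_per_frame() if isinstance(A, PSPointSet)
                  else pd.Series(dtype=np.int64)),
        counts_B=(B.counts_per_frame() if isinstance(B, PSPointSet)
                  else pd.Series(dtype=np.int64)))


def _phase_window(phase: PhaseMovie, window_ms) -> PhaseMovie:
    if window_ms is None:
        return phase
    t = phase.times_ms()
    sel = (t >= window_ms[0] - 1e-9) & (t < window_ms[1] - 1e-9)
    if sel.sum() < 2:
        raise ValueError("analysis window selects fewer than 2 phase frames")
    i0 = int(np.argmax(sel))
    i1 = i0 + int(sel.sum())
    # contiguous range: slice as a view, frames can be movie-sized
    return PhaseMovie(phase.frames[i0:i1], phase.tau_ms,
                      phase.frame_interval_ms, phase.dx_mm, float(t[i0]),
                      phase.degenerate, dict(phase.meta))


def detect_both(movie: VoltageMovie, tau_ms: float = 30.0,
                M: float = -np.pi, *, window_ms=None,
                vmean_window_ms=None, phase: PhaseMovie | None = None,
                ) -> tuple[PSPointSet, PSPointSet, PhaseMovie]:
    """Phase once, then both detectors over the (windowed) phase movie."""
    if phase is None:
        vmean = compute_vmean(movie, vmean_window_ms)
        phase = compute_phase(movie, tau_ms, vmean)
    phase = _phase_window(phase, window_ms)
    ig = detect_movie(phase, DetectorConfig(method="iyer_gray"))
    lc = detect_movie(phase, DetectorConfig(method="location_centric",
                                            M_threshold=M))
    return ig, lc, phase


def compare_methods(movie: VoltageMovie, tau_ms: float = 30.0,
                    M: float = -np.pi,
                    resolution_mm: float = DISPLAY_RESOLUTION_MM, *,
                    window_ms: tuple[float, float] | None = None,
                    vmean_window_ms: tuple[float, float] | None = None,
                    phase: PhaseMovie | None = None) -> HausdorffReport:
    """Hausdorff agreement between the two detectors on one movie.

    The phase is computed once and shared; detections are pooled across the
    analysis window into two spatial trajectories, snapped to the display
    resolution and compared.  An empty detection from either detector raises
    :class:`EmptyPointSetError` naming the offender.
    """
    ig, lc, phase = detect_both(movie, tau_ms, M, window_ms=window_ms,
                                vmean_window_ms=vmean_window_ms, phase=phase)
    if ig.is_empty or lc.is_empty:
        raise EmptyPointSetError(
            "no detections to compare: "
            f"iyer_gray n={len(ig)}, location_centric n={len(lc)}")
    rep = hausdorff(ig, lc, resolution_mm)
    rep.meta.update({"tau_ms": tau_ms, "M": M,
                     "window_ms": window_ms,
                     "n_phase_frames": phase.n_frames})
    return rep


def per_frame_hausdorff(movie: VoltageMovie, tau_ms: float = 30.0,
                        M: float = -np.pi,
                        resolution_mm: float = DISPLAY_RESOLUTION_MM, *,
                        window_ms=None) -> pd.Series:
    """Optional per-frame variant: H between the detections of each frame.

    Frames where either detector is silent are skipped (the location-centric
    criterion fires on crossing events, not continuously).
    """
    ig, lc, _ = detect_both(movie, tau_ms, M, window_ms=window_ms)
    out = {}
    ig_by = dict(tuple(ig.points.groupby("frame")))
    for f, g_lc in lc.points.groupby("frame"):
        if f not in ig_by:
            continue
        a = np.round(ig_by[f][["x_mm", "y_mm"]].to_numpy() / resolution_mm) * resolution_mm
        b = np.round(g_lc[["x_mm", "y_mm"]].to_numpy() / resolution_mm) * resolution_mm
        h_ab, h_ba = hausdorff_xy(np.unique(a, axis=0), np.unique(b, axis=0))
        out[f] = max(h_ab, h_ba)
    return pd.Series(out, name="H_mm")


_SWEEPABLE = ("tau_ms", "sample_interval_ms", "M", "scenario")


def sweep(movie_or_config, parameter: str, values, *, tau_ms: float = 30.0,
          M: float = -np.pi, resolution_mm: float = DISPLAY_RESOLUTION_MM,
          window_ms=None, run_simulation=None) -> SweepResult:
    """One :func:`compare_methods` report per swept parameter value.

    ``parameter`` is one of ``tau_ms``, ``sample_interval_ms``, ``M`` (all of
    which sweep over a fixed :class:`VoltageMovie`) or ``scenario`` (which
    re-simulates from a :class:`SimConfig`).  Sampling-interval sweeps expect
    the movie stored at its finest interval and decimate it.  Values that are
    invalid for the movie (e.g. a delay that is not a multiple of the
    sampling interval) are skipped with a warning.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {_SWEEPABLE}")
    if run_simulation is None:
        from .monodomain import run_monodomain as run_simulation

    kept, reports = [], []
    for val in values:
        try:
            if parameter == "tau_ms":
                rep = compare_methods(movie_or_config, float(val), M,
                                      resolution_mm, window_ms=window_ms)
            elif parameter == "M":
                rep = compare_methods(movie_or_config, tau_ms, float(val),
                                      resolution_mm, window_ms=window_ms)
            elif parameter == "sample_interval_ms":
                factor = float(val) / movie_or_config.frame_interval_ms
                if abs(factor - round(factor)) > 1e-9 or factor < 1:
                    raise ValueError(
                        f"interval {val} ms is not a multiple of the stored "
                        f"{movie_or_config.frame_interval_ms} ms cadence")
                dec = movie_or_config.decimate_time(int(round(factor)))
                rep = compare_methods(dec, tau_ms, M, resolution_mm,
                                      window_ms=window_ms)
            else:  # scenario
                if not isinstance(movie_or_config, SimConfig):
                    raise TypeError("scenario sweeps need a SimConfig")
                cfg = replace(movie_or_config, scenario=scenario_like(val))
                mov = run_simulation(cfg)
                rep = compare_methods(mov, tau_ms, M, resolution_mm,
                                      window_ms=window_ms)
        except (ValueError, TypeError) as err:
            log.warning("sweep value %r skipped: %s", val, err)
            continue
        kept.append(val)
        reports.append(rep)
    return SweepResult(parameter, kept, reports)


def benchmark(movie: VoltageMovie, tau_ms: float = 30.0, M: float = -np.pi,
              repeats: int = 5) -> dict:
    """Median wall-clock time of each detector on the same phase movie.

    The shared phase computation and any I/O are excluded; a warm-up pass is
    discarded (it also triggers lazy compilation).  Only the *ratio* is a
    meaningful quantity across machines — the location-centric criterion
    touches each pixel once per frame pair, the line integral touches each
    interior pixel and its 8 neighbours.
    """
    if repeats < 3:
        raise ValueError("need at least 3 repeats for a stable median")
    phase = compute_phase(movie, tau_ms, compute_vmean(movie))
    cfg_ig = DetectorConfig(method="iyer_gray")
    cfg_lc = DetectorConfig(method="location_centric", M_threshold=M)

    def _time(cfg):
        detect_movie(phase, cfg)  # warm-up, discarded
        samples = []
        for _ in range(repeats):
            t0 = time.perf_counter()
            detect_movie(phase, cfg)
            samples.append(time.perf_counter() - t0)
        return float(np.median(samples))

    t_ig = _time(cfg_ig)
    t_lc = _time(cfg_lc)
    return {"iyer_gray_s": t_ig, "location_centric_s": t_lc,
            "ratio": t_ig / max(t_lc, 1e-12), "repeats": repeats,
            "n_frames": phase.n_frames, "shape": phase.frames.shape[1:]}
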