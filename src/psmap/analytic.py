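"""Analytic spiral movies with an exactly known phase-singularity location.

The pseudo-voltage is

    V(r, c, t) = offset + amp * cos(atan2(y - y0(t), x - x0(t))
                                    + k * dist - omega * t)

an Archimedean spiral rotating rigidly about a core that is either static or
orbits a circle.  The spatial phase field has winding +1 about the core (in
the display convention, row axis downward), so the core pixel is the exact
ground truth against which both detectors are scored.

A physical caveat that the fixtures deliberately expose: a *static* smooth
spiral has no temporal phase discontinuity — every pixel's phase advances by
-omega*dt per frame — so the temporal-jump (location-centric) criterion is
silent on it; only a moving core produces the sub-pixel phase slips that
criterion keys on.  Real fibrillatory rotors always meander.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AnalyticSpiralSpec, PSPointSet, SimGrid, VoltageMovie

__all__ = ["analytic_spiral_movie", "default_orbit_spec"]


def analytic_spiral_movie(spec: AnalyticSpiralSpec, grid: SimGrid,
                          duration_ms: float, frame_interval_ms: float = 1.0,
                          ) -> tuple[VoltageMovie, PSPointSet]:
    """Render the spiral movie and its per-frame ground-truth core pixel.

    The returned point set lists, for every frame whose core lies inside the
    grid, the grid pixel nearest the true core (method tag ``ground_truth``,
    chirality +1 by construction).  A core outside the grid contributes no
    truth point — and no singularity is enclosed, so detectors must stay
    silent.
    """
    H, W = grid.shape
    dx = grid.dx_mm
    n_frames = int(round(duration_ms / frame_interval_ms))
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t = np.arange(n_frames) * frame_interval_ms
    y0, x0 = spec.core_at(t)

    yy = np.arange(H)[:, None] * dx
    xx = np.arange(W)[None, :] * dx
    frames = np.empty((n_frames, H, W), dtype=np.float32)
    for n in range(n_frames):
        dyy = yy - y0[n]
        dxx = xx - x0[n]
        ang = np.arctan2(dyy, dxx)
        dist = np.hypot(dyy, dxx)
        frames[n] = spec.offset_mV + spec.amplitude_mV * np.cos(
            ang + spec.k_rad_per_mm * dist - spec.omega_rad_per_ms * t[n])

    rows = np.round(y0 / dx).astype(np.int64)
    cols = np.round(x0 / dx).astype(np.int64)
    inside = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    truth = PSPointSet.from_arrays(
        "ground_truth", np.nonzero(inside)[0], rows[inside], cols[inside],
        np.ones(int(inside.sum()), dtype=np.int64),
        dx_mm=dx, frame_interval_ms=frame_interval_ms,
        config={"spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__}})
    movie = VoltageMovie(frames, dx, frame_interval_ms, 0.0,
                         {"solver": "analytic_spiral", "scenario": "analytic"})
    return movie, truth


def default_orbit_spec(grid: SimGrid, *, orbit_radius_mm: float = 3.0,
                       orbit_period_ms: float = 110.0,
                       omega_rad_per_ms: float = np.pi / 4.0,
                       k_rad_per_mm: float = 0.4) -> AnalyticSpiralSpec:
    """Orbiting-core spiral centred in the grid, the accuracy fixture.

    The defaults balance two opposing needs: the core must move (~0.7 pixel
    per frame here) so the temporal-jump detector sees phase slips, while the
    displacement over the embedding delay stays near one pixel so the
    embedded singularity — which lives between core(t) and core(t + tau) —
    remains within a pixel of the true core.  Use a short delay (about 2 ms)
    when embedding this fixture.
    """
    h_mm = (grid.height_cells - 1) * grid.dx_mm
    w_mm = (grid.width_cells - 1) * grid.dx_mm
    return AnalyticSpiralSpec(
        omega_rad_per_ms=omega_rad_per_ms, k_rad_per_mm=k_rad_per_mm,
        core_row_mm=h_mm / 2, core_col_mm=w_mm / 2,
        orbit_radius_mm=orbit_radius_mm, orbit_period_ms=orbit_period_ms)


def score_against_truth(ps: PSPointSet, truth: PSPointSet,
                        lag_frames: int = 0, tol_px: float = 1.0) -> dict:
    """Per-frame localization score of a detection set against ground truth.

    For every detection frame, the Chebyshev distance (pixels) from the
    nearest detected pixel to the true core at ``frame + lag_frames`` is
    computed (``lag_frames`` compensates the embedding's half-delay lag).
    Returns the fraction of detection frames within ``tol_px``, the number of
    frames scored, and the worst distance.
    """
    tr = truth.points.set_index("frame")
    ok = tot = 0
    worst = 0.0
    for f, grp in ps.points.groupby("frame"):
        ft = f + lag_frames
        if ft not in tr.index:
            continue
        tot += 1
        e = float(np.min(np.maximum(np.abs(grp["row"] - tr.loc[ft, "row"]),
                                    np.abs(grp["col"] - tr.loc[ft, "col"]))))
        ok += e <= tol_px
        worst = max(worst, e)
    return {"fraction_within": ok / tot if tot else np.nan,
            "n_frames_scored": tot, "worst_px": worst}
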