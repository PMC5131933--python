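"""Phase-singularity detectors.

Two criteria are implemented over the same phase movie:

* **Iyer-Gray line integral** — a pixel is a PS when the phase accumulated
  along the closed loop of its 8 neighbours is one full turn (winding number
  ±1).  Needs the neighbourhood, so it is restricted to interior pixels, and
  the winding sign gives the rotor chirality.
* **Location-centric temporal jump** — a pixel is a PS when its *raw*
  successive-frame phase difference theta_{n+1} - theta_n drops below a
  negative threshold M (default -pi).  The difference is deliberately not
  wrapped: wrapping would fold every jump back into (-pi, pi] and empty the
  criterion.  Positive jumps are depolarisation upstrokes (or 2*pi wraps) and
  are ignored.  No neighbour access is needed — each pixel's detections are a
  pure function of that pixel's own phase series — which is what makes the
  criterion cheap and trivially parallel.

The 8-neighbour loop is traversed counter-clockwise in the display convention
(row axis pointing down), starting at the east neighbour:
E, SE, S, SW, W, NW, N, NE.  With this traversal the field
``atan2(row - r0, col - c0)`` has winding +1 about its centre.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import DetectorConfig, PhaseMovie, PSPointSet

__all__ = ["wrapped_diff", "winding_number", "winding_map",
           "detect_iyer_gray", "detect_location_centric", "detect_movie",
           "reduce_to_centroids"]

TWO_PI = 2.0 * np.pi

#: 8-neighbour loop, counter-clockwise in display coordinates, from east
LOOP_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1),
                (0, -1), (-1, -1), (-1, 0), (-1, 1))


def wrapped_diff(a, b):
    """Phase difference a - b wrapped into (-pi, pi]."""
    r = np.remainder(np.asarray(a, dtype=float) - b, TWO_PI)
    return np.where(r > np.pi, r - TWO_PI, r)


def winding_number(phase_frame: np.ndarray, row: int, col: int) -> int:
    """Winding of the phase around one interior pixel (integer).

    Sum of wrapped differences between consecutive neighbours along the
    closed 8-neighbour loop, divided by 2*pi and rounded.
    """
    H, W = phase_frame.shape
    if not (1 <= row < H - 1 and 1 <= col < W - 1):
        raise ValueError("winding number needs all 8 neighbours: pixel must "
                         "be at least 1 cell from the border")
    loop = [phase_frame[row + dr, col + dc] for dr, dc in LOOP_OFFSETS]
    loop.append(loop[0])
    total = float(np.sum(wrapped_diff(loop[1:], loop[:-1])))
    return int(round(total / TWO_PI))


def winding_map(phase_frame: np.ndarray, *, warn_high_order: bool = True) -> np.ndarray:
    """Winding number at every interior pixel (border pixels are 0).

    Values outside {-1, 0, +1} indicate an under-resolved phase field and
    raise a warning.
    """
    th = np.asarray(phase_frame)
    H, W = th.shape
    total = np.zeros((H - 2, W - 2), dtype=float)
    cycle = LOOP_OFFSETS + (LOOP_OFFSETS[0],)
    for (r0, c0), (r1, c1) in zip(cycle[:-1], cycle[1:]):
        nxt = th[1 + r1:H - 1 + r1, 1 + c1:W - 1 + c1]
        cur = th[1 + r0:H - 1 + r0, 1 + c0:W - 1 + c0]
        total += wrapped_diff(nxt, cur)
    w = np.zeros((H, W), dtype=np.int8)
    w[1:-1, 1:-1] = np.rint(total / TWO_PI).astype(np.int8)
    if warn_high_order and np.abs(w).max() > 1:
        warnings.warn("winding numbers beyond +/-1 found: the phase field is "
                      "under-resolved on this grid", stacklevel=2)
    return w


def _chirality_mask(w: np.ndarray, config: DetectorConfig) -> np.ndarray:
    m = np.zeros(w.shape, dtype=bool)
    if config.include_positive_winding:
        m |= w == 1
    if config.include_negative_winding:
        m |= w == -1
    return m


def _apply_margin(mask: np.ndarray, margin: int) -> None:
    if margin > 0:
        mask[:margin, :] = False
        mask[-margin:, :] = False
        mask[:, :margin] = False
        mask[:, -margin:] = False


def detect_iyer_gray(phase: PhaseMovie, frame_index: int,
                     config: DetectorConfig | None = None) -> PSPointSet:
    """Line-integral detection on one phase frame.

    All interior pixels with |winding| = 1 are reported (clusters are kept,
    not merged); chirality is the winding sign.
    """
    config = config or DetectorConfig(method="iyer_gray")
    w = winding_map(phase.frames[frame_index])
    mask = _chirality_mask(w, config) & ~phase.degenerate
    _apply_margin(mask, max(1, config.border_margin))
    rows, cols = np.nonzero(mask)
    return PSPointSet.from_arrays(
        "iyer_gray", np.full(rows.size, frame_index), rows, cols,
        w[rows, cols].astype(np.int64), dx_mm=phase.dx_mm,
        frame_interval_ms=phase.frame_interval_ms, t0_ms=phase.t0_ms,
        config=_snapshot(config))


def detect_location_centric(phase: PhaseMovie, frame_index: int,
                            config: DetectorConfig | None = None) -> PSPointSet:
    """Temporal-jump detection between frames ``frame_index`` and the next.

    Flags pixels whose raw phase difference falls below M; the detection is
    stamped at the later frame by default (the frame where the new phase
    holds).  Chirality is unknown (0) — the criterion sees no neighbours.
    """
    config = config or DetectorConfig()
    if frame_index >= phase.n_frames - 1:
        raise ValueError("the last frame has no successor to difference with")
    d = phase.frames[frame_index + 1].astype(float) - phase.frames[frame_index]
    mask = (d < config.M_threshold) & ~phase.degenerate
    _apply_margin(mask, config.border_margin)
    rows, cols = np.nonzero(mask)
    stamp = frame_index + 1 if config.stamp_at_later_frame else frame_index
    return PSPointSet.from_arrays(
        "location_centric", np.full(rows.size, stamp), rows, cols,
        np.zeros(rows.size, dtype=np.int64), dx_mm=phase.dx_mm,
        frame_interval_ms=phase.frame_interval_ms, t0_ms=phase.t0_ms,
        config=_snapshot(config))


def detect_movie(phase: PhaseMovie, config: DetectorConfig,
                 *, chunk_frames: int = 256) -> PSPointSet:
    """Run the configured detector over every frame of a phase movie."""
    if config.method == "iyer_gray":
        frames, rows, cols, chis = [], [], [], []
        margin = max(1, config.border_margin)
        warned = False
        for n in range(phase.n_frames):
            w = winding_map(phase.frames[n], warn_high_order=not warned)
            warned = warned or np.abs(w).max() > 1
            mask = _chirality_mask(w, config) & ~phase.degenerate
            _apply_margin(mask, margin)
            r, c = np.nonzero(mask)
            frames.append(np.full(r.size, n))
            rows.append(r)
            cols.append(c)
            chis.append(w[r, c].astype(np.int64))
        frames, rows, cols, chis = (np.concatenate(x) if x else np.empty(0, int)
                                    for x in (frames, rows, cols, chis))
        method = "iyer_gray"
    elif config.method == "location_centric":
        frames, rows, cols = [], [], []
        th = phase.frames
        for start in range(0, phase.n_frames - 1, chunk_frames):
            stop = min(start + chunk_frames, phase.n_frames - 1)
            d = th[start + 1:stop + 1].astype(np.float32) - th[start:stop]
            mask = (d < config.M_threshold) & ~phase.degenerate
            if config.border_margin:
                mask[:, :config.border_margin, :] = False
                mask[:, -config.border_margin:, :] = False
                mask[:, :, :config.border_margin] = False
                mask[:, :, -config.border_margin:] = False
            f, r, c = np.nonzero(mask)
            frames.append(f + start + (1 if config.stamp_at_later_frame else 0))
            rows.append(r)
            cols.append(c)
        frames, rows, cols = (np.concatenate(x) if x else np.empty(0, int)
                              for x in (frames, rows, cols))
        chis = np.zeros(frames.size, dtype=np.int64)
        method = "location_centric"
    else:  # pragma: no cover - DetectorConfig already validates
        raise ValueError(f"unknown method {config.method!r}")

    return PSPointSet.from_arrays(
        method, frames, rows, cols, chis, dx_mm=phase.dx_mm,
        frame_interval_ms=phase.frame_interval_ms, t0_ms=phase.t0_ms,
        config=_snapshot(config))


def reduce_to_centroids(ps: PSPointSet) -> PSPointSet:
    """Optional post-hoc reducer: one centroid per connected cluster per frame.

    Both detectors report every flagged pixel by default (a rotor core often
    appears as a small cluster under the line-integral criterion); this
    collapses each 8-connected cluster to its centroid pixel.
    """
    from scipy import ndimage

    if ps.is_empty:
        return ps
    out_frames, out_rows, out_cols, out_chi = [], [], [], []
    for frame, grp in ps.points.groupby("frame"):
        h = int(grp["row"].max()) + 2
        w = int(grp["col"].max()) + 2
        mask = np.zeros((h, w), dtype=bool)
        mask[grp["row"], grp["col"]] = True
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        for lab in range(1, n + 1):
            rr, cc = np.nonzero(labels == lab)
            out_frames.append(frame)
            out_rows.append(int(round(rr.mean())))
            out_cols.append(int(round(cc.mean())))
            sel = grp[(grp["row"].isin(rr)) & (grp["col"].isin(cc))]
            out_chi.append(int(np.sign(sel["chirality"].sum())))
    return PSPointSet.from_arrays(
        ps.points["method"].iloc[0], np.array(out_frames), np.array(out_rows),
        np.array(out_cols), np.array(out_chi), dx_mm=ps.dx_mm,
        frame_interval_ms=ps.frame_interval_ms,
        config=dict(ps.config, centroid_reduced=True))


def _snapshot(config: DetectorConfig) -> dict:
    return {k: getattr(config, k) for k in config.__dataclass_fields__}
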