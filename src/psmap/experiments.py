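"""Desk-scale spiral-wave study protocol and agreement experiments.

The full-size experiment initiates fibrillation on a 15 x 15 cm sheet at
0.25 mm spacing with a cross-field S1-S2 protocol.  The desk-scale study
keeps a near-full-size 12 x 12 cm sheet — the unremodeled wavelength
(~10 cm) cannot re-enter on a much smaller domain — and coarsens the grid to
0.5 mm, which preserves the wavelength physics and the millimetre scale of
the agreement distances at a quarter of the compute cost.  Because the S1
crossing time differs from the full-size sheet, a fixed S2 coupling interval
lands either inside the absolute refractory period (nothing captures) or
after full recovery (no wavebreak), depending on the scenario's
action-potential duration; :func:`run_study` therefore times S2 adaptively,
firing it into the partially recovered repolarisation tail behind S1 —
the protocol's structural intent — for every remodeling scenario.  The run
is fully deterministic.
"""

from __future__ import annotations

import logging

import numpy as np

from .compare import (DISPLAY_RESOLUTION_MM, THRESHOLD_SWEEP_FULL,
                      compare_methods, detect_both, hausdorff)
from .courtemanche import CellParams, apply_scenario, build_lut, pack_params
from .datatypes import (DetectorConfig, SimGrid, VoltageMovie, scenario_like)
from .detect import detect_movie
from .monodomain import (DVDT_SUBSTEP_THRESHOLD, NumericalBlowupError,
                         _alloc_state, _tissue_kernel)
from .phase import compute_phase, compute_vmean

__all__ = ["run_study", "study_window", "fibrillation_window",
           "plateau_hausdorff", "study_compare", "STUDY_SCENARIOS",
           "ProtocolFailureError"]

log = logging.getLogger(__name__)

#: scenarios of the agreement study, in reporting order
STUDY_SCENARIOS = ("control", "0.3xICaL", "0.7xINa", "af", "0.7xD", "0.3xD")


class ProtocolFailureError(RuntimeError):
    """The S1 wave never produced the recovery pattern S2 needs."""


def run_study(scenario="control", *, size_cm: float = 12.0, dx_mm: float = 0.5,
              post_s2_ms: float = 1260.0, sample_interval_ms: float = 1.0,
              s2_recovery_fraction: float = 0.4, s2_max_wait_ms: float = 900.0,
              recovery_mV: float = -70.0, amplitude_pA_per_pF: float = 40.0,
              stim_duration_ms: float = 2.0, D_cm2_per_ms: float = 0.001,
              dt_max_ms: float = 0.1, dt_min_ms: float = 0.01,
              record_offset_ms: float = 0.0,
              base_params: CellParams | None = None) -> VoltageMovie:
    """Cross-field initiation with recovery-timed S2; records from S2 onward.

    S1 excites a left-edge stripe at t = 1 ms.  The solver then advances in
    short segments until the fraction of the sheet that the S1 wave has
    excited *and* that has repolarised below ``recovery_mV`` reaches
    ``s2_recovery_fraction`` (while part of the sheet is still refractory),
    at which point S2 excites the bottom half-plane and the run continues for
    ``post_s2_ms``.  Tracking the excited-and-recovered area makes the
    trigger work for long action potentials (whole sheet depolarised, then a
    recovery front sweeps it) and short ones (a travelling excited band)
    alike.  Frames are recorded every ``sample_interval_ms`` starting just
    after S2; the firing time is in ``meta['s2_time_ms']``.

    The defaults (12 x 12 cm sheet, 0.5 mm grid) are the smallest domain and
    coarsest grid on which the unremodeled sheet still sustains reentrant
    activity through the full 1-s analysis window; the display resolution at
    which PS positions are reported remains 0.5 mm.
    """
    scenario = scenario_like(scenario)
    grid = SimGrid.from_cm(size_cm, size_cm, dx_mm)
    H, W = grid.shape
    p = apply_scenario(base_params or CellParams(), scenario)
    n_sub = max(1, int(round(dt_max_ms / dt_min_ms)))
    lut = build_lut(p, dt_max_ms, dt_max_ms / n_sub)
    prm = pack_params(p)
    lap_coef = D_cm2_per_ms * scenario.D_scale * 100.0 * dt_max_ms / dx_mm ** 2
    if lap_coef > 0.25:
        raise ValueError("explicit diffusion unstable for these settings")

    s1 = (0, H, 0, max(3, W // 40))
    s2 = (H // 2, H, 0, W)
    st = _alloc_state(H, W)
    no_out = np.empty((0, H, W), dtype=np.float32)

    def advance(stims, n_steps, step0, steps_per_sample, first_step, out, frame0):
        t0s = np.array([s[0] for s in stims], dtype=float)
        t1s = np.array([s[1] for s in stims], dtype=float)
        regs = np.array([s[2] for s in stims], dtype=np.int64)
        amps = np.array([s[3] for s in stims], dtype=float)
        res = _tissue_kernel(
            st["V"], st["G"], st["fca"], st["u"], st["v"], st["Nai"],
            st["Ki"], st["Cai"], st["Caup"], st["Carel"], st["dvdt_prev"],
            lut, prm, dt_max_ms, n_sub, DVDT_SUBSTEP_THRESHOLD, 1.0, lap_coef,
            t0s, t1s, regs, amps, n_steps, steps_per_sample, first_step,
            out, step0, frame0)
        if res[0] != 0:
            raise NumericalBlowupError(res[1], res[2], res[3])
        return res[4]

    s1_stim = (1.0, 1.0 + stim_duration_ms, s1, amplitude_pA_per_pF)

    # stage 1: S1, then wait for the repolarisation tail behind the wave
    chunk = int(round(5.0 / dt_max_ms))
    max_steps = int(round(s2_max_wait_ms / dt_max_ms))
    step = 0
    t_s2 = None
    excited = np.zeros((H, W), dtype=bool)
    while step < max_steps:
        advance([s1_stim], chunk, step, 10 ** 9, 10 ** 9, no_out, 0)
        step += chunk
        excited |= st["V"] > -40.0
        recovered_behind = float((excited & (st["V"] < recovery_mV)).mean())
        still_refractory = float((excited & (st["V"] >= recovery_mV)).mean())
        if recovered_behind >= s2_recovery_fraction and still_refractory >= 0.05:
            t_s2 = step * dt_max_ms
            break
    if t_s2 is None:
        raise ProtocolFailureError(
            f"S2 condition (excited-and-recovered fraction >= "
            f"{s2_recovery_fraction} with refractory tissue present) not "
            f"reached within {s2_max_wait_ms} ms for scenario "
            f"{scenario.name!r}")
    log.info("scenario %s: S2 fired at %.1f ms", scenario.name, t_s2)

    # stage 2: S2 and the recorded fibrillation window; recording may start
    # later than S2 (record_offset_ms) to bound memory on fine-sampled runs
    steps_per_sample = int(round(sample_interval_ms / dt_max_ms))
    n_steps2 = int(round(post_s2_ms / dt_max_ms))
    offset_steps = int(round(record_offset_ms / dt_max_ms))
    k_first = (step + offset_steps) // steps_per_sample + 1
    first_step = k_first * steps_per_sample
    n_frames = (step + n_steps2) // steps_per_sample - k_first + 1
    out = np.empty((n_frames, H, W), dtype=np.float32)
    s2_stim = (t_s2, t_s2 + stim_duration_ms, s2, amplitude_pA_per_pF)
    written = advance([s1_stim, s2_stim], n_steps2, step, steps_per_sample,
                      first_step, out, 0)

    meta = {
        "solver": "crn_monodomain", "scenario": scenario.name,
        "protocol": "cross_field_auto_s2", "s1_time_ms": 1.0,
        "s2_time_ms": t_s2, "s2_recovery_fraction": s2_recovery_fraction,
        "s1_region": list(s1), "s2_region": list(s2),
        "stim_amplitude_pA_per_pF": amplitude_pA_per_pF,
        "stim_duration_ms": stim_duration_ms,
        "D_cm2_per_ms": D_cm2_per_ms * scenario.D_scale,
        "dt_min_ms": dt_max_ms / n_sub, "dt_max_ms": dt_max_ms,
    }
    return VoltageMovie(out[:written], dx_mm, sample_interval_ms,
                        k_first * sample_interval_ms, meta)


def study_window(movie: VoltageMovie, length_ms: float = 1000.0,
                 offset_ms: float = 200.0) -> tuple[float, float]:
    """The standard 1-s analysis window.

    It opens 200 ms (roughly one rotor period) after S2 so that it covers the
    *established* reentry rather than the initiation transient — the
    full-size experiment likewise analyses a window starting hundreds of
    milliseconds after S2.  The immediate post-S2 wavebreaks are brief and
    asymmetrically visible to the two detectors, so including them measures
    initiation debris rather than rotor-tracking agreement.
    """
    s2 = movie.meta.get("s2_time_ms")
    if s2 is None:
        raise ValueError("movie carries no s2_time_ms metadata")
    return (s2 + offset_ms, s2 + offset_ms + length_ms)


def study_compare(movie: VoltageMovie, tau_ms: float = 30.0,
                  M: float = -np.pi,
                  resolution_mm: float = DISPLAY_RESOLUTION_MM,
                  window_ms: tuple[float, float] | None = None):
    """:func:`~psmap.compare.compare_methods` under the study conventions:
    the 1-s post-S2 analysis window and the fibrillation-state Vmean."""
    if window_ms is None:
        window_ms = study_window(movie)
    return compare_methods(movie, tau_ms, M, resolution_mm,
                           window_ms=window_ms,
                           vmean_window_ms=fibrillation_window(movie))


def fibrillation_window(movie: VoltageMovie,
                        active_mV: float = -40.0) -> tuple[float, float]:
    """Time span over which the sheet carries activity (any pixel above
    ``active_mV``).

    The embedding origin Vmean is defined as the temporal average *during the
    fibrillation state*; on desk-scale runs where the rotor terminates before
    the record ends, averaging over the quiescent tail would drag Vmean to
    the resting potential and collapse the phase construction, so Vmean is
    taken over this span.
    """
    active = np.nonzero(movie.frames.max(axis=(1, 2)) > active_mV)[0]
    if active.size < 2:
        raise ValueError("no activity in the movie")
    t = movie.times_ms()
    return (float(t[active[0]]),
            float(t[active[-1]]) + movie.frame_interval_ms)


def plateau_hausdorff(movie: VoltageMovie, tau_ms: float = 30.0,
                      thresholds=THRESHOLD_SWEEP_FULL,
                      resolution_mm: float = DISPLAY_RESOLUTION_MM,
                      window_ms: tuple[float, float] | None = None,
                      plateau_tol_mm: float = 1.0) -> dict:
    """Hausdorff agreement across the location-centric threshold sweep.

    Computes the phase and the line-integral detection once, then sweeps the
    temporal-jump threshold M.  Tight (very negative) thresholds admit only
    the deep phase discontinuities at singularities and the agreement is flat
    — the *plateau*; loose thresholds start admitting conduction events
    (collisions, stimulus edges) far from any rotor and the distance
    diverges.  The plateau is identified operationally as the maximal run of
    consecutive thresholds, starting from the tightest with any detection,
    whose distance stays within ``plateau_tol_mm`` of the tight-end value;
    its mean and spread are the study's agreement statistic.
    """
    if window_ms is None:
        window_ms = study_window(movie)
    vmean = compute_vmean(movie, fibrillation_window(movie))
    phase = compute_phase(movie, tau_ms, vmean)
    from .compare import _phase_window
    phase = _phase_window(phase, window_ms)
    ig = detect_movie(phase, DetectorConfig(method="iyer_gray"))
    kept, H_mm, skipped = [], [], []
    for m in sorted(float(m) for m in thresholds):
        lc = detect_movie(phase, DetectorConfig(method="location_centric",
                                                M_threshold=m))
        if lc.is_empty:
            # the most extreme thresholds may see no jump on short records
            skipped.append(m)
            continue
        rep = hausdorff(ig, lc, resolution_mm)
        kept.append(m)
        H_mm.append(rep.H_mm)
    if not H_mm:
        raise ValueError("no threshold in the sweep produced any "
                         "location-centric detection")
    H_mm = np.asarray(H_mm)
    n_plateau = 1
    while (n_plateau < len(H_mm)
           and abs(H_mm[n_plateau] - H_mm[0]) <= plateau_tol_mm):
        n_plateau += 1
    plateau = H_mm[:n_plateau]
    return {"thresholds": np.asarray(kept), "skipped": np.asarray(skipped),
            "H_mm": H_mm,
            "plateau_thresholds": np.asarray(kept[:n_plateau]),
            "plateau_H_mm": plateau,
            "mean_H_mm": float(plateau.mean()),
            "std_H_mm": float(plateau.std()),
            "n_ig": len(ig), "window_ms": window_ms}
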