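"""Phase maps by time-delay embedding.

Each pixel's instantaneous phase is the angle in the plane spanned by the
voltage and its delayed copy, both centred on the pixel's temporal mean:

    theta(x, y, t) = atan2(V(t + tau) - Vmean, V(t) - Vmean)

with the delayed signal on the ordinate (the phase-plane construction of
optical-mapping work; the opposite ordering only flips chirality and is
available via ``delayed_first=False``).  The default delay is tau = 30 ms;
the standard sensitivity sweep covers 10-40 ms.
"""

from __future__ import annotations

import numpy as np

from .datatypes import MeanVoltageMap, PhaseMovie, VoltageMovie

__all__ = ["compute_vmean", "compute_phase", "TAU_SWEEP_MS"]

#: delay values of the standard tau-sensitivity sweep (ms)
TAU_SWEEP_MS = (10.0, 20.0, 30.0, 40.0)

#: amplitude below which a pixel is considered flat (degenerate), relative to
#: the movie's global voltage excursion
_DEGENERATE_REL_AMP = 1e-6


def compute_vmean(movie: VoltageMovie,
                  window_ms: tuple[float, float] | None = None) -> MeanVoltageMap:
    """Per-pixel arithmetic mean of V over a time window.

    The default window is the whole provided record (the fibrillation-state
    average).  For streaming use a shorter window — e.g. one action potential
    — or a fixed empirical map can be supplied to :func:`compute_phase`
    instead.
    """
    if window_ms is None:
        sub = movie
        window_ms = (float(movie.t0_ms),
                     float(movie.t0_ms + movie.n_frames * movie.frame_interval_ms))
    else:
        sub = movie.window(*window_ms)
    return MeanVoltageMap(sub.frames.mean(axis=0, dtype=np.float64),
                          (float(window_ms[0]), float(window_ms[1])))


def compute_phase(movie: VoltageMovie, tau_ms: float,
                  vmean: MeanVoltageMap | np.ndarray | None = None, *,
                  delayed_first: bool = True) -> PhaseMovie:
    """Delay-embedding phase movie; output spans the first T - tau frames.

    ``tau_ms`` must be an integer multiple of the frame interval (no temporal
    interpolation is performed).  Values lie strictly in (-pi, pi]; pixels
    whose trace never departs from Vmean get phase 0 and are flagged
    degenerate, to be excluded from singularity candidacy downstream.
    """
    ratio = tau_ms / movie.frame_interval_ms
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"tau = {tau_ms} ms is not aligned to the {movie.frame_interval_ms} "
            f"ms sampling grid; no interpolation is performed")
    tau_frames = int(round(ratio))
    if tau_frames < 1:
        raise ValueError("tau must be at least one frame interval")
    if movie.n_frames <= tau_frames:
        raise ValueError("movie shorter than the embedding delay")

    if vmean is None:
        vmean = compute_vmean(movie)
    vm = vmean.values if isinstance(vmean, MeanVoltageMap) else np.asarray(vmean)
    if vm.shape != movie.shape:
        raise ValueError("Vmean grid does not match the movie")

    # blockwise to avoid movie-sized temporaries on long fine-sampled records
    frames = movie.frames
    vm_cast = vm.astype(frames.dtype)
    n_out = frames.shape[0] - tau_frames
    theta = np.empty((n_out,) + movie.shape, dtype=frames.dtype)
    amp = np.zeros(movie.shape, dtype=frames.dtype)
    block = 512
    for lo in range(0, frames.shape[0], block):
        hi = min(lo + block, frames.shape[0])
        np.maximum(amp, np.abs(frames[lo:hi] - vm_cast).max(axis=0), out=amp)
    for lo in range(0, n_out, block):
        hi = min(lo + block, n_out)
        current = frames[lo:hi] - vm_cast
        delayed = frames[lo + tau_frames:hi + tau_frames] - vm_cast
        if delayed_first:
            np.arctan2(delayed, current, out=theta[lo:hi])
        else:
            np.arctan2(current, delayed, out=theta[lo:hi])
    # atan2 returns [-pi, pi]; fold the closed lower end onto +pi
    theta[theta == -np.pi] = np.pi

    scale = max(float(np.abs(frames).max()), 1.0)
    degenerate = amp < _DEGENERATE_REL_AMP * scale
    if degenerate.any():
        theta[:, degenerate] = 0.0

    return PhaseMovie(theta, float(tau_ms), movie.frame_interval_ms,
                      movie.dx_mm, movie.t0_ms, degenerate,
                      {"delayed_first": delayed_first,
                       "vmean_window_ms": (vmean.window_ms
                                           if isinstance(vmean, MeanVoltageMap)
                                           else None),
                       "source": movie.meta.get("solver", "unknown")})
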