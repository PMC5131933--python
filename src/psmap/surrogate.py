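"""Fast two-variable excitable-medium surrogate (Aliev-Panfilov kinetics).

A phenomenological reaction-diffusion model that sustains a spiral wave on a
few-centimetre sheet in seconds of compute, for fast tests and benchmarks.
The excitation variable u in [0, 1] is mapped affinely to a pseudo-voltage so
the result honours the same :class:`~psmap.datatypes.VoltageMovie` contract
as the ionic-model solver.  The model's dimensionless time unit is mapped to
12.5 ms so that frames land exactly on a 1 ms grid; default kinetics give a
rotor period of roughly 140 ms, in the range of atrial reentry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import SimGrid, VoltageMovie

__all__ = ["SurrogateParams", "surrogate_spiral", "SpiralFailureError"]


class SpiralFailureError(RuntimeError):
    """The excitation wave died instead of forming a sustained spiral."""


@dataclass(frozen=True)
class SurrogateParams:
    """Aliev-Panfilov kinetics plus the physical mapping of the surrogate.

    ``a`` is the excitation threshold (larger = less excitable; ~0.5 kills
    propagation), ``k`` the upstroke steepness, ``eps0/mu1/mu2`` shape the
    restitution of the recovery variable.  ``time_scale_ms`` converts model
    time units to ms; ``dx_space_units`` sets how much dimensionless space a
    pixel spans, controlling wavelength relative to the sheet.
    """

    a: float = 0.15
    b: float = 0.15
    k: float = 8.0
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    #: relative left-right gradient of the threshold parameter ``a`` across
    #: the sheet.  A mild gradient makes the rotor drift steadily (as an
    #: excitability/APD gradient does in tissue), so its core sweeps pixels —
    #: which temporal-jump detection needs — while the rotation stays stable.
    a_gradient: float = 0.3
    time_scale_ms: float = 12.5
    dt_time_units: float = 0.04
    dx_space_units: float = 0.5
    v_rest_mV: float = -80.0
    v_amplitude_mV: float = 100.0
    noise_amplitude: float = 0.0


def surrogate_spiral(grid: SimGrid, duration_ms: float,
                     params: SurrogateParams | None = None, *,
                     frame_interval_ms: float = 1.0, seed: int | None = None,
                     require_spiral: bool = True) -> VoltageMovie:
    """Simulate a broken-wavefront spiral and return the pseudo-voltage movie.

    The initial condition is a left-edge excitation stripe facing a refractory
    upper half-plane: the wave propagates through the recovered lower half and
    curls into the upper half as it recovers, pinning a rotor near mid-sheet.
    With ``require_spiral`` (default) the run fails loudly if the medium
    returns to rest instead of sustaining activity.  Identical parameters and
    seed give bit-identical movies.
    """
    p = params or SurrogateParams()
    H, W = grid.shape
    dt = p.dt_time_units
    dx2 = p.dx_space_units ** 2
    if dt / dx2 > 0.25:
        raise ValueError("unstable surrogate step: dt/dx^2 > 0.25")

    steps_per_frame = (frame_interval_ms / p.time_scale_ms) / dt
    if abs(steps_per_frame - round(steps_per_frame)) > 1e-9:
        raise ValueError("frame_interval_ms must be an integer number of "
                         "surrogate steps (default mapping: 0.5 ms per step)")
    steps_per_frame = int(round(steps_per_frame))
    n_frames = int(round(duration_ms / frame_interval_ms))

    u = np.zeros((H, W))
    r = np.zeros((H, W))
    a_map = p.a * (1.0 + p.a_gradient * (np.arange(W) / max(W - 1, 1) - 0.5))
    a_map = np.broadcast_to(a_map, (H, W))
    u[:, : max(2, W // 40)] = 1.0       # S1-like excitation stripe
    r[: H // 2, :] = 1.2                # refractory upper half -> wavebreak
    rng_meta: dict = {}
    if seed is not None:
        rng = np.random.default_rng(seed)
        u += p.noise_amplitude * rng.random((H, W))
        rng_meta["seed"] = int(seed)

    frames = np.empty((n_frames, H, W), dtype=np.float32)
    inv_dx2 = dt / dx2
    for fr in range(n_frames):
        for _ in range(steps_per_frame):
            padded = np.pad(u, 1, mode="edge")
            lap = (padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2]
                   + padded[1:-1, 2:] - 4.0 * u)
            eps = p.eps0 + p.mu1 * r / (p.mu2 + u)
            du = -p.k * u * (u - a_map) * (u - 1.0) - u * r
            dr = eps * (-r - p.k * u * (u - p.b - 1.0))
            u = u + dt * du + inv_dx2 * lap
            r = r + dt * dr
            np.clip(u, -0.1, 1.5, out=u)
        frames[fr] = p.v_rest_mV + p.v_amplitude_mV * u

    if require_spiral:
        tail = frames[-max(1, n_frames // 5):]
        if (tail - p.v_rest_mV).max() < 0.1 * p.v_amplitude_mV:
            raise SpiralFailureError(
                "excitation died out; no sustained spiral (reduce the "
                "threshold parameter a, or pass require_spiral=False)")

    meta = {"solver": "aliev_panfilov_surrogate", "scenario": "surrogate",
            "params": {k: getattr(p, k) for k in p.__dataclass_fields__},
            **rng_meta}
    return VoltageMovie(frames, grid.dx_mm, frame_interval_ms, 0.0, meta)
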