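"""Core data containers exchanged between the simulator, phase, and detector stages.

Conventions used throughout the package:

* movies are ``T x H x W`` arrays, row-major, origin at the top-left pixel;
* the physical coordinates of pixel ``(r, c)`` are ``y = r * dx_mm`` and
  ``x = c * dx_mm`` (millimetres);
* all phases are radians in the half-open interval ``(-pi, pi]``;
* time is milliseconds everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimGrid",
    "ScenarioConfig",
    "StimProtocol",
    "SimConfig",
    "VoltageMovie",
    "AnalyticSpiralSpec",
    "MeanVoltageMap",
    "PhaseMovie",
    "PSPointSet",
    "DetectorConfig",
    "HausdorffReport",
    "SweepResult",
    "CONTROL",
    "SCENARIOS",
]


# --------------------------------------------------------------------------- #
# simulation configuration
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SimGrid:
    """Uniform 2D tissue grid with no-flux (Neumann) boundaries."""

    height_cells: int
    width_cells: int
    dx_mm: float = 0.25

    def __post_init__(self) -> None:
        if self.height_cells < 3 or self.width_cells < 3:
            raise ValueError("tissue grids need at least 3x3 cells")
        if self.dx_mm <= 0:
            raise ValueError("dx_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_cells, self.width_cells)

    @property
    def size_cm(self) -> tuple[float, float]:
        return (self.height_cells * self.dx_mm / 10.0,
                self.width_cells * self.dx_mm / 10.0)

    @classmethod
    def from_cm(cls, height_cm: float, width_cm: float, dx_mm: float = 0.25) -> "SimGrid":
        return cls(int(round(height_cm * 10 / dx_mm)),
                   int(round(width_cm * 10 / dx_mm)), dx_mm)


#: names of the ionic/flux multipliers a scenario may scale
_MULTIPLIER_NAMES = ("g_Na", "g_to", "g_CaL", "g_Kur", "g_K1",
                     "k_NaCa_max", "sr_leak", "D_scale")


@dataclass(frozen=True)
class ScenarioConfig:
    """Named multipliers on ionic conductances/fluxes and on the diffusivity.

    The control scenario is all ones.  Electrical-remodeling scenarios scale
    individual currents (e.g. ``g_CaL=0.3`` reduces the L-type calcium
    conductance by 70 %, the classic stable-rotor condition).
    """

    name: str = "control"
    g_Na: float = 1.0
    g_to: float = 1.0
    g_CaL: float = 1.0
    g_Kur: float = 1.0
    g_K1: float = 1.0
    k_NaCa_max: float = 1.0
    sr_leak: float = 1.0
    D_scale: float = 1.0

    def __post_init__(self) -> None:
        for n in _MULTIPLIER_NAMES:
            if getattr(self, n) <= 0:
                raise ValueError(f"scenario multiplier {n} must be > 0")

    def multipliers(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in _MULTIPLIER_NAMES}

    @property
    def is_control(self) -> bool:
        return all(getattr(self, n) == 1.0 for n in _MULTIPLIER_NAMES)


CONTROL = ScenarioConfig()

#: the scenarios exercised in the comparison experiments.  "af" is the
#: seven-multiplier chronic-AF remodeling set: I_Na -10 %, I_to -70 %,
#: I_CaL -70 %, I_Kur -50 %, SR Ca leak +25 %, I_K1 +100 %, I_NaCa(max) +40 %.
SCENARIOS: dict[str, ScenarioConfig] = {
    "control": CONTROL,
    "0.3xICaL": ScenarioConfig(name="0.3xICaL", g_CaL=0.3),
    "0.7xINa": ScenarioConfig(name="0.7xINa", g_Na=0.7),
    "af": ScenarioConfig(name="af", g_Na=0.9, g_to=0.3, g_CaL=0.3,
                         g_Kur=0.5, sr_leak=1.25, g_K1=2.0, k_NaCa_max=1.4),
    "0.7xD": ScenarioConfig(name="0.7xD", D_scale=0.7),
    "0.3xD": ScenarioConfig(name="0.3xD", D_scale=0.3),
}


@dataclass(frozen=True)
class StimProtocol:
    """Cross-field S1-S2 stimulation.

    S1 is a vertical stripe on the left edge (launches a plane wave travelling
    left to right); S2 covers the bottom half of the sheet and fires one
    coupling interval after S1, catching the S1 repolarisation tail to break
    the wave and spawn a spiral.  Regions are (row0, row1, col0, col1) slices
    in cells; ``None`` selects the default geometry for the grid.
    """

    s1_time_ms: float = 0.0
    s2_coupling_interval_ms: float = 300.0
    s1_region: Optional[tuple[int, int, int, int]] = None
    s2_region: Optional[tuple[int, int, int, int]] = None
    amplitude_pA_per_pF: float = 40.0
    duration_ms: float = 2.0

    @property
    def s2_time_ms(self) -> float:
        return self.s1_time_ms + self.s2_coupling_interval_ms

    def resolve_regions(self, grid: SimGrid) -> tuple[tuple[int, int, int, int],
                                                      tuple[int, int, int, int]]:
        h, w = grid.shape
        s1 = self.s1_region if self.s1_region is not None else (0, h, 0, max(3, w // 40))
        s2 = self.s2_region if self.s2_region is not None else (h // 2, h, 0, w)
        for name, (r0, r1, c0, c1) in (("s1", s1), ("s2", s2)):
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"{name} region {r0, r1, c0, c1} outside grid {h}x{w}")
        return s1, s2


@dataclass(frozen=True)
class SimConfig:
    """Full monodomain run configuration.

    ``D_cm2_per_ms`` is the diffusion coefficient of the monodomain equation
    dV/dt = -(I_ion + I_stim)/Cm + D (Vxx + Vyy); the integration time step
    adapts per cell within [dt_min_ms, dt_max_ms].
    """

    grid: SimGrid
    duration_ms: float
    D_cm2_per_ms: float = 0.001
    Cm_uF_per_cm2: float = 1.0
    dt_min_ms: float = 0.01
    dt_max_ms: float = 0.1
    sample_interval_ms: float = 1.0
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    protocol: StimProtocol = field(default_factory=StimProtocol)
    record_start_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.dt_min_ms <= self.dt_max_ms <= self.sample_interval_ms + 1e-12):
            raise ValueError("need 0 < dt_min <= dt_max <= sample_interval")
        if self.D_cm2_per_ms <= 0 or self.Cm_uF_per_cm2 <= 0:
            raise ValueError("D and Cm must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")


# --------------------------------------------------------------------------- #
# movies
# --------------------------------------------------------------------------- #

@dataclass
class VoltageMovie:
    """T x H x W transmembrane-potential movie (mV) with physical metadata."""

    frames: np.ndarray
    dx_mm: float
    frame_interval_ms: float
    t0_ms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be T x H x W with T >= 2")
        if not np.isfinite(self.frames).all():
            raise ValueError("voltage movie contains non-finite values")
        if self.dx_mm <= 0 or self.frame_interval_ms <= 0:
            raise ValueError("dx_mm and frame_interval_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_frames) * self.frame_interval_ms

    def decimate_time(self, factor: int) -> "VoltageMovie":
        """Keep every ``factor``-th frame (e.g. 0.1 ms cadence -> 1 ms)."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("decimation factor must be a positive integer")
        return VoltageMovie(self.frames[::factor], self.dx_mm,
                            self.frame_interval_ms * factor, self.t0_ms,
                            dict(self.meta, decimated_by=int(factor)))

    def decimate_space(self, factor: int = 2) -> "VoltageMovie":
        """Spatial decimation, e.g. the 0.25 mm compute grid to 0.5 mm display."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("decimation factor must be a positive integer")
        return VoltageMovie(self.frames[:, ::factor, ::factor],
                            self.dx_mm * factor, self.frame_interval_ms,
                            self.t0_ms, dict(self.meta, space_decimated_by=int(factor)))

    def window(self, start_ms: float, end_ms: float) -> "VoltageMovie":
        """Sub-movie covering [start_ms, end_ms) in absolute time."""
        t = self.times_ms()
        sel = (t >= start_ms - 1e-9) & (t < end_ms - 1e-9)
        if sel.sum() < 2:
            raise ValueError("window selects fewer than 2 frames")
        i0 = int(np.argmax(sel))
        return VoltageMovie(self.frames[sel], self.dx_mm, self.frame_interval_ms,
                            float(t[i0]), dict(self.meta))


@dataclass(frozen=True)
class AnalyticSpiralSpec:
    """Archimedean pseudo-voltage spiral with an exactly known core path.

    V(r, c, t) = offset + amp * cos(atan2(y - y0(t), x - x0(t)) + k*dist - omega*t)
    where (x0, y0) follows ``core_path_mm`` and dist is the distance to the core.
    """

    omega_rad_per_ms: float
    k_rad_per_mm: float = 0.0
    core_row_mm: float = 0.0
    core_col_mm: float = 0.0
    orbit_radius_mm: float = 0.0
    orbit_period_ms: float = 100.0
    amplitude_mV: float = 50.0
    offset_mV: float = -30.0

    def core_at(self, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Core (row_mm, col_mm) at each time."""
        t = np.asarray(t_ms, dtype=float)
        if self.orbit_radius_mm == 0.0:
            return (np.full_like(t, self.core_row_mm),
                    np.full_like(t, self.core_col_mm))
        ang = 2 * np.pi * t / self.orbit_period_ms
        return (self.core_row_mm + self.orbit_radius_mm * np.sin(ang),
                self.core_col_mm + self.orbit_radius_mm * np.cos(ang))


# --------------------------------------------------------------------------- #
# phase
# --------------------------------------------------------------------------- #

@dataclass
class MeanVoltageMap:
    """Per-pixel temporal mean of V (the origin of the delay-embedding plane)."""

    values: np.ndarray
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or not np.isfinite(self.values).all():
            raise ValueError("Vmean must be a finite H x W map")


@dataclass
class PhaseMovie:
    """T' x H x W phase movie in (-pi, pi], from delay embedding with lag tau.

    ``degenerate`` marks pixels whose trace never leaves Vmean (zero amplitude);
    their phase is defined as 0 and they are excluded from PS candidacy.
    """

    frames: np.ndarray
    tau_ms: float
    frame_interval_ms: float
    dx_mm: float
    t0_ms: float = 0.0
    degenerate: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("phase frames must be T' x H x W")
        self.frames = f
        if self.degenerate is None:
            self.degenerate = np.zeros(f.shape[1:], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def tau_frames(self) -> int:
        return int(round(self.tau_ms / self.frame_interval_ms))

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_frames) * self.frame_interval_ms


# --------------------------------------------------------------------------- #
# detections
# --------------------------------------------------------------------------- #

_PS_COLUMNS = ["method", "frame", "t_ms", "row", "col", "x_mm", "y_mm", "chirality"]


@dataclass
class PSPointSet:
    """Detected phase singularities as a table of (frame, row, col) records.

    ``chirality`` is the winding sign for the line-integral detector and 0
    (unknown) for the location-centric detector.  Rows are unique in
    (frame, row, col) and sorted by frame then row-major position.
    """

    points: pd.DataFrame
    dx_mm: float
    frame_interval_ms: float
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.points, columns=_PS_COLUMNS)
        df = df.astype({"frame": np.int64, "row": np.int64, "col": np.int64,
                        "t_ms": float, "x_mm": float, "y_mm": float,
                        "chirality": np.int64, "method": str})
        if df.duplicated(["frame", "row", "col"]).any():
            raise ValueError("duplicate (frame, row, col) detections")
        self.points = df.sort_values(["frame", "row", "col"], kind="mergesort",
                                     ignore_index=True)

    @classmethod
    def from_arrays(cls, method: str, frame: np.ndarray, row: np.ndarray,
                    col: np.ndarray, chirality: np.ndarray, *, dx_mm: float,
                    frame_interval_ms: float, t0_ms: float = 0.0,
                    config: Optional[dict] = None) -> "PSPointSet":
        frame = np.asarray(frame, dtype=np.int64)
        df = pd.DataFrame({
            "method": method,
            "frame": frame,
            "t_ms": t0_ms + frame * frame_interval_ms,
            "row": np.asarray(row, dtype=np.int64),
            "col": np.asarray(col, dtype=np.int64),
            "x_mm": np.asarray(col, dtype=float) * dx_mm,
            "y_mm": np.asarray(row, dtype=float) * dx_mm,
            "chirality": np.asarray(chirality, dtype=np.int64),
        })
        return cls(df, dx_mm, frame_interval_ms, dict(config or {}))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0

    def xy_mm(self) -> np.ndarray:
        """N x 2 array of (x, y) positions in mm (all frames pooled)."""
        return self.points[["x_mm", "y_mm"]].to_numpy(dtype=float)

    def pooled_xy_mm(self, resolution_mm: Optional[float] = None) -> np.ndarray:
        """Unique spatial positions across frames, optionally snapped."""
        xy = self.xy_mm()
        if resolution_mm is not None:
            xy = np.round(xy / resolution_mm) * resolution_mm
        return np.unique(xy, axis=0) if len(xy) else xy.reshape(0, 2)

    def counts_per_frame(self) -> pd.Series:
        return self.points.groupby("frame").size()

    def frames_with_points(self) -> np.ndarray:
        return self.points["frame"].unique()


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration shared by the two PS detectors.

    ``M_threshold`` (radians, negative) is the temporal phase-jump threshold of
    the location-centric criterion: a pixel is a PS where the raw successive
    phase difference drops below M.  Only negative jumps count — depolarisation
    produces positive jumps.  ``stamp_at_later_frame`` controls whether a
    temporal-jump detection is stamped at frame n+1 (default) or n.
    """

    method: str = "location_centric"
    M_threshold: float = -np.pi
    include_positive_winding: bool = True
    include_negative_winding: bool = True
    border_margin: int = 0
    stamp_at_later_frame: bool = True
    delayed_first: bool = True  # delayed signal on the ordinate of the phase plane

    def __post_init__(self) -> None:
        if self.method not in ("iyer_gray", "location_centric"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.M_threshold >= 0:
            raise ValueError("M_threshold must be negative (only negative "
                             "phase jumps mark a singularity)")


# --------------------------------------------------------------------------- #
# comparison
# --------------------------------------------------------------------------- #

@dataclass
class HausdorffReport:
    """Directed and symmetric Hausdorff distances between two PS point sets."""

    h_AB_mm: float
    h_BA_mm: float
    H_mm: float
    resolution_mm: float
    n: int
    m: int
    counts_A: pd.Series = field(default_factory=lambda: pd.Series(dtype=np.int64))
    counts_B: pd.Series = field(default_factory=lambda: pd.Series(dtype=np.int64))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.H_mm >= 0 and abs(self.H_mm - max(self.h_AB_mm, self.h_BA_mm)) < 1e-9


@dataclass
class SweepResult:
    """One HausdorffReport per swept parameter value."""

    parameter: str
    values: list
    reports: list

    def __post_init__(self) -> None:
        if len(self.values) != len(self.reports):
            raise ValueError("one report per swept value required")

    def H_mm(self) -> np.ndarray:
        return np.array([r.H_mm for r in self.reports], dtype=float)


def scenario_like(obj) -> ScenarioConfig:
    """Coerce a scenario name or config into a ScenarioConfig."""
    if isinstance(obj, ScenarioConfig):
        return obj
    if isinstance(obj, str):
        if obj not in SCENARIOS:
            raise KeyError(f"unknown scenario {obj!r}; known: {sorted(SCENARIOS)}")
        return SCENARIOS[obj]
    raise TypeError(f"cannot interpret {obj!r} as a scenario")
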