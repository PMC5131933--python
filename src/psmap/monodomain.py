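"""2D monodomain reaction-diffusion solver for atrial tissue.

dV/dt = -(I_ion + I_stim)/Cm + D (d2V/dx2 + d2V/dy2)

Explicit 5-point Laplacian with no-flux boundaries (ghost-node mirroring),
operator-split from the ionic step.  Diffusion advances at the coarse step
``dt_max``; each cell's ionic ODEs substep down to ``dt_min`` whenever that
cell's reaction rate |dV/dt| exceeds a switching threshold (upstrokes), which
keeps the cost of quiescent and plateau tissue at the coarse step.  The
stepper is deterministic: identical configurations produce identical movies.

Voltage-dependent kinetics come from the lookup table built in
:mod:`psmap.courtemanche`; the inner loop is compiled with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import courtemanche as crn
from .courtemanche import (
    CellParams, apply_scenario, build_lut, initial_state, pack_params,
    LUT_VMIN, LUT_DV, COL_INF, COL_RL_COARSE, COL_RL_FINE,
    COL_FK1, COL_FKR, COL_GKUR, COL_FNAK, COL_ENACA1, COL_ENACA2,
    P_GNA, P_GK1, P_GTO, P_GKR, P_GKS, P_GCAL, P_GBCA, P_GBNA, P_GKUR,
    P_INAK, P_INACA, P_IPCA, P_IUP, P_KUP, P_CAUPMAX, P_KREL, P_TAUTR,
    P_SRLEAK, P_KMNAI, P_KMKO, P_NACADEN, P_KSAT, P_GAMMA,
)
from .datatypes import SimConfig, VoltageMovie

__all__ = ["run_monodomain", "pace_single_cell", "diffusion_only_run",
           "NumericalBlowupError", "ap_metrics", "DVDT_SUBSTEP_THRESHOLD"]

#: reaction-rate threshold (mV/ms) above which a cell's ionic ODEs substep at
#: the fine time step; upstrokes exceed it by two orders of magnitude while
#: plateau and resting dynamics stay below it.
DVDT_SUBSTEP_THRESHOLD = 1.0

_V_BLOWUP = 300.0


class NumericalBlowupError(RuntimeError):
    """Raised when the solver leaves the physiological voltage range."""

    def __init__(self, t_ms: float, row: int, col: int):
        self.t_ms, self.row, self.col = t_ms, row, col
        super().__init__(
            f"numerical blow-up (|V| > {_V_BLOWUP:g} mV or non-finite) at "
            f"t = {t_ms:.3f} ms, cell ({row}, {col})")


@njit(cache=True, fastmath=True)
def _tissue_kernel(V, G, fca, u, v, Nai, Ki, Cai, Caup, Carel, dvdt_prev,
                   lut, prm, dt_c, n_sub, dvdt_thresh, inv_cm, lap_coef,
                   stim_t0, stim_t1, stim_reg, stim_amp,
                   n_steps, steps_per_sample, first_sample_step, out,
                   step0, frame0):
    H, W = V.shape
    n_lut = lut.shape[0]
    inv_dv = 1.0 / LUT_DV
    dt_f = dt_c / n_sub
    rev_every = max(1, int(round(1.0 / dt_c)))

    # Rush-Larsen factors for the fixed-tau gates, both step sizes
    f_fca_c = np.exp(-dt_c / 2.0)
    f_fca_f = np.exp(-dt_f / 2.0)
    f_u_c = np.exp(-dt_c / 8.0)
    f_u_f = np.exp(-dt_f / 8.0)
    f_v_lo_c = np.exp(-dt_c / 1.91)
    f_v_lo_f = np.exp(-dt_f / 1.91)
    f_v_hi_c = np.exp(-dt_c / 4.0)
    f_v_hi_f = np.exp(-dt_f / 4.0)

    nao3 = 140.0 ** 3
    cmfvi = crn.CM_PF / (crn.FARADAY * crn.V_I)
    cm2fvi = 0.5 * cmfvi
    fn_c1 = 1e-12 * crn.V_REL
    fn_c2 = 5e-13 * crn.CM_PF / crn.FARADAY
    inv13 = 1.0 / 13.67e-16
    ko_term = crn.KO / (crn.KO + prm[P_KMKO])

    ENa = np.empty((H, W))
    EK = np.empty((H, W))
    ECa = np.empty((H, W))
    naki = np.empty((H, W))
    nai3 = np.empty((H, W))
    lap = np.empty((H, W))

    n_stim = stim_t0.shape[0]
    frame = frame0

    for local_step in range(n_steps):
        step = step0 + local_step
        t = step * dt_c

        if step % rev_every == 0:
            for i in range(H):
                for j in range(W):
                    ENa[i, j] = crn.RTF * np.log(140.0 / Nai[i, j])
                    EK[i, j] = crn.RTF * np.log(5.4 / Ki[i, j])
                    ECa[i, j] = 0.5 * crn.RTF * np.log(1.8 / Cai[i, j])
                    naki[i, j] = ko_term / (
                        1.0 + (prm[P_KMNAI] / Nai[i, j]) ** 1.5)
                    nai3[i, j] = Nai[i, j] ** 3

        # diffusion step (no-flux boundaries by mirroring)
        for i in range(H):
            im = i - 1 if i > 0 else min(1, H - 1)
            ip = i + 1 if i < H - 1 else max(H - 2, 0)
            for j in range(W):
                jm = j - 1 if j > 0 else min(1, W - 1)
                jp = j + 1 if j < W - 1 else max(W - 2, 0)
                lap[i, j] = (V[im, j] + V[ip, j] + V[i, jm] + V[i, jp]
                             - 4.0 * V[i, j])
        for i in range(H):
            for j in range(W):
                V[i, j] += lap_coef * lap[i, j]

        # ionic step, per-cell adaptive substepping
        for i in range(H):
            for j in range(W):
                fine = abs(dvdt_prev[i, j]) > dvdt_thresh
                if fine:
                    n = n_sub
                    dt = dt_f
                    rl0 = COL_RL_FINE
                    f_fca = f_fca_f
                    f_u = f_u_f
                    f_v_lo = f_v_lo_f
                    f_v_hi = f_v_hi_f
                else:
                    n = 1
                    dt = dt_c
                    rl0 = COL_RL_COARSE
                    f_fca = f_fca_c
                    f_u = f_u_c
                    f_v_lo = f_v_lo_c
                    f_v_hi = f_v_hi_c

                vl = V[i, j]
                ena = ENa[i, j]
                ek = EK[i, j]
                eca = ECa[i, j]
                nk = naki[i, j]
                n3 = nai3[i, j]
                cai = Cai[i, j]
                caup = Caup[i, j]
                carel = Carel[i, j]
                fc = fca[i, j]
                ul = u[i, j]
                vv = v[i, j]
                dvdt = 0.0

                gl = G[i, j]
                m = gl[0]
                hh = gl[1]
                jj = gl[2]
                oa = gl[3]
                oi = gl[4]
                ua = gl[5]
                ui = gl[6]
                xr = gl[7]
                xs = gl[8]
                dd = gl[9]
                ff = gl[10]
                w = gl[11]

                for s in range(n):
                    ts = t + s * dt
                    # LUT lookup with linear interpolation
                    x = (vl - LUT_VMIN) * inv_dv
                    if x < 0.0:
                        x = 0.0
                    elif x > n_lut - 2.0:
                        x = n_lut - 2.0
                    i0 = int(x)
                    fr = x - i0
                    l0 = lut[i0]
                    l1 = lut[i0 + 1]

                    # gates (Rush-Larsen, exact for frozen V)
                    inf = l0[0] + fr * (l1[0] - l0[0])
                    m = inf + (m - inf) * (l0[rl0] + fr * (l1[rl0] - l0[rl0]))
                    inf = l0[1] + fr * (l1[1] - l0[1])
                    hh = inf + (hh - inf) * (l0[rl0 + 1] + fr * (l1[rl0 + 1] - l0[rl0 + 1]))
                    inf = l0[2] + fr * (l1[2] - l0[2])
                    jj = inf + (jj - inf) * (l0[rl0 + 2] + fr * (l1[rl0 + 2] - l0[rl0 + 2]))
                    inf = l0[3] + fr * (l1[3] - l0[3])
                    oa = inf + (oa - inf) * (l0[rl0 + 3] + fr * (l1[rl0 + 3] - l0[rl0 + 3]))
                    inf = l0[4] + fr * (l1[4] - l0[4])
                    oi = inf + (oi - inf) * (l0[rl0 + 4] + fr * (l1[rl0 + 4] - l0[rl0 + 4]))
                    inf = l0[5] + fr * (l1[5] - l0[5])
                    ua = inf + (ua - inf) * (l0[rl0 + 5] + fr * (l1[rl0 + 5] - l0[rl0 + 5]))
                    inf = l0[6] + fr * (l1[6] - l0[6])
                    ui = inf + (ui - inf) * (l0[rl0 + 6] + fr * (l1[rl0 + 6] - l0[rl0 + 6]))
                    inf = l0[7] + fr * (l1[7] - l0[7])
                    xr = inf + (xr - inf) * (l0[rl0 + 7] + fr * (l1[rl0 + 7] - l0[rl0 + 7]))
                    inf = l0[8] + fr * (l1[8] - l0[8])
                    xs = inf + (xs - inf) * (l0[rl0 + 8] + fr * (l1[rl0 + 8] - l0[rl0 + 8]))
                    inf = l0[9] + fr * (l1[9] - l0[9])
                    dd = inf + (dd - inf) * (l0[rl0 + 9] + fr * (l1[rl0 + 9] - l0[rl0 + 9]))
                    inf = l0[10] + fr * (l1[10] - l0[10])
                    ff = inf + (ff - inf) * (l0[rl0 + 10] + fr * (l1[rl0 + 10] - l0[rl0 + 10]))
                    inf = l0[11] + fr * (l1[11] - l0[11])
                    w = inf + (w - inf) * (l0[rl0 + 11] + fr * (l1[rl0 + 11] - l0[rl0 + 11]))

                    fk1 = l0[COL_FK1] + fr * (l1[COL_FK1] - l0[COL_FK1])
                    fkr = l0[COL_FKR] + fr * (l1[COL_FKR] - l0[COL_FKR])
                    gkur = l0[COL_GKUR] + fr * (l1[COL_GKUR] - l0[COL_GKUR])
                    fnak = l0[COL_FNAK] + fr * (l1[COL_FNAK] - l0[COL_FNAK])
                    e1 = l0[COL_ENACA1] + fr * (l1[COL_ENACA1] - l0[COL_ENACA1])
                    e2 = l0[COL_ENACA2] + fr * (l1[COL_ENACA2] - l0[COL_ENACA2])

                    i_na = prm[P_GNA] * m * m * m * hh * jj * (vl - ena)
                    i_k1 = prm[P_GK1] * fk1 * (vl - ek)
                    i_to = prm[P_GTO] * oa * oa * oa * oi * (vl - ek)
                    i_kur = prm[P_GKUR] * gkur * ua * ua * ua * ui * (vl - ek)
                    i_kr = prm[P_GKR] * fkr * xr * (vl - ek)
                    i_ks = prm[P_GKS] * xs * xs * (vl - ek)
                    i_cal = prm[P_GCAL] * dd * ff * fc * (vl - 65.0)
                    i_nak = prm[P_INAK] * fnak * nk
                    i_naca = prm[P_INACA] * (e1 * n3 * 1.8 - e2 * nao3 * cai) / (
                        prm[P_NACADEN] * (1.0 + prm[P_KSAT] * e2))
                    i_bna = prm[P_GBNA] * (vl - ena)
                    i_bca = prm[P_GBCA] * (vl - eca)
                    i_pca = prm[P_IPCA] * cai / (0.0005 + cai)

                    # SR fluxes and Ca-release gating
                    i_rel = prm[P_KREL] * ul * ul * vv * w * (carel - cai)
                    i_tr = (caup - carel) / prm[P_TAUTR]
                    i_up = prm[P_IUP] / (1.0 + prm[P_KUP] / cai)
                    i_leak = prm[P_SRLEAK] * prm[P_IUP] * caup / prm[P_CAUPMAX]

                    fn = fn_c1 * i_rel - fn_c2 * (0.5 * i_cal - 0.2 * i_naca)
                    z = (fn - 3.4175e-13) * inv13
                    if z > 30.0:
                        u_inf = 1.0
                    elif z < -30.0:
                        u_inf = 0.0
                    else:
                        u_inf = 1.0 / (1.0 + np.exp(-z))
                    zv = (fn - 6.835e-14) * inv13
                    if zv > 30.0:
                        v_inf = 0.0
                    elif zv < -30.0:
                        v_inf = 1.0
                    else:
                        v_inf = 1.0 - 1.0 / (1.0 + np.exp(-zv))
                    if u_inf <= 0.0:
                        f_v = f_v_lo
                    elif u_inf >= 1.0:
                        f_v = f_v_hi
                    else:
                        f_v = np.exp(-dt / (1.91 + 2.09 * u_inf))

                    ul = u_inf + (ul - u_inf) * f_u
                    vv = v_inf + (vv - v_inf) * f_v
                    fca_inf = 1.0 / (1.0 + cai / 0.00035)
                    fc = fca_inf + (fc - fca_inf) * f_fca

                    # concentrations (forward Euler)
                    Nai[i, j] += dt * cmfvi * (-3.0 * i_nak - 3.0 * i_naca
                                               - i_bna - i_na)
                    Ki[i, j] += dt * cmfvi * (2.0 * i_nak - i_k1 - i_to
                                              - i_kur - i_kr - i_ks)
                    b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * cm2fvi
                          + (crn.V_UP * (i_leak - i_up)
                             + i_rel * crn.V_REL) / crn.V_I)
                    kt = cai + 0.0005
                    kc = cai + 0.00238
                    b2 = 1.0 + 0.07 * 0.0005 / (kt * kt) \
                        + 0.05 * 0.00238 / (kc * kc)
                    cai += dt * b1 / b2
                    caup += dt * (i_up - i_leak
                                  - i_tr * crn.V_REL / crn.V_UP)
                    kq = carel + 0.8
                    carel += dt * (i_tr - i_rel) / (1.0 + 8.0 / (kq * kq))

                    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
                             + i_nak + i_naca + i_bna + i_bca + i_pca)
                    stim = 0.0
                    for k in range(n_stim):
                        if stim_t0[k] <= ts < stim_t1[k]:
                            if (stim_reg[k, 0] <= i < stim_reg[k, 1]
                                    and stim_reg[k, 2] <= j < stim_reg[k, 3]):
                                stim += stim_amp[k]
                    dvdt = (-i_ion + stim) * inv_cm
                    vl += dt * dvdt

                gl[0] = m
                gl[1] = hh
                gl[2] = jj
                gl[3] = oa
                gl[4] = oi
                gl[5] = ua
                gl[6] = ui
                gl[7] = xr
                gl[8] = xs
                gl[9] = dd
                gl[10] = ff
                gl[11] = w
                V[i, j] = vl
                Cai[i, j] = cai
                Caup[i, j] = caup
                Carel[i, j] = carel
                fca[i, j] = fc
                u[i, j] = ul
                v[i, j] = vv
                dvdt_prev[i, j] = dvdt

                if not (-_V_BLOWUP < vl < _V_BLOWUP):
                    return 1, t + dt_c, i, j, frame

        if (step + 1) % steps_per_sample == 0 and step + 1 >= first_sample_step:
            if frame < out.shape[0]:
                for i in range(H):
                    for j in range(W):
                        out[frame, i, j] = V[i, j]
                frame += 1

    return 0, 0.0, -1, -1, frame


def _alloc_state(H: int, W: int) -> dict:
    y0 = initial_state()
    st = {
        "V": np.full((H, W), y0[0]),
        "G": np.empty((H, W, 12)),
        "fca": np.full((H, W), y0[12]),
        "u": np.full((H, W), y0[13]),
        "v": np.full((H, W), y0[14]),
        "Nai": np.full((H, W), y0[16]),
        "Ki": np.full((H, W), y0[17]),
        "Cai": np.full((H, W), y0[18]),
        "Caup": np.full((H, W), y0[19]),
        "Carel": np.full((H, W), y0[20]),
        "dvdt_prev": np.zeros((H, W)),
    }
    gate_idx = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15]  # m..f then w
    for g, k in enumerate(gate_idx):
        st["G"][:, :, g] = y0[k]
    return st


def _sampling_plan(config: SimConfig) -> tuple[int, int, int, float]:
    dt_c = config.dt_max_ms
    ratio = config.sample_interval_ms / dt_c
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("sample_interval_ms must be an integer multiple of "
                         "dt_max_ms for exact frame timing")
    steps_per_sample = int(round(ratio))
    n_steps = int(round(config.duration_ms / dt_c))
    t_first = max(config.record_start_ms, config.sample_interval_ms)
    k_first = int(np.ceil(t_first / config.sample_interval_ms - 1e-9))
    first_sample_step = k_first * steps_per_sample
    n_frames = n_steps // steps_per_sample - k_first + 1
    t0 = k_first * config.sample_interval_ms
    if n_frames < 2:
        raise ValueError("configuration records fewer than 2 frames")
    return steps_per_sample, first_sample_step, n_frames, t0


def run_monodomain(config: SimConfig,
                   base_params: CellParams | None = None) -> VoltageMovie:
    """Integrate the monodomain equation and return the sampled voltage movie.

    The cross-field S1-S2 protocol in ``config.protocol`` provides the two
    stimuli; ``config.scenario`` scales ionic conductances and the diffusion
    coefficient.  Raises :class:`NumericalBlowupError` with the failing time
    and cell if the integration leaves the physiological range.
    """
    grid = config.grid
    H, W = grid.shape
    p = apply_scenario(base_params or CellParams(), config.scenario)
    n_sub = max(1, int(round(config.dt_max_ms / config.dt_min_ms)))
    lut = build_lut(p, config.dt_max_ms, config.dt_max_ms / n_sub)
    prm = pack_params(p)

    s1, s2 = config.protocol.resolve_regions(grid)
    pr = config.protocol
    stim_t0 = np.array([pr.s1_time_ms, pr.s2_time_ms], dtype=float)
    stim_t1 = stim_t0 + pr.duration_ms
    stim_reg = np.array([s1, s2], dtype=np.int64)
    stim_amp = np.full(2, pr.amplitude_pA_per_pF, dtype=float)

    D_mm2 = config.D_cm2_per_ms * config.scenario.D_scale * 100.0
    lap_coef = D_mm2 * config.dt_max_ms / grid.dx_mm ** 2
    if lap_coef > 0.25:
        raise ValueError(f"explicit diffusion unstable: D*dt/dx^2 = "
                         f"{lap_coef:.3f} > 0.25; reduce dt_max or refine dx")

    steps_per_sample, first_step, n_frames, t0 = _sampling_plan(config)
    n_steps = int(round(config.duration_ms / config.dt_max_ms))
    out = np.empty((n_frames, H, W), dtype=np.float32)

    st = _alloc_state(H, W)
    status, t_fail, i_fail, j_fail, n_written = _tissue_kernel(
        st["V"], st["G"], st["fca"], st["u"], st["v"], st["Nai"], st["Ki"],
        st["Cai"], st["Caup"], st["Carel"], st["dvdt_prev"],
        lut, prm, config.dt_max_ms, n_sub, DVDT_SUBSTEP_THRESHOLD,
        1.0 / config.Cm_uF_per_cm2, lap_coef,
        stim_t0, stim_t1, stim_reg, stim_amp,
        n_steps, steps_per_sample, first_step, out, 0, 0)
    if status != 0:
        raise NumericalBlowupError(t_fail, i_fail, j_fail)

    meta = {
        "solver": "crn_monodomain",
        "scenario": config.scenario.name,
        "D_cm2_per_ms": config.D_cm2_per_ms * config.scenario.D_scale,
        "dt_min_ms": config.dt_max_ms / n_sub,
        "dt_max_ms": config.dt_max_ms,
        "s1_region": list(s1), "s2_region": list(s2),
        "s1_time_ms": pr.s1_time_ms, "s2_time_ms": pr.s2_time_ms,
        "stim_amplitude_pA_per_pF": pr.amplitude_pA_per_pF,
        "stim_duration_ms": pr.duration_ms,
    }
    return VoltageMovie(out[:n_written], grid.dx_mm,
                        config.sample_interval_ms, t0, meta)


def pace_single_cell(params: CellParams | None = None, *, n_beats: int = 1,
                     cl_ms: float = 1000.0, stim_amp_pA_per_pF: float = 20.0,
                     stim_duration_ms: float = 2.0, duration_ms: float | None = None,
                     dt_max_ms: float = 0.1, dt_min_ms: float = 0.01,
                     sample_interval_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Pace one isolated cell and return (t_ms, V_mV) sampled traces.

    Uses the same compiled stepper as the tissue solver on a 1x1 grid with
    zero diffusion, so the single-cell validation exercises the production
    integration path.
    """
    p = params or CellParams()
    n_sub = max(1, int(round(dt_max_ms / dt_min_ms)))
    lut = build_lut(p, dt_max_ms, dt_max_ms / n_sub)
    prm = pack_params(p)
    duration = duration_ms if duration_ms is not None else n_beats * cl_ms
    n_steps = int(round(duration / dt_max_ms))
    steps_per_sample = int(round(sample_interval_ms / dt_max_ms))
    n_frames = n_steps // steps_per_sample
    out = np.empty((n_frames, 1, 1), dtype=np.float32)

    stim_t0 = np.arange(n_beats, dtype=float) * cl_ms + 1.0
    stim_t1 = stim_t0 + stim_duration_ms
    stim_reg = np.tile(np.array([[0, 1, 0, 1]], dtype=np.int64), (n_beats, 1))
    stim_amp = np.full(n_beats, stim_amp_pA_per_pF, dtype=float)

    st = _alloc_state(1, 1)
    status, t_fail, i_fail, j_fail, n_written = _tissue_kernel(
        st["V"], st["G"], st["fca"], st["u"], st["v"], st["Nai"], st["Ki"],
        st["Cai"], st["Caup"], st["Carel"], st["dvdt_prev"],
        lut, prm, dt_max_ms, n_sub, DVDT_SUBSTEP_THRESHOLD, 1.0, 0.0,
        stim_t0, stim_t1, stim_reg, stim_amp,
        n_steps, steps_per_sample, steps_per_sample, out, 0, 0)
    if status != 0:
        raise NumericalBlowupError(t_fail, i_fail, j_fail)
    t = np.arange(1, n_written + 1) * sample_interval_ms
    return t, out[:n_written, 0, 0].astype(float)


def diffusion_only_run(V0: np.ndarray, D_cm2_per_ms: float, dx_mm: float,
                       duration_ms: float, dt_ms: float = 0.1) -> np.ndarray:
    """Pure diffusion (I_ion = I_stim = 0) with no-flux boundaries.

    With insulated boundaries the spatial mean of V is conserved exactly by
    the mirrored 5-point stencil; used to verify boundary handling.
    """
    V = np.array(V0, dtype=float)
    coef = D_cm2_per_ms * 100.0 * dt_ms / dx_mm ** 2
    if coef > 0.25:
        raise ValueError("unstable diffusion step")
    for _ in range(int(round(duration_ms / dt_ms))):
        padded = np.pad(V, 1, mode="edge")
        lap = (padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2]
               + padded[1:-1, 2:] - 4.0 * V)
        V += coef * lap
    return V


def ap_metrics(t_ms: np.ndarray, V_mV: np.ndarray) -> dict:
    """Resting potential, peak, amplitude and APD90 of a single-cell trace.

    APD90 is measured from the maximal-upstroke time to 90 % repolarisation
    towards the pre-stimulus resting potential.
    """
    t = np.asarray(t_ms, dtype=float)
    V = np.asarray(V_mV, dtype=float)
    dvdt = np.gradient(V, t)
    i_up = int(np.argmax(dvdt))
    v_rest = float(V[:max(i_up - 2, 1)].min()) if i_up > 2 else float(V[0])
    v_peak = float(V.max())
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.nonzero(V[i_up:] <= v90)[0]
    apd90 = float(t[i_up + below[0]] - t[i_up]) if below.size else np.nan
    return {"V_rest_mV": v_rest, "V_peak_mV": v_peak,
            "amplitude_mV": v_peak - v_rest, "APD90_ms": apd90}
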