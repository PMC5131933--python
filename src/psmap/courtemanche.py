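"""Courtemanche-Ramirez-Nattel human atrial action-potential model.

The model describes a single atrial myocyte with 21 state variables: membrane
potential, 12 Hodgkin-Huxley gates (fast Na, transient outward, ultrarapid K,
rapid/slow delayed rectifiers, L-type Ca), the Ca-release machinery (u, v, w
and the Ca-induced fCa gate) and five concentrations (Nai, Ki, Cai, SR uptake
and release compartments).  Conductance/flux multipliers emulate electrical
remodeling of atrial fibrillation (e.g. a 70 % reduction of the L-type Ca
current stabilises reentry).

Two evaluation paths are provided on purpose:

* :func:`rhs` — a plain NumPy right-hand side, usable with any ODE integrator
  (tests integrate it with SciPy's stiff solvers as an independent check);
* :func:`build_lut` — voltage-dependent gate kinetics and current factors
  tabulated on a fine V grid, consumed by the compiled tissue stepper in
  :mod:`psmap.monodomain`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import ScenarioConfig

__all__ = [
    "CellParams",
    "apply_scenario",
    "initial_state",
    "STATE_NAMES",
    "rhs",
    "currents",
    "build_lut",
    "GATE_NAMES",
    "N_LUT_COLS",
]

# physical constants
R_GAS = 8.3143          # J / (mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C / mmol
RTF = R_GAS * TEMP / FARADAY   # ~26.71 mV

# cell geometry / capacitance
CM_PF = 100.0           # membrane capacitance, pF
V_I = 13668.0           # intracellular volume, um^3
V_UP = 1109.52          # SR uptake compartment volume
V_REL = 96.48           # SR release compartment volume

# fixed extracellular concentrations (mM)
KO = 5.4
NAO = 140.0
CAO = 1.8

# buffering
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

KQ10 = 3.0
SIGMA_NAK = (np.exp(NAO / 67.3) - 1.0) / 7.0


@dataclass(frozen=True)
class CellParams:
    """Maximal conductances (nS/pF), pump/exchanger rates and SR fluxes.

    Scenario multipliers scale these fields; ``g_Kur_scale`` scales the whole
    voltage-dependent ultrarapid conductance and ``sr_leak_scale`` the SR leak
    flux.
    """

    g_Na: float = 7.8
    g_K1: float = 0.09
    g_to: float = 0.1652
    g_Kr: float = 0.0294117647
    g_Ks: float = 0.12941176
    g_CaL: float = 0.12375
    g_bCa: float = 0.001131
    g_bNa: float = 0.0006744375
    g_Kur_scale: float = 1.0
    i_NaK_max: float = 0.59933874     # pA/pF
    i_NaCa_max: float = 1600.0        # pA/pF
    i_pCa_max: float = 0.275          # pA/pF
    i_up_max: float = 0.005           # mM/ms
    k_up: float = 0.00092             # mM
    ca_up_max: float = 15.0           # mM
    k_rel: float = 30.0               # 1/ms
    tau_tr: float = 180.0             # ms
    sr_leak_scale: float = 1.0
    km_Nai: float = 10.0
    km_Ko: float = 1.5
    km_Na: float = 87.5
    km_Ca: float = 1.38
    k_sat: float = 0.1
    gamma: float = 0.35


#: scenario multiplier name -> CellParams field it scales
_SCENARIO_FIELDS = {
    "g_Na": "g_Na",
    "g_to": "g_to",
    "g_CaL": "g_CaL",
    "g_Kur": "g_Kur_scale",
    "g_K1": "g_K1",
    "k_NaCa_max": "i_NaCa_max",
    "sr_leak": "sr_leak_scale",
}


def apply_scenario(base: CellParams, scenario: ScenarioConfig) -> CellParams:
    """Return cell parameters with the scenario's multipliers applied.

    ``D_scale`` is not a cell-level parameter and is handled by the tissue
    solver.  The base parameters are never mutated; applying the control
    scenario returns parameters equal to the base.
    """
    if not isinstance(scenario, ScenarioConfig):
        raise TypeError("scenario must be a ScenarioConfig (unknown multiplier "
                        "names are rejected at construction)")
    changes = {}
    for mult_name, field_name in _SCENARIO_FIELDS.items():
        factor = getattr(scenario, mult_name)
        if factor != 1.0:
            changes[field_name] = getattr(base, field_name) * factor
    return replace(base, **changes) if changes else base


STATE_NAMES = ("V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
               "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai",
               "Ca_up", "Ca_rel")

_REST = {
    "V": -81.18, "m": 2.908e-3, "h": 9.649e-1, "j": 9.775e-1,
    "oa": 3.043e-2, "oi": 9.992e-1, "ua": 4.966e-3, "ui": 9.986e-1,
    "xr": 3.296e-5, "xs": 1.869e-2, "d": 1.367e-4, "f": 9.996e-1,
    "fca": 7.755e-1, "u": 0.0, "v": 1.0, "w": 9.992e-1,
    "Nai": 11.17, "Ki": 139.0, "Cai": 1.013e-4,
    "Ca_up": 1.488, "Ca_rel": 1.488,
}


def initial_state() -> np.ndarray:
    """Published resting steady state, the standard 1 Hz initial condition."""
    return np.array([_REST[n] for n in STATE_NAMES], dtype=float)


# --------------------------------------------------------------------------- #
# voltage-dependent gate kinetics (safe at removable singularities)
# --------------------------------------------------------------------------- #

def _safe_ratio(num, den, limit):
    """num/den with the analytic limit substituted where den ~ 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-10
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_kinetics(V):
    """Steady states and time constants of the 12 V-dependent gates.

    Returns two dicts keyed by gate name: ``inf`` and ``tau`` (ms).
    """
    V = np.asarray(V, dtype=float)
    inf, tau = {}, {}

    a_m = _safe_ratio(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    b_m = 0.08 * np.exp(-V / 11.0)
    inf["m"], tau["m"] = a_m / (a_m + b_m), 1.0 / (a_m + b_m)

    lo = V < -40.0
    a_h = np.where(lo, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b_h = np.where(lo, 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
                   1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    inf["h"], tau["h"] = a_h / (a_h + b_h), 1.0 / (a_h + b_h)

    a_j = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0)
    b_j = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))))
    inf["j"], tau["j"] = a_j / (a_j + b_j), 1.0 / (a_j + b_j)

    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf["oa"] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    tau["oa"] = 1.0 / ((a_oa + b_oa) * KQ10)

    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    inf["oi"] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    tau["oi"] = 1.0 / ((a_oi + b_oi) * KQ10)

    a_ua = a_oa  # same rate expressions as the activation of I_to
    b_ua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf["ua"] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    tau["ua"] = 1.0 / ((a_ua + b_ua) * KQ10)

    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    inf["ui"] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    tau["ui"] = 1.0 / ((a_ui + b_ui) * KQ10)

    a_xr = _safe_ratio(0.0003 * (V + 14.1), 1.0 - np.exp(-(V + 14.1) / 5.0),
                       0.0003 * 5.0)
    b_xr = _safe_ratio(7.3898e-5 * (V - 3.3328),
                       np.exp((V - 3.3328) / 5.1237) - 1.0, 7.3898e-5 * 5.1237)
    inf["xr"] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    tau["xr"] = 1.0 / (a_xr + b_xr)

    a_xs = _safe_ratio(4e-5 * (V - 19.9), 1.0 - np.exp(-(V - 19.9) / 17.0),
                       4e-5 * 17.0)
    b_xs = _safe_ratio(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9.0) - 1.0,
                       3.5e-5 * 9.0)
    inf["xs"] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    tau["xs"] = 0.5 / (a_xs + b_xs)

    ex = np.exp(-(V + 10.0) / 6.24)
    inf["d"] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    tau["d"] = _safe_ratio(1.0 - ex, 0.035 * (V + 10.0) * (1.0 + ex),
                           1.0 / (2.0 * 0.035 * 6.24))

    inf["f"] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau["f"] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)

    ew = np.exp(-(V - 7.9) / 5.0)
    inf["w"] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    tau["w"] = _safe_ratio(6.0 * (1.0 - ew), (1.0 + 0.3 * ew) * (V - 7.9),
                           6.0 / (5.0 * 1.3))

    return inf, tau


GATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")


# --------------------------------------------------------------------------- #
# currents and full right-hand side (NumPy path)
# --------------------------------------------------------------------------- #

def currents(y: np.ndarray, p: CellParams) -> dict:
    """All membrane currents (pA/pF) and SR fluxes (mM/ms) at state ``y``.

    ``y`` may be a (21,) vector or a (21, N) batch.
    """
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
     Nai, Ki, Cai, Ca_up, Ca_rel) = y

    ENa = RTF * np.log(NAO / Nai)
    EK = RTF * np.log(KO / Ki)
    ECa = 0.5 * RTF * np.log(CAO / Cai)

    out = {}
    out["I_Na"] = p.g_Na * m ** 3 * h * j * (V - ENa)
    out["I_K1"] = p.g_K1 * (V - EK) / (1.0 + np.exp(0.07 * (V + 80.0)))
    out["I_to"] = p.g_to * oa ** 3 * oi * (V - EK)
    g_kur = p.g_Kur_scale * (0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0)))
    out["I_Kur"] = g_kur * ua ** 3 * ui * (V - EK)
    out["I_Kr"] = p.g_Kr * xr * (V - EK) / (1.0 + np.exp((V + 15.0) / 22.4))
    out["I_Ks"] = p.g_Ks * xs ** 2 * (V - EK)
    out["I_CaL"] = p.g_CaL * d * f * fca * (V - 65.0)

    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                   + 0.0365 * SIGMA_NAK * np.exp(-V / RTF))
    out["I_NaK"] = (p.i_NaK_max * f_nak * (1.0 / (1.0 + (p.km_Nai / Nai) ** 1.5))
                    * KO / (KO + p.km_Ko))

    e1 = np.exp(p.gamma * V / RTF)
    e2 = np.exp((p.gamma - 1.0) * V / RTF)
    den = ((p.km_Na ** 3 + NAO ** 3) * (p.km_Ca + CAO)
           * (1.0 + p.k_sat * e2))
    out["I_NaCa"] = p.i_NaCa_max * (e1 * Nai ** 3 * CAO - e2 * NAO ** 3 * Cai) / den

    out["I_bNa"] = p.g_bNa * (V - ENa)
    out["I_bCa"] = p.g_bCa * (V - ECa)
    out["I_pCa"] = p.i_pCa_max * Cai / (0.0005 + Cai)

    out["I_rel"] = p.k_rel * u ** 2 * v * w * (Ca_rel - Cai)
    out["I_tr"] = (Ca_up - Ca_rel) / p.tau_tr
    out["I_up"] = p.i_up_max / (1.0 + p.k_up / Cai)
    out["I_up_leak"] = p.sr_leak_scale * p.i_up_max * Ca_up / p.ca_up_max
    return out


def rhs(y: np.ndarray, p: CellParams, i_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the full state (reaction only, no diffusion).

    ``i_stim`` follows the monodomain sign convention
    dV/dt = -(I_ion + I_stim)/Cm, so a depolarising stimulus is negative.
    """
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
     Nai, Ki, Cai, Ca_up, Ca_rel) = y
    cur = currents(y, p)
    inf, tau = gate_kinetics(V)

    i_ion = (cur["I_Na"] + cur["I_K1"] + cur["I_to"] + cur["I_Kur"]
             + cur["I_Kr"] + cur["I_Ks"] + cur["I_CaL"] + cur["I_NaK"]
             + cur["I_NaCa"] + cur["I_bNa"] + cur["I_bCa"] + cur["I_pCa"])

    dy = np.empty_like(np.asarray(y, dtype=float))
    dy[0] = -(i_ion + i_stim)

    gates = dict(zip(STATE_NAMES[1:12], (m, h, j, oa, oi, ua, ui, xr, xs, d, f)))
    for k, name in enumerate(("m", "h", "j", "oa", "oi", "ua", "ui",
                              "xr", "xs", "d", "f"), start=1):
        dy[k] = (inf[name] - gates[name]) / tau[name]

    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    dy[12] = (fca_inf - fca) / 2.0

    # Ca release gating driven by Fn (currents converted to pA via Cm)
    fn = (1e-12 * V_REL * cur["I_rel"]
          - (5e-13 / FARADAY) * (0.5 * CM_PF * cur["I_CaL"]
                                 - 0.2 * CM_PF * cur["I_NaCa"]))
    u_inf = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 * u_inf
    dy[13] = (u_inf - u) / 8.0
    dy[14] = (v_inf - v) / tau_v
    dy[15] = (inf["w"] - w) / tau["w"]

    dy[16] = (-3.0 * cur["I_NaK"] - 3.0 * cur["I_NaCa"] - cur["I_bNa"]
              - cur["I_Na"]) * CM_PF / (FARADAY * V_I)
    dy[17] = (2.0 * cur["I_NaK"] - cur["I_K1"] - cur["I_to"] - cur["I_Kur"]
              - cur["I_Kr"] - cur["I_Ks"]) * CM_PF / (FARADAY * V_I)

    b1 = ((2.0 * cur["I_NaCa"] - cur["I_pCa"] - cur["I_CaL"] - cur["I_bCa"])
          * CM_PF / (2.0 * FARADAY * V_I)
          + (V_UP * (cur["I_up_leak"] - cur["I_up"])
             + cur["I_rel"] * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2)
    dy[18] = b1 / b2
    dy[19] = cur["I_up"] - cur["I_up_leak"] - cur["I_tr"] * V_REL / V_UP
    dy[20] = (cur["I_tr"] - cur["I_rel"]) / (
        1.0 + CSQN_MAX * KM_CSQN / (Ca_rel + KM_CSQN) ** 2)
    return dy


# --------------------------------------------------------------------------- #
# lookup table for the compiled tissue stepper
# --------------------------------------------------------------------------- #

LUT_VMIN = -120.0
LUT_VMAX = 80.0
LUT_DV = 0.05

# column layout: 12 gate steady states, 12 Rush-Larsen factors for the coarse
# step, 12 for the fine step, then V-dependent current factors
COL_INF = 0
COL_RL_COARSE = 12
COL_RL_FINE = 24
COL_FK1 = 36
COL_FKR = 37
COL_GKUR = 38
COL_FNAK = 39
COL_ENACA1 = 40
COL_ENACA2 = 41
N_LUT_COLS = 42


def build_lut(p: CellParams, dt_coarse: float, dt_fine: float) -> np.ndarray:
    """Tabulate V-dependent kinetics/current factors on the LUT voltage grid.

    Rush-Larsen factors exp(-dt/tau(V)) are stored for the two discrete time
    steps the tissue stepper uses, so the inner loop needs no transcendental
    calls for the gates.
    """
    V = np.arange(LUT_VMIN, LUT_VMAX + LUT_DV / 2, LUT_DV)
    lut = np.empty((V.size, N_LUT_COLS), dtype=np.float64)
    inf, tau = gate_kinetics(V)
    for k, name in enumerate(GATE_NAMES):
        lut[:, COL_INF + k] = inf[name]
        lut[:, COL_RL_COARSE + k] = np.exp(-dt_coarse / tau[name])
        lut[:, COL_RL_FINE + k] = np.exp(-dt_fine / tau[name])
    lut[:, COL_FK1] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
    lut[:, COL_FKR] = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))
    lut[:, COL_GKUR] = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    lut[:, COL_FNAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                              + 0.0365 * SIGMA_NAK * np.exp(-V / RTF))
    lut[:, COL_ENACA1] = np.exp(p.gamma * V / RTF)
    lut[:, COL_ENACA2] = np.exp((p.gamma - 1.0) * V / RTF)
    return lut


def pack_params(p: CellParams) -> np.ndarray:
    """Flatten CellParams into the vector consumed by the compiled stepper."""
    return np.array([
        p.g_Na, p.g_K1, p.g_to, p.g_Kr, p.g_Ks, p.g_CaL, p.g_bCa, p.g_bNa,
        p.g_Kur_scale, p.i_NaK_max, p.i_NaCa_max, p.i_pCa_max,
        p.i_up_max, p.k_up, p.ca_up_max, p.k_rel, p.tau_tr, p.sr_leak_scale,
        p.km_Nai, p.km_Ko,
        (p.km_Na ** 3 + NAO ** 3) * (p.km_Ca + CAO),   # NaCa denominator
        p.k_sat, p.gamma,
    ], dtype=np.float64)


# indices into the packed parameter vector (kept in sync with pack_params)
(P_GNA, P_GK1, P_GTO, P_GKR, P_GKS, P_GCAL, P_GBCA, P_GBNA, P_GKUR,
 P_INAK, P_INACA, P_IPCA, P_IUP, P_KUP, P_CAUPMAX, P_KREL, P_TAUTR,
 P_SRLEAK, P_KMNAI, P_KMKO, P_NACADEN, P_KSAT, P_GAMMA) = range(23)
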