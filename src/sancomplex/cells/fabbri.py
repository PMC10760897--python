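"""Human sinoatrial-node pacemaker cell model (Fabbri/Severi lineage).

A Hodgkin-Huxley-type pacemaker myocyte with the full current complement of
the modern human SAN formulations: If (funny current), INa, ICaL, ICaT, IKr,
IKs, Ito, IKur, IKACh, INaK, INaCa, coupled to a Maltsev-Lakatta style
intracellular Ca2+ system (subsarcolemmal space, myoplasm, junctional and
network SR, RyR release with Ca-dependent activation/inactivation, SERCA
uptake, troponin/calmodulin/calsequestrin buffers).  Intracellular Na+ and K+
are held fixed, as in the published human SAN model.

Acetylcholine / adenosine acts through four effects (the convention of the
human SAN model this package follows): IKACh activation, a negative shift of
the If activation curve, fractional ICaL block, and reduced SR Ca uptake.
Adenosine doses are expressed through the same pathway (A1 receptors couple
to the same GIRK channel); regional A1R expression scales the maximal IKACh
conductance per node.

A Courtemanche-type inward-rectifier IK1 can be added with a regional scale
factor; it is zero in genuine pacemaker compartments and positive in the
transitional cells of the conduction pathways (SACPs), which renders those
cells excitable but quiescent.

Because the archived reference implementation of the published human SAN
model is not redistributable here, maximal conductances were calibrated once
so that the cell reproduces the published human SAN action-potential
biomarkers (cycle length ~814 ms, MDP near -59 mV, low upstroke velocity,
peak near +17 mV); see docs/methods.md.

Units: time ms, V mV, currents nA, concentrations mM, conductances uS.
"""

from __future__ import annotations

import numpy as np
from numba import njit

R_GAS = 8314.472
TEMP = 310.0
FARADAY = 96485.3415
RTF = R_GAS * TEMP / FARADAY  # mV (~26.73)

CM_NF = 5.7e-2  # membrane capacitance, nF (57 pF)

# fixed ion concentrations (mM)
NAI = 5.0
KI = 140.0
KO = 5.4
NAO = 140.0
CAO = 1.8
MGI = 2.5

# compartment volumes (litres); cylinder r=3.9 um, L=67 um
V_CELL = np.pi * 3.9 ** 2 * 67.0 * 1e-15
V_SUB = 0.01 * V_CELL
V_JSR = 0.0012 * V_CELL
V_NSR = 0.0116 * V_CELL
V_MYO = 0.46 * V_CELL - V_SUB

# charge->concentration conversion, mM per (nA*ms) in each volume
K_FLUX_SUB = 1e-12 / (2.0 * FARADAY * V_SUB)

E_MH = RTF * np.log((NAO + 0.12 * KO) / (NAI + 0.12 * KI))
EK = RTF * np.log(KO / KI)
EKS = RTF * np.log((KO + 0.12 * NAO) / (KI + 0.12 * NAI))
ENA = RTF * np.log(NAO / NAI)

# --- default maximal conductances / transport rates -------------------------
# Calibrated to the published human SAN AP biomarkers (see module docstring).
DEFAULTS = dict(
    g_na=0.004,         # uS
    g_f_na=3.582e-4,    # uS
    g_f_k=4.104e-4,     # uS
    p_cal=0.115,        # nA/mM
    p_cat=0.0045,       # nA/mM
    g_kr=0.00135,       # uS
    g_ks=0.00065,       # uS
    g_to=0.0035,        # uS
    g_kur=0.0001539,    # uS
    g_kach=0.002,       # uS
    g_k1=0.0,           # uS, inward rectifier addon (0 in SAN compartments)
    g_k1_base=0.00513,  # uS, unit conductance used by the regional IK1 scale
    i_nak_max=0.08105,  # nA
    k_naca=2.2,         # nA
    p_up=0.0013,        # mM/ms
    k_up=2.86e-4,       # mM
    slope_up=5e-5,      # mM
    ks_rel=35.0,        # 1/ms, RyR release rate
    tau_dif_ca=0.04,    # ms, sub <-> myoplasm Ca diffusion
    tau_tr=40.0,        # ms, NSR -> JSR transfer
    km_fca=0.000338,    # mM
    alpha_fca=0.0075,   # 1/ms
)

# RyR kinetics (Maltsev-Lakatta)
KOCA = 10.0     # mM^-2 ms^-1
KOM = 0.06      # ms^-1
KICA = 0.5      # mM^-1 ms^-1
KIM = 0.005     # ms^-1
EC50_SR = 0.45  # mM
MAX_SR = 15.0
MIN_SR = 1.0
HSR = 2.5

# buffers
TC_TOT, TMC_TOT, CM_TOT, CQ_TOT = 0.031, 0.062, 0.045, 10.0
KF_TC, KB_TC = 88.8, 0.446
KF_TMC, KB_TMC = 227.7, 0.00751
KF_TMM, KB_TMM = 2.277, 0.751
KF_CM, KB_CM = 227.7, 0.542
KF_CQ, KB_CQ = 0.534, 0.445

# NaCa exchanger (6-state) constants
K1NI, K1NO = 395.3, 1628.0
K2NI, K2NO = 2.289, 561.4
K3NI, K3NO = 26.44, 4.663
KCI, KCO, KCNI = 0.0207, 3.663, 26.44
QCI, QCO, QN = 0.1369, 0.0, 0.4315

_NACA_NA1 = (NAI / K1NI) * (1.0 + (NAI / K2NI) * (1.0 + NAI / K3NI))
_NACA_C14 = (NAI / K1NI) * (NAI / K2NI) * (1.0 + NAI / K3NI)
_NACA_K43 = NAI / (K3NI + NAI)
_NACA_DO = 1.0 + (CAO / KCO) * 2.0 + (NAO / K1NO) * (1.0 + (NAO / K2NO) * (1.0 + NAO / K3NO))
_NACA_K21 = (CAO / KCO) / _NACA_DO
_NACA_C23 = (NAO / K1NO) * (NAO / K2NO) * (1.0 + NAO / K3NO) / _NACA_DO
_NACA_K34 = NAO / (K3NO + NAO)

# state vector layout (V carried separately)
(Y, M, H, DL, FL, FCA, DT_, FT, PAS, PAF, PI_, N_, Q, R_, RKUR, SKUR, A,
 RYR_R, RYR_O, RYR_I, RYR_RI, FTC, FTMC, FTMM, FCMI, FCMS, FCQ,
 CAI, CASUB, CAJSR, CANSR) = range(31)
N_STATES = 31

# lookup-table rows
(T_Y_INF, T_Y_RATE, T_M_INF, T_M_RATE, T_H_INF, T_H_RATE,
 T_DL_INF, T_DL_RATE, T_FL_INF, T_FL_RATE, T_DT_INF, T_DT_RATE,
 T_FT_INF, T_FT_RATE, T_PAS_INF, T_PAS_RATE, T_PAF_INF, T_PAF_RATE,
 T_PI_INF, T_PI_RATE, T_N_INF, T_N_RATE, T_Q_INF, T_Q_RATE,
 T_R_INF, T_R_RATE, T_RKUR_INF, T_RKUR_RATE, T_SKUR_INF, T_SKUR_RATE,
 T_A2, T_E2, T_A1, T_E1, T_FNAK, T_KACH_V, T_BETA_A,
 T_E_QCI, T_E_QN, T_E_MQN, T_K1_V) = range(41)
N_TAB = 41

TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.02

# cell-parameter scalar block passed to the kernel
(CP_GNA, CP_GFNA, CP_GFK, CP_PCAL, CP_PCAT, CP_GKR, CP_GKS, CP_GTO,
 CP_GKUR, CP_GKACH, CP_GK1, CP_INAK, CP_KNACA, CP_PUP, CP_KS,
 CP_ALPHA_A, CP_ACH_ON) = range(17)
N_CP = 17


def ach_effects(ach_nm: float) -> dict:
    """The four agonist effects, as fractional modifiers.

    Returns dict with: ``if_shift`` (mV, negative), ``cal_block`` (0..1),
    ``up_block`` (0..1), ``alpha_a`` (1/ms IKACh gate opening rate).
    """
    if ach_nm < 0:
        raise ValueError("ACh concentration must be >= 0")
    ach_mm = ach_nm * 1e-6
    if ach_nm == 0:
        return dict(if_shift=0.0, cal_block=0.0, up_block=0.0, alpha_a=0.025641e-3)
    pow_a = ach_mm ** 0.618
    shift = -1.0 - 9.898 * pow_a / (pow_a + 0.00122 ** 0.618)
    cal_block = 0.31 * ach_mm / (ach_mm + 9e-5)
    up_block = 0.7 * ach_mm / (ach_mm + 9e-5)
    alpha_a = ((3.5988 - 0.025641) / (1.0 + 1.2155e-6 / ach_mm ** 1.6951)
               + 0.025641) * 1e-3
    return dict(if_shift=shift, cal_block=cal_block, up_block=up_block, alpha_a=alpha_a)


def cell_params(ach_nm: float = 0.0, overrides: dict | None = None) -> np.ndarray:
    """Assemble the scalar parameter block for the kernel.

    ``overrides`` replaces entries of :data:`DEFAULTS` (absolute values, not
    scale factors; regional scale factors are applied per node by the
    caller).
    """
    p = dict(DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(p)
        if unknown:
            raise KeyError(f"unknown cell parameters: {sorted(unknown)}")
        p.update(overrides)
    eff = ach_effects(ach_nm)
    cp = np.zeros(N_CP)
    cp[CP_GNA] = p["g_na"]
    cp[CP_GFNA] = p["g_f_na"]
    cp[CP_GFK] = p["g_f_k"]
    cp[CP_PCAL] = p["p_cal"] * (1.0 - eff["cal_block"])
    cp[CP_PCAT] = p["p_cat"]
    cp[CP_GKR] = p["g_kr"]
    cp[CP_GKS] = p["g_ks"]
    cp[CP_GTO] = p["g_to"]
    cp[CP_GKUR] = p["g_kur"]
    cp[CP_GKACH] = p["g_kach"]
    cp[CP_GK1] = p["g_k1_base"]
    cp[CP_INAK] = p["i_nak_max"]
    cp[CP_KNACA] = p["k_naca"]
    cp[CP_PUP] = p["p_up"] * (1.0 - eff["up_block"])
    cp[CP_KS] = p["ks_rel"]
    cp[CP_ALPHA_A] = eff["alpha_a"]
    cp[CP_ACH_ON] = 1.0 if ach_nm > 0 else 0.0
    return cp


def _lim(num, den, limit):
    out = np.where(np.abs(den) < 1e-9, limit, num / np.where(np.abs(den) < 1e-9, 1.0, den))
    return out


def build_tables(ach_nm: float = 0.0) -> np.ndarray:
    """Voltage-dependent quantities on a uniform grid; the If activation
    shift produced by the agonist is baked into the y-gate rows."""
    v = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    tab = np.zeros((N_TAB, v.size))
    eff = ach_effects(ach_nm)
    vs = v - eff["if_shift"]  # negative shift moves activation to more negative V

    # If gate y
    tab[T_Y_INF] = 1.0 / (1.0 + np.exp((vs + 68.0) / 9.0))
    tau_y = 0.7166529 / (np.exp(-(vs + 386.9) / 45.302) + np.exp((vs - 73.08) / 19.231))
    tab[T_Y_RATE] = 1.0 / np.maximum(tau_y, 1.0)

    # INa (Noble-type kinetics, rates in 1/ms)
    e0 = v + 41.0
    a_m = _lim(0.2 * e0, 1.0 - np.exp(-0.1 * e0), 2.0)
    b_m = 8.0 * np.exp(-0.056 * (v + 66.0))
    tab[T_M_INF] = a_m / (a_m + b_m)
    tab[T_M_RATE] = a_m + b_m
    a_h = 0.02 * np.exp(-0.125 * (v + 75.0))
    b_h = 2.0 / (320.0 * np.exp(-0.1 * (v + 75.0)) + 1.0)
    tab[T_H_INF] = a_h / (a_h + b_h)
    tab[T_H_RATE] = a_h + b_h

    # ICaL gates
    tab[T_DL_INF] = 1.0 / (1.0 + np.exp(-(v + 20.3) / 4.2))
    a_dl = _lim(-0.02839 * (v + 41.8), np.exp(-(v + 41.8) / 2.5) - 1.0, 0.071) \
        + _lim(-0.0849 * (v + 6.8), np.exp(-(v + 6.8) / 4.8) - 1.0, 0.408)
    b_dl = _lim(0.01143 * (v + 1.8), np.exp((v + 1.8) / 2.5) - 1.0, 0.0286)
    tab[T_DL_RATE] = 2.0 * (a_dl + b_dl)
    tab[T_FL_INF] = 1.0 / (1.0 + np.exp((v + 37.4) / 5.3))
    tab[T_FL_RATE] = 1.0 / (44.3 + 230.0 * np.exp(-((v + 36.0) / 10.0) ** 2))

    # ICaT gates
    tab[T_DT_INF] = 1.0 / (1.0 + np.exp(-(v + 38.3) / 5.5))
    tab[T_DT_RATE] = 1.068 * np.exp((v + 38.3) / 30.0) + 1.068 * np.exp(-(v + 38.3) / 30.0)
    tab[T_FT_INF] = 1.0 / (1.0 + np.exp((v + 58.7) / 3.8))
    tab[T_FT_RATE] = 0.0153 * np.exp(-(v + 61.7) / 83.3) + 0.015 * np.exp((v + 61.7) / 15.38)

    # IKr gates
    pa_inf = 1.0 / (1.0 + np.exp(-(v + 10.0144) / 7.6607))
    tab[T_PAS_INF] = pa_inf
    tab[T_PAF_INF] = pa_inf
    tab[T_PAS_RATE] = (0.0042 * np.exp(v / 17.0) + 0.00015 * np.exp(-v / 21.6)) / 0.84655354
    tab[T_PAF_RATE] = 0.0372 * np.exp(v / 15.883) + 0.00096 * np.exp(-v / 20.0277)
    tab[T_PI_INF] = 1.0 / (1.0 + np.exp((v + 28.6) / 17.1))
    tab[T_PI_RATE] = 0.1 * np.exp(-v / 54.645) + 0.656 * np.exp(v / 106.157)

    # IKs gate
    tab[T_N_INF] = 1.0 / (1.0 + np.exp(-(v + 0.6383) / 10.7071))
    tab[T_N_RATE] = 0.028 / (1.0 + np.exp(-(v - 40.0) / 3.0)) + 0.001 * np.exp(-v / 25.0)

    # Ito gates
    tab[T_Q_INF] = 1.0 / (1.0 + np.exp((v + 49.0) / 13.0))
    tau_q = 0.6 * (65.17 / (0.57 * np.exp(-0.08 * (v + 44.0))
                            + 0.065 * np.exp(0.1 * (v + 45.93))) + 10.1)
    tab[T_Q_RATE] = 1.0 / tau_q
    tab[T_R_INF] = 1.0 / (1.0 + np.exp(-(v - 19.3) / 15.0))
    tau_r = 0.66 * 1.4 * (15.59 / (1.037 * np.exp(0.09 * (v + 30.61))
                                   + 0.369 * np.exp(-0.12 * (v + 23.84))) + 2.98)
    tab[T_R_RATE] = 1.0 / tau_r

    # IKur gates
    tab[T_RKUR_INF] = 1.0 / (1.0 + np.exp(-(v + 6.0) / 8.6))
    tab[T_RKUR_RATE] = 1.0 / (9.0 / (1.0 + np.exp((v + 5.0) / 12.0)) + 0.5)
    tab[T_SKUR_INF] = 1.0 / (1.0 + np.exp((v + 7.5) / 10.0))
    tab[T_SKUR_RATE] = 1.0 / (590.0 / (1.0 + np.exp((v + 60.0) / 10.0)) + 3050.0)

    # GHK voltage profiles
    x2 = 2.0 * v / RTF
    e2 = np.exp(-x2)
    tab[T_A2] = _lim(2.0 * v / RTF, 1.0 - e2, 1.0)
    tab[T_E2] = e2
    x1 = v / RTF
    e1 = np.exp(-x1)
    tab[T_A1] = _lim(v / RTF, 1.0 - e1, 1.0)
    tab[T_E1] = e1

    tab[T_FNAK] = 1.0 / (1.0 + np.exp(-(v - ENA + 110.0) / 20.0))
    tab[T_KACH_V] = (v - EK) * (1.0 + np.exp((v + 20.0) / 20.0))
    tab[T_BETA_A] = 0.01 * np.exp(0.0133 * (v + 40.0))

    tab[T_E_QCI] = np.exp(-QCI * v / RTF)
    tab[T_E_QN] = np.exp(QN * v / (2.0 * RTF))
    tab[T_E_MQN] = np.exp(-QN * v / (2.0 * RTF))
    tab[T_K1_V] = (v - EK) / (1.0 + np.exp(0.07 * (v + 80.0)))
    return np.ascontiguousarray(tab)


def initial_state(v: float = -60.0) -> np.ndarray:
    """A physiologically plausible cold-start state (diastolic).  Production
    runs start from region-specific limit-cycle states instead (see
    :mod:`sancomplex.singlecell`)."""
    tab = build_tables(0.0)
    vgrid = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    i = int(np.searchsorted(vgrid, v))
    s = np.zeros(N_STATES)
    for gate, (ti, _tr) in GATE_ROWS.items():
        s[gate] = tab[ti, i]
    s[FCA] = 0.7
    s[A] = 0.0
    s[RYR_R] = 0.9
    s[RYR_O] = 1e-6
    s[RYR_I] = 1e-6
    s[RYR_RI] = 0.05
    s[FTC] = 0.02
    s[FTMC] = 0.35
    s[FTMM] = 0.5
    s[FCMI] = 0.05
    s[FCMS] = 0.05
    s[FCQ] = 0.3
    s[CAI] = 1e-4
    s[CASUB] = 5e-5
    s[CAJSR] = 0.3
    s[CANSR] = 1.0
    return s


GATE_ROWS = {
    Y: (T_Y_INF, T_Y_RATE), M: (T_M_INF, T_M_RATE), H: (T_H_INF, T_H_RATE),
    DL: (T_DL_INF, T_DL_RATE), FL: (T_FL_INF, T_FL_RATE),
    DT_: (T_DT_INF, T_DT_RATE), FT: (T_FT_INF, T_FT_RATE),
    PAS: (T_PAS_INF, T_PAS_RATE), PAF: (T_PAF_INF, T_PAF_RATE),
    PI_: (T_PI_INF, T_PI_RATE), N_: (T_N_INF, T_N_RATE),
    Q: (T_Q_INF, T_Q_RATE), R_: (T_R_INF, T_R_RATE),
    RKUR: (T_RKUR_INF, T_RKUR_RATE), SKUR: (T_SKUR_INF, T_SKUR_RATE),
}


@njit(cache=True)
def san_node_step(v, s, dt, tab, cp, s_na, s_f, s_k1, s_kach):
    """Advance one SAN-model node one forward-Euler step.

    ``s_na, s_f, s_k1, s_kach`` are the regional scale factors for INa, If,
    the IK1 addon and IKACh (A1R expression).  Returns the ionic dV/dt
    (mV/ms) at the pre-step state; gating/Ca states update in place.
    """
    u = (v - TAB_VMIN) / TAB_DV
    i = int(u)
    if i < 0:
        i = 0
    elif i > tab.shape[1] - 2:
        i = tab.shape[1] - 2
    fr = u - i

    def lk(row):
        a0 = tab[row, i]
        return a0 + fr * (tab[row, i + 1] - a0)

    # floors keep ratio terms defined if an unstable step drives a
    # concentration to zero; divergence is then caught by the |V| guard
    cai = max(s[CAI], 1e-12)
    casub = max(s[CASUB], 1e-12)
    cajsr = max(s[CAJSR], 1e-12)
    cansr = max(s[CANSR], 1e-12)

    # membrane currents (nA)
    i_f = s[Y] * (s_f * cp[CP_GFNA] * (v - ENA) + s_f * cp[CP_GFK] * (v - EK))
    i_na = s_na * cp[CP_GNA] * s[M] ** 3 * s[H] * (v - E_MH)
    ghk2 = lk(T_A2)
    e2 = lk(T_E2)
    ghk1 = lk(T_A1)
    e1 = lk(T_E1)
    dlfl = s[DL] * s[FL] * s[FCA]
    i_sica = 2.0 * cp[CP_PCAL] * ghk2 * (casub - CAO * e2) * dlfl
    i_sik = 0.000365 * cp[CP_PCAL] * ghk1 * (KI - KO * e1) * dlfl
    i_sina = 0.0000185 * cp[CP_PCAL] * ghk1 * (NAI - NAO * e1) * dlfl
    i_cal = i_sica + i_sik + i_sina
    i_cat = 2.0 * cp[CP_PCAT] * ghk2 * (casub - CAO * e2) * s[DT_] * s[FT]
    i_kr = cp[CP_GKR] * (0.9 * s[PAF] + 0.1 * s[PAS]) * s[PI_] * (v - EK)
    i_ks = cp[CP_GKS] * s[N_] ** 2 * (v - EKS)
    i_to = cp[CP_GTO] * s[Q] * s[R_] * (v - EK)
    i_kur = cp[CP_GKUR] * s[RKUR] * s[SKUR] * (v - EK)
    i_kach = cp[CP_ACH_ON] * s_kach * cp[CP_GKACH] * s[A] * lk(T_KACH_V)
    i_k1 = s_k1 * cp[CP_GK1] * lk(T_K1_V)
    i_nak = cp[CP_INAK] * 0.1736 * lk(T_FNAK)

    # NaCa exchanger (6-state, fixed Nai)
    e_qci = lk(T_E_QCI)
    e_qn = lk(T_E_QN)
    e_mqn = lk(T_E_MQN)
    di = 1.0 + (casub / KCI) * (1.0 + e_qci + NAI / KCNI) + _NACA_NA1
    k12 = (casub / KCI) * e_qci / di
    k14 = _NACA_C14 * e_qn / di
    k41 = e_mqn
    k21 = _NACA_K21
    k23 = _NACA_C23 * e_mqn
    k32 = e_qn
    k34 = _NACA_K34
    k43 = _NACA_K43
    x1 = k41 * k34 * (k23 + k21) + k21 * k32 * (k43 + k41)
    x2 = k32 * k43 * (k14 + k12) + k41 * k12 * (k34 + k32)
    x3 = k14 * k43 * (k23 + k21) + k12 * k23 * (k43 + k41)
    x4 = k23 * k34 * (k14 + k12) + k14 * k21 * (k34 + k32)
    i_naca = cp[CP_KNACA] * (x2 * k21 - x1 * k12) / (x1 + x2 + x3 + x4)

    itot = (i_f + i_na + i_cal + i_cat + i_kr + i_ks + i_to + i_kur
            + i_kach + i_k1 + i_nak + i_naca)

    # gate updates
    s[Y] += dt * (lk(T_Y_INF) - s[Y]) * lk(T_Y_RATE)
    s[M] += dt * (lk(T_M_INF) - s[M]) * lk(T_M_RATE)
    s[H] += dt * (lk(T_H_INF) - s[H]) * lk(T_H_RATE)
    s[DL] += dt * (lk(T_DL_INF) - s[DL]) * lk(T_DL_RATE)
    s[FL] += dt * (lk(T_FL_INF) - s[FL]) * lk(T_FL_RATE)
    fca_inf = DEF_KM_FCA / (DEF_KM_FCA + casub)
    s[FCA] += dt * (fca_inf - s[FCA]) * DEF_ALPHA_FCA / max(fca_inf, 1e-4)
    s[DT_] += dt * (lk(T_DT_INF) - s[DT_]) * lk(T_DT_RATE)
    s[FT] += dt * (lk(T_FT_INF) - s[FT]) * lk(T_FT_RATE)
    s[PAS] += dt * (lk(T_PAS_INF) - s[PAS]) * lk(T_PAS_RATE)
    s[PAF] += dt * (lk(T_PAF_INF) - s[PAF]) * lk(T_PAF_RATE)
    s[PI_] += dt * (lk(T_PI_INF) - s[PI_]) * lk(T_PI_RATE)
    s[N_] += dt * (lk(T_N_INF) - s[N_]) * lk(T_N_RATE)
    s[Q] += dt * (lk(T_Q_INF) - s[Q]) * lk(T_Q_RATE)
    s[R_] += dt * (lk(T_R_INF) - s[R_]) * lk(T_R_RATE)
    s[RKUR] += dt * (lk(T_RKUR_INF) - s[RKUR]) * lk(T_RKUR_RATE)
    s[SKUR] += dt * (lk(T_SKUR_INF) - s[SKUR]) * lk(T_SKUR_RATE)
    beta_a = lk(T_BETA_A)
    s[A] += dt * (cp[CP_ALPHA_A] * (1.0 - s[A]) - beta_a * s[A])

    # RyR release
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC50_SR / cajsr) ** HSR)
    kosrca = KOCA / kcasr
    kisrca = KICA * kcasr
    dR = KIM * s[RYR_RI] - kisrca * casub * s[RYR_R] - (kosrca * casub ** 2 * s[RYR_R] - KOM * s[RYR_O])
    dO = kosrca * casub ** 2 * s[RYR_R] - KOM * s[RYR_O] - (kisrca * casub * s[RYR_O] - KIM * s[RYR_I])
    dI = kisrca * casub * s[RYR_O] - KIM * s[RYR_I] - (KOM * s[RYR_I] - kosrca * casub ** 2 * s[RYR_RI])
    dRI = KOM * s[RYR_I] - kosrca * casub ** 2 * s[RYR_RI] - KIM * s[RYR_RI]
    j_rel = cp[CP_KS] * s[RYR_O] * (cajsr - casub)

    # SR fluxes
    j_up = cp[CP_PUP] / (1.0 + np.exp((-cai + DEF_K_UP) / DEF_SLOPE_UP))
    j_tr = (cansr - cajsr) / DEF_TAU_TR
    j_diff = (casub - cai) / DEF_TAU_DIF

    # buffers
    dftc = KF_TC * cai * (1.0 - s[FTC]) - KB_TC * s[FTC]
    dftmc = KF_TMC * cai * (1.0 - s[FTMC] - s[FTMM]) - KB_TMC * s[FTMC]
    dftmm = KF_TMM * MGI * (1.0 - s[FTMC] - s[FTMM]) - KB_TMM * s[FTMM]
    dfcmi = KF_CM * cai * (1.0 - s[FCMI]) - KB_CM * s[FCMI]
    dfcms = KF_CM * casub * (1.0 - s[FCMS]) - KB_CM * s[FCMS]
    dfcq = KF_CQ * cajsr * (1.0 - s[FCQ]) - KB_CQ * s[FCQ]

    s[RYR_R] += dt * dR
    s[RYR_O] += dt * dO
    s[RYR_I] += dt * dI
    s[RYR_RI] += dt * dRI
    s[FTC] += dt * dftc
    s[FTMC] += dt * dftmc
    s[FTMM] += dt * dftmm
    s[FCMI] += dt * dfcmi
    s[FCMS] += dt * dfcms
    s[FCQ] += dt * dfcq

    s[CAI] += dt * ((j_diff * V_SUB - j_up * V_NSR) / V_MYO
                    - (CM_TOT * dfcmi + TC_TOT * dftc + TMC_TOT * dftmc))
    s[CASUB] += dt * (-(i_sica + i_cat - 2.0 * i_naca) * K_FLUX_SUB
                      + j_rel * V_JSR / V_SUB - j_diff - CM_TOT * dfcms)
    s[CAJSR] += dt * (j_tr - j_rel - CQ_TOT * dfcq)
    s[CANSR] += dt * (j_up - j_tr * V_JSR / V_NSR)

    return -itot / CM_NF


# constants referenced inside the kernel (resolved at compile time)
DEF_KM_FCA = DEFAULTS["km_fca"]
DEF_ALPHA_FCA = DEFAULTS["alpha_fca"]
DEF_K_UP = DEFAULTS["k_up"]
DEF_SLOPE_UP = DEFAULTS["slope_up"]
DEF_TAU_TR = DEFAULTS["tau_tr"]
DEF_TAU_DIF = DEFAULTS["tau_dif_ca"]
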