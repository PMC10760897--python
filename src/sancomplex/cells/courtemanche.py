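"""Human right-atrial myocyte model (Courtemanche-Ramirez-Nattel formulation).

The working-myocardium cells of the right atrium (RA) are non-automatic: they
rest near -81 mV and fire a single action potential only when driven by a
stimulus or by an incoming wave.  The model is the standard human atrial
formulation with Hodgkin-Huxley gating (INa, Ito, IKur, IKr, IKs, ICaL, IK1),
Na/K and Na/Ca exchange, sarcolemmal Ca pump, background currents, and a
two-compartment sarcoplasmic reticulum (uptake + release).

An acetylcholine/adenosine-activated K+ current (IKACh) is added with the
algebraic dose-activation form used in human atrial modelling (Grandi-style):
it has no gating state and switches on with agonist concentration, shortening
the atrial action potential.

Units: time ms, voltage mV, currents pA/pF, concentrations mM.

All voltage-dependent gating rates are evaluated through a lookup table
(``build_tables``) shared by the single-cell driver and the tissue solver, so
an isolated cell and an uncoupled tissue node follow bit-identical
trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# physical constants
R_GAS = 8.3143
TEMP = 310.0
FARADAY = 96.4867
RTF = R_GAS * TEMP / FARADAY  # ~26.71 mV

# cell geometry (volumes in um^3)
CM = 100.0  # pF
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

# external concentrations (mM)
KO = 5.4
NAO = 140.0
CAO = 1.8

# maximal conductances (nS/pF) and transport rates
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.0294117649
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375
I_NAK_MAX = 0.59933874
KM_NAI = 10.0
KM_KO = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0
K_REL = 30.0
TAU_TR = 180.0
TAU_FCA = 2.0
TAU_U = 8.0
KQ10 = 3.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

# state vector layout (V is carried separately by the solver)
(M, H, J, OA, OI, UA, UI, XR, XS, D, F, FCA, U, VV, W,
 NAI, KI, CAI, CAUP, CAREL) = range(20)
N_STATES = 20

# lookup-table rows
(T_M_INF, T_M_RATE, T_H_INF, T_H_RATE, T_J_INF, T_J_RATE,
 T_OA_INF, T_OA_RATE, T_OI_INF, T_OI_RATE, T_UA_INF, T_UA_RATE,
 T_UI_INF, T_UI_RATE, T_XR_INF, T_XR_RATE, T_XS_INF, T_XS_RATE,
 T_D_INF, T_D_RATE, T_F_INF, T_F_RATE, T_W_INF, T_W_RATE,
 T_K1_RECT, T_KR_RECT, T_GKUR, T_FNAK, T_E_G, T_E_G1, T_KACH_V) = range(31)
N_TAB = 31

TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.02


def _safe_div(num, den):
    den = np.where(np.abs(den) < 1e-12, 1e-12 * np.sign(den + 1e-30), den)
    return num / den


def build_tables(ach_nm: float = 0.0) -> np.ndarray:
    """Tabulate every voltage-dependent quantity on a uniform V grid.

    ``ach_nm`` enters only through the ACh-activated K+ current; its
    dose-activation factor is folded into the tabulated voltage profile.
    """
    v = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    tab = np.zeros((N_TAB, v.size))

    # INa gates (Luo-Rudy style alpha/beta)
    e0 = v + 47.13
    a_m = np.where(np.abs(e0) < 1e-6, 3.2, _safe_div(0.32 * e0, 1.0 - np.exp(-0.1 * e0)))
    b_m = 0.08 * np.exp(-v / 11.0)
    tab[T_M_INF] = a_m / (a_m + b_m)
    tab[T_M_RATE] = a_m + b_m

    lo = v < -40.0
    a_h = np.where(lo, 0.135 * np.exp(-(v + 80.0) / 6.8), 0.0)
    b_h = np.where(lo, 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
                   1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    tab[T_H_INF] = a_h / (a_h + b_h)
    tab[T_H_RATE] = a_h + b_h

    a_j = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0)
    b_j = np.where(lo,
                   0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
                   0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))))
    tab[T_J_INF] = a_j / (a_j + b_j)
    tab[T_J_RATE] = a_j + b_j

    # Ito
    a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tab[T_OA_INF] = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))
    tab[T_OA_RATE] = (a_oa + b_oa) * KQ10
    a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    tab[T_OI_INF] = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))
    tab[T_OI_RATE] = (a_oi + b_oi) * KQ10

    # IKur
    a_ua = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tab[T_UA_INF] = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))
    tab[T_UA_RATE] = (a_ua + b_ua) * KQ10
    a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b_ui = np.exp((v - 158.0) / 16.0)
    tab[T_UI_INF] = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))
    tab[T_UI_RATE] = (a_ui + b_ui) * KQ10

    # IKr activation
    a_xr = _safe_div(0.0003 * (v + 14.1), 1.0 - np.exp(-(v + 14.1) / 5.0))
    b_xr = _safe_div(7.3898e-5 * (v - 3.3328), np.exp((v - 3.3328) / 5.1237) - 1.0)
    tab[T_XR_INF] = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))
    tab[T_XR_RATE] = a_xr + b_xr

    # IKs activation
    a_xs = _safe_div(4e-5 * (v - 19.9), 1.0 - np.exp(-(v - 19.9) / 17.0))
    b_xs = _safe_div(3.5e-5 * (v - 19.9), np.exp((v - 19.9) / 9.0) - 1.0)
    tab[T_XS_INF] = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))
    tab[T_XS_RATE] = 2.0 * (a_xs + b_xs)

    # ICaL gates
    tab[T_D_INF] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0))
    e = _safe_div(1.0 - np.exp(-(v + 10.0) / 6.24), 0.035 * (v + 10.0) * (1.0 + np.exp(-(v + 10.0) / 6.24)))
    tau_d = np.where(np.abs(v + 10.0) < 1e-6, 4.579 / (1.0 + np.exp(-(v + 10.0) / 6.24)), e)
    tab[T_D_RATE] = 1.0 / tau_d
    tab[T_F_INF] = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))
    tab[T_F_RATE] = (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02) / 9.0

    # SR release inactivation gate w
    tab[T_W_INF] = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))
    num = 6.0 * (1.0 - np.exp(-(v - 7.9) / 5.0))
    den = (1.0 + 0.3 * np.exp(-(v - 7.9) / 5.0)) * (v - 7.9) / 5.0
    tau_w = np.where(np.abs(v - 7.9) < 1e-6, 6.0 * 0.2 / 1.3, _safe_div(num, den))
    tab[T_W_RATE] = 1.0 / tau_w

    # rectifications and transporter voltage profiles
    tab[T_K1_RECT] = 1.0 / (1.0 + np.exp(0.07 * (v + 80.0)))
    tab[T_KR_RECT] = 1.0 / (1.0 + np.exp((v + 15.0) / 22.4))
    tab[T_GKUR] = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    sigma = (np.exp(NAO / 67.3) - 1.0) / 7.0
    tab[T_FNAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF) + 0.0365 * sigma * np.exp(-v / RTF))
    tab[T_E_G] = np.exp(GAMMA * v / RTF)
    tab[T_E_G1] = np.exp((GAMMA - 1.0) * v / RTF)

    # ACh-activated K+ current: dose activation x voltage profile
    ach_um = ach_nm * 1e-3
    act = 0.0 if ach_um <= 0.0 else 1.0 / (1.0 + (0.03 / ach_um) ** 2.1)
    tab[T_KACH_V] = act * (0.08 + 0.04 / (1.0 + np.exp((v + 91.0) / 12.0)))

    return np.ascontiguousarray(tab)


def initial_state() -> tuple[float, np.ndarray]:
    """Published resting state: (V, state vector)."""
    s = np.zeros(N_STATES)
    s[M] = 2.908e-3
    s[H] = 0.9649
    s[J] = 0.9775
    s[OA] = 3.043e-2
    s[OI] = 0.9992
    s[UA] = 4.966e-3
    s[UI] = 0.9986
    s[XR] = 3.296e-5
    s[XS] = 1.869e-2
    s[D] = 1.367e-4
    s[F] = 0.9996
    s[FCA] = 0.7755
    s[U] = 0.0
    s[VV] = 1.0
    s[W] = 0.9992
    s[NAI] = 11.17
    s[KI] = 139.0
    s[CAI] = 1.013e-4
    s[CAUP] = 1.488
    s[CAREL] = 1.488
    return -81.18, s


@njit(cache=True)
def ra_node_step(v, s, dt, tab, scale_na):
    """Advance one RA node by one forward-Euler step.

    Returns the ionic dV/dt (mV/ms) evaluated at the *pre-step* state; the
    caller combines it with diffusion and stimulus to update V.  Gating and
    concentration states are updated in place.
    """
    # table interpolation index
    u = (v - TAB_VMIN) / TAB_DV
    i = int(u)
    if i < 0:
        i = 0
    elif i > tab.shape[1] - 2:
        i = tab.shape[1] - 2
    fr = u - i

    def lk(row):
        a = tab[row, i]
        return a + fr * (tab[row, i + 1] - a)

    # floors keep Nernst/ratio terms defined if an unstable step drives a
    # concentration to zero; divergence is then caught by the |V| guard
    nai = max(s[NAI], 1e-9)
    ki = max(s[KI], 1e-9)
    cai = max(s[CAI], 1e-12)

    ena = RTF * np.log(NAO / nai)
    ek = RTF * np.log(KO / ki)
    eca = 0.5 * RTF * np.log(CAO / cai)

    ina = scale_na * G_NA * s[M] ** 3 * s[H] * s[J] * (v - ena)
    ik1 = G_K1 * (v - ek) * lk(T_K1_RECT)
    ito = G_TO * s[OA] ** 3 * s[OI] * (v - ek)
    ikur = lk(T_GKUR) * s[UA] ** 3 * s[UI] * (v - ek)
    ikr = G_KR * s[XR] * (v - ek) * lk(T_KR_RECT)
    iks = G_KS * s[XS] ** 2 * (v - ek)
    ical = G_CAL * s[D] * s[F] * s[FCA] * (v - 65.0)
    ikach = lk(T_KACH_V) * (v - ek)
    inak = I_NAK_MAX * lk(T_FNAK) * (KO / (KO + KM_KO)) / (1.0 + (KM_NAI / nai) ** 1.5)
    eg = lk(T_E_G)
    eg1 = lk(T_E_G1)
    inaca = I_NACA_MAX * (eg * nai ** 3 * CAO - eg1 * NAO ** 3 * cai) / (
        (KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * eg1))
    ibna = G_B_NA * (v - ena)
    ibca = G_B_CA * (v - eca)
    ipca = I_PCA_MAX * cai / (0.0005 + cai)

    itot = (ina + ik1 + ito + ikur + ikr + iks + ical + ikach
            + inak + inaca + ibna + ibca + ipca)

    # SR fluxes
    irel = K_REL * s[U] ** 2 * s[VV] * s[W] * (s[CAREL] - cai)
    iup = I_UP_MAX / (1.0 + K_UP / cai)
    iupleak = I_UP_MAX * s[CAUP] / CA_UP_MAX
    itr = (s[CAUP] - s[CAREL]) / TAU_TR

    # Ca-release control variable (Fn) and its gates
    fn = 1e-12 * V_REL * irel - (5e-13 / FARADAY) * (0.5 * ical - 0.2 * inaca) * CM
    u_inf = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))

    # gate updates
    s[M] += dt * (lk(T_M_INF) - s[M]) * lk(T_M_RATE)
    s[H] += dt * (lk(T_H_INF) - s[H]) * lk(T_H_RATE)
    s[J] += dt * (lk(T_J_INF) - s[J]) * lk(T_J_RATE)
    s[OA] += dt * (lk(T_OA_INF) - s[OA]) * lk(T_OA_RATE)
    s[OI] += dt * (lk(T_OI_INF) - s[OI]) * lk(T_OI_RATE)
    s[UA] += dt * (lk(T_UA_INF) - s[UA]) * lk(T_UA_RATE)
    s[UI] += dt * (lk(T_UI_INF) - s[UI]) * lk(T_UI_RATE)
    s[XR] += dt * (lk(T_XR_INF) - s[XR]) * lk(T_XR_RATE)
    s[XS] += dt * (lk(T_XS_INF) - s[XS]) * lk(T_XS_RATE)
    s[D] += dt * (lk(T_D_INF) - s[D]) * lk(T_D_RATE)
    s[F] += dt * (lk(T_F_INF) - s[F]) * lk(T_F_RATE)
    fca_inf = 1.0 / (1.0 + cai / 0.00035)
    s[FCA] += dt * (fca_inf - s[FCA]) / TAU_FCA
    s[U] += dt * (u_inf - s[U]) / TAU_U
    s[VV] += dt * (v_inf - s[VV]) / tau_v
    s[W] += dt * (lk(T_W_INF) - s[W]) * lk(T_W_RATE)

    # concentrations
    s[NAI] += dt * (-3.0 * inak - 3.0 * inaca - ibna - ina) * CM / (FARADAY * V_I)
    s[KI] += dt * (2.0 * inak - ik1 - ito - ikur - ikr - iks - ikach) * CM / (FARADAY * V_I)
    b1 = (2.0 * inaca - ipca - ical - ibca) * CM / (2.0 * FARADAY * V_I) \
        + (V_UP * (iupleak - iup) + irel * V_REL) / V_I
    b2 = 1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2 + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2
    s[CAI] += dt * b1 / b2
    s[CAUP] += dt * (iup - iupleak - itr * V_REL / V_UP)
    s[CAREL] += dt * (itr - irel) / (1.0 + CSQN_MAX * KM_CSQN / (s[CAREL] + KM_CSQN) ** 2)

    return -itot
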