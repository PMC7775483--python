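"""Numerical core: right-hand side and fixed-step integrator (numba).

The cell state is a flat 41-element vector (see ``STATE_NAMES``).  Gating
variables advance by Rush-Larsen exponential updates; concentrations,
Markov-state occupancies and phosphorylation fractions by forward Euler.
The step size is phase-dependent: 0.01 ms during the upstroke and whenever
junctional Ca2+ is elevated (active release), 0.02 ms for the rest of the
systole, 0.05 ms in diastole.  Trace samples are taken on an exact fixed
grid (default 0.5 ms) because the step size always lands on sample times.

The same jitted RHS serves single derivative evaluations (the public
``cell_derivatives``) and the integrator, so there is exactly one set of
model equations.

Sign conventions: membrane currents in pA/pF, inward negative.  The
stimulus and the square Ca2+ probe are rectangular; the stimulus charge is
carried by K+, the probe delivers Ca2+ to the junctional cleft with the
membrane potential clamped (it substitutes I_CaL as a calcium-delivery
device).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import PARAM_INDEX

F_CONST = 96485.0
R_CONST = 8314.0

STATE_NAMES = (
    "V", "m", "h", "j", "hL", "d", "f", "fCa", "a_to", "i_to",
    "a_kur", "i_kur", "ryr_R", "ryr_O", "ryr_I",
    "Na_i", "K_i", "Ca_i", "Ca_jn", "Ca_SR", "B_TnC", "B_jn",
    "phos_LTCC", "phos_PLB", "phos_RyR",
    "kjn_Pi", "kjn_Pb", "kjn_Pt", "kjn_Pt2", "kjn_Pa", "kjn_Pb2",
    "kjn_Pot", "kjn_Po",
    "kcyt_Pi", "kcyt_Pb", "kcyt_Pt", "kcyt_Pt2", "kcyt_Pa", "kcyt_Pb2",
    "kcyt_Pot", "kcyt_Po", "a_ss",
)
NSTATE = len(STATE_NAMES)
STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}

# gate states advanced by Rush-Larsen
GATE_IDX = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 41], dtype=np.int64)
NGATE = len(GATE_IDX)

AUX_NAMES = (
    "I_Na", "I_NaL", "I_CaL", "I_to", "I_Kur", "I_K1", "I_NCX", "I_NaK",
    "I_pCa", "I_Cab", "I_Nab", "J_rel", "J_up", "J_leak",
    "act_jn", "act_cyt", "jca_sl", "I_stim",
)
NAUX = len(AUX_NAMES)
AUX_INDEX = {n: i for i, n in enumerate(AUX_NAMES)}

REC_NAMES = (
    "t", "V", "Ca_i", "Ca_jn", "Ca_SR", "Na_i", "K_i", "act_jn",
    "phos_LTCC", "phos_PLB", "phos_RyR", "J_rel", "J_up", "I_NCX", "dVdt",
)
NREC = len(REC_NAMES)
REC_INDEX = {n: i for i, n in enumerate(REC_NAMES)}

STAT_NAMES = (
    "dvdt_max", "v_max", "v_min", "ca_i_max", "ca_i_min",
    "casr_max", "casr_min", "jrel_max", "act_jn_max", "act_jn_min",
    "sr_content_start", "sr_content_min", "ca_total_start", "ca_total_end",
    "ca_influx_integral",
)
NSTAT = len(STAT_NAMES)
STAT_INDEX = {n: i for i, n in enumerate(STAT_NAMES)}

_P = PARAM_INDEX  # shorthand used when building the jitted closures


def _pidx(*names):
    return tuple(PARAM_INDEX[n] for n in names)


# parameter indices, bound as compile-time constants for the jitted RHS
(_iCm, _ivcyto, _ivjnf, _ivsrf, _iNao, _iKo, _iCao, _iTemp) = _pidx(
    "Cm", "v_cyto", "v_jn_frac", "v_sr_frac", "Na_o", "K_o", "Ca_o", "temperature")
(_igNa, _igNaL, _ivhNaL, _ikNaL, _itauhL, _ishiftNaL) = _pidx(
    "g_Na", "g_NaL", "vh_NaL_inact", "k_NaL_inact", "tau_hL", "shift_NaL_inact")
(_igCaL, _iECaL, _iKmfCa, _itaufCa, _iltccg, _iltcctf, _iph0L) = _pidx(
    "g_CaL", "E_CaL", "Km_fCa", "tau_fCa", "ltcc_g_slope", "ltcc_tauf_slope",
    "phos0_LTCC")
(_igto, _iKfto, _iKbto, _igKur, _igK1, _igss, _igKb) = _pidx(
    "g_to", "K_f_to", "K_b_to", "g_Kur", "g_K1", "g_ss", "g_Kb")
(_ivNCX, _iKmNan, _iKmCan, _iksat, _ieta, _iKmact, _incxjn) = _pidx(
    "v_NCX", "Km_Na_ncx", "Km_Ca_ncx", "ksat_ncx", "eta_ncx", "Km_act_ncx",
    "ncx_jn_frac")
(_iibarNaK, _iKmNai, _iKmKo) = _pidx("ibar_NaK", "Km_Nai_nak", "Km_Ko_nak")
(_igNab, _igCab, _iibarpCa, _iKmpCa) = _pidx(
    "g_Nab", "g_Cab", "ibar_pCa", "Km_pCa")
(_ikoCa, _ikom, _ikiCa, _ikim, _iEC50, _ihSR, _iMaxSR, _iMinSR, _iks,
 _iryrslope, _iph0R, _ikob, _ibhill) = _pidx(
    "ko_Ca", "kom", "ki_Ca", "kim", "EC50_SR", "h_SR", "Max_SR", "Min_SR",
    "ks_rel", "ryr_phos_slope", "phos0_RyR", "ko_basal", "basal_hill")
(_ivup, _iKmupf, _iKmupr, _iplbslope, _iph0P, _ikleak) = _pidx(
    "v_up", "Km_up_f", "Km_up_r", "plb_km_slope", "phos0_PLB", "k_leak")
(_iBtnc, _ikontnc, _ikofftnc, _iBjn, _ikonjn, _ikoffjn, _iBcsqn, _iKmcsqn,
 _itaujn) = _pidx(
    "Btot_TnC", "kon_TnC", "koff_TnC", "Btot_jn", "kon_jn", "koff_jn",
    "Btot_csqn", "Km_csqn", "tau_jn_diff")
(_iCaMjn, _iCaMcyt, _iKdC, _iKdN) = _pidx(
    "CaM_tot_jn", "CaM_tot_cyt", "Kd_CaM_C", "Kd_CaM_N")
(_icktot, _ickcytf, _ikbi, _ikib, _ikib2, _ikb2i, _ikauto, _iktdis,
 _ikt2dis, _ipp1jn, _ipp1cyt, _ipp1kcat, _ipp1Km) = _pidx(
    "camkii_total", "camkii_cyt_frac", "k_bi", "k_ib", "k_ib2", "k_b2i",
    "k_auto", "k_t_dis", "k_t2_dis", "pp1_conc_jn", "pp1_conc_cyt",
    "pp1_kcat", "pp1_Km")
(_ikcamca,) = _pidx("k_cam_ca")
(_ikox, _iKmROS, _ikredox, _iKmMsrA, _iMsrA, _iros, _ioxts) = _pidx(
    "k_ox", "Km_ROS", "k_redox", "Km_MsrA", "MsrA_conc", "ros_conc",
    "ox_timescale")
(_ikfL, _ikbL, _iKmL, _ikfP, _ikbP, _iKmP, _ikfR, _ikbR, _iKmR) = _pidx(
    "kf_phos_LTCC", "kb_phos_LTCC", "Km_phos_LTCC",
    "kf_phos_PLB", "kb_phos_PLB", "Km_phos_PLB",
    "kf_phos_RyR", "kb_phos_RyR", "Km_phos_RyR")
(_istimamp, _istimdur) = _pidx("stim_amp", "stim_dur")


@njit(cache=True)
def _kinase_block(y, off, ca4cam, ca2cam, ros, p, total, pp1_conc, dy):
    """Derivatives of one 8-state kinase instance, fraction/ms."""
    Pi = y[off]
    Pb = y[off + 1]
    Pt = y[off + 2]
    Pt2 = y[off + 3]
    Pa = y[off + 4]
    Pb2 = y[off + 5]
    Pot = y[off + 6]
    Po = y[off + 7]
    ms = 1.0e-3  # chain rates are per second
    ox = p[_ikox] * ros / (ros + p[_iKmROS]) * ms * p[_ioxts] if ros > 0.0 else 0.0
    red = (p[_ikredox] * p[_iMsrA] / (p[_iMsrA] + p[_iKmMsrA]) * ms
           * p[_ioxts])
    T = Pb + Pt + Pt2 + Pa + Pot + Po

    f_pi_pb = p[_ikib] * ms * ca4cam * Pi
    f_pb_pi = p[_ikbi] * ms * Pb
    f_pi_pb2 = p[_ikib2] * ms * ca2cam * Pi
    f_pb2_pi = p[_ikb2i] * ms * Pb2
    # Ca loading state of the bound CaM follows the local free-CaM pools
    tot_cam = ca4cam + ca2cam
    fN = ca4cam / tot_cam if tot_cam > 0.0 else 0.0
    f_pb_pb2 = p[_ikcamca] * ms * (1.0 - fN) * Pb
    f_pb2_pb = p[_ikcamca] * ms * fN * Pb2
    f_pb_pt = p[_ikauto] * ms * T * Pb
    f_pt_pa = p[_iktdis] * ms * Pt
    f_pa_pt = p[_ikib] * ms * ca4cam * Pa
    f_pa_pt2 = p[_ikib2] * ms * ca2cam * Pa
    f_pt2_pa = p[_ikt2dis] * ms * Pt2
    sub = (Pa + Pt2) * total
    if sub > 0.0:
        v_tot = p[_ipp1kcat] * ms * pp1_conc * sub / (p[_ipp1Km] + sub)
        f_pa_pi = v_tot * (Pa / (Pa + Pt2)) / total
        f_pt2_pb2 = v_tot * (Pt2 / (Pa + Pt2)) / total
    else:
        f_pa_pi = 0.0
        f_pt2_pb2 = 0.0
    f_pb_pot = ox * Pb
    f_pot_pb = red * Pot
    f_pot_po = p[_ikbi] * ms * Pot
    f_po_pot = p[_ikib] * ms * ca4cam * Po
    f_po_pi = red * Po

    dy[off] = f_pb_pi + f_pb2_pi + f_po_pi + f_pa_pi - f_pi_pb - f_pi_pb2
    dy[off + 1] = (f_pi_pb + f_pot_pb + f_pb2_pb
                   - f_pb_pi - f_pb_pt - f_pb_pot - f_pb_pb2)
    dy[off + 2] = f_pb_pt + f_pa_pt - f_pt_pa
    dy[off + 3] = f_pa_pt2 - f_pt2_pa - f_pt2_pb2
    dy[off + 4] = f_pt_pa + f_pt2_pa - f_pa_pt - f_pa_pt2 - f_pa_pi
    dy[off + 5] = f_pi_pb2 + f_pt2_pb2 + f_pb_pb2 - f_pb2_pi - f_pb2_pb
    dy[off + 6] = f_pb_pot + f_po_pot - f_pot_pb - f_pot_po
    dy[off + 7] = f_pot_po - f_po_pot - f_po_pi
    return T


@njit(cache=True)
def rhs(y, p, i_stim, probe_amp, icals_on, dy, aux, ginf, gtau):
    """Model equations.  Fills dy (d/dt per ms), aux, and gate inf/tau."""
    V = y[0]
    m = y[1]
    h = y[2]
    jg = y[3]
    hL = y[4]
    d = y[5]
    f = y[6]
    fCa = y[7]
    a_to = y[8]
    i_to = y[9]
    a_kur = y[10]
    i_kur = y[11]
    R = y[12]
    O = y[13]
    I = y[14]
    Na_i = y[15]
    K_i = y[16]
    Ca_i = y[17]
    Ca_jn = y[18]
    Ca_SR = y[19]
    B_TnC = y[20]
    B_jn = y[21]
    pL = y[22]
    pP = y[23]
    pR = y[24]

    RTF = R_CONST * p[_iTemp] / F_CONST
    E_Na = RTF * np.log(p[_iNao] / Na_i)
    E_K = RTF * np.log(p[_iKo] / K_i)

    vjnf = p[_ivjnf]
    vsrf = p[_ivsrf]
    # pA/pF -> uM/ms (cytosolic basis), divalent and monovalent
    conv2 = p[_iCm] * 1.0e-9 / (2.0 * F_CONST * p[_ivcyto])
    conv1_mM = p[_iCm] * 1.0e-12 / (F_CONST * p[_ivcyto])  # -> mM/ms

    # --- gates ------------------------------------------------------------
    ginf[0] = 1.0 / (1.0 + np.exp(-(V + 45.0) / 6.5))
    gtau[0] = 0.04 + 0.12 * np.exp(-((V + 45.0) / 15.0) ** 2)
    hinf = 1.0 / (1.0 + np.exp((V + 76.1) / 6.07))
    ginf[1] = hinf
    gtau[1] = 0.25 + 6.0 / (1.0 + np.exp((V + 60.0) / 8.0))
    ginf[2] = hinf
    gtau[2] = 2.0 + 60.0 / (1.0 + np.exp((V + 60.0) / 6.0))
    ginf[3] = 1.0 / (1.0 + np.exp((V - (p[_ivhNaL] + p[_ishiftNaL])) / p[_ikNaL]))
    # inactivation much faster at depolarized potentials
    gtau[3] = 75.0 + (p[_itauhL] - 75.0) / (1.0 + np.exp((V + 70.0) / 6.0))
    ginf[4] = 1.0 / (1.0 + np.exp(-(V + 9.0) / 6.0))
    gtau[4] = 0.6 + 1.2 * np.exp(-((V + 15.0) / 25.0) ** 2)
    ginf[5] = 1.0 / (1.0 + np.exp((V + 30.0) / 7.0))
    tau_f = 10.0 + 30.0 * np.exp(-((V + 25.0) / 20.0) ** 2)
    gtau[5] = tau_f * (1.0 + p[_iltcctf] * (pL - p[_iph0L]))
    rat = Ca_jn / p[_iKmfCa]
    ginf[6] = 1.0 / (1.0 + rat * rat)
    gtau[6] = p[_itaufCa]
    ginf[7] = 1.0 / (1.0 + np.exp(-(V - 8.0) / 11.0))
    gtau[7] = 0.6 + 1.6 * np.exp(-((V + 20.0) / 35.0) ** 2)
    beta_ito = p[_iKfto] / (1.0 + np.exp(-(V + 28.0) / 6.0))
    alpha_ito = p[_iKbto] / (1.0 + np.exp((V + 48.0) / 6.0))
    ginf[8] = alpha_ito / (alpha_ito + beta_ito)
    gtau[8] = 1.0 / (alpha_ito + beta_ito)
    ginf[9] = 1.0 / (1.0 + np.exp(-(V + 5.0) / 12.0))
    gtau[9] = 2.0 + 8.0 * np.exp(-((V + 20.0) / 30.0) ** 2)
    ginf[10] = 0.25 + 0.75 / (1.0 + np.exp((V + 45.0) / 5.0))
    gtau[10] = 1200.0
    ginf[11] = 1.0 / (1.0 + np.exp(-(V + 15.0) / 11.0))
    gtau[11] = 40.0

    # --- membrane currents (pA/pF) ----------------------------------------
    I_Na = p[_igNa] * m * m * m * h * jg * (V - E_Na)
    mL = 1.0 / (1.0 + np.exp(-(V + 30.0) / 6.0))
    I_NaL = p[_igNaL] * mL * hL * (V - E_Na)
    gCaL_eff = p[_igCaL] * (1.0 + p[_iltccg] * (pL - p[_iph0L]))
    if gCaL_eff < 0.0:
        gCaL_eff = 0.0
    I_CaL = icals_on * gCaL_eff * d * f * fCa * (V - p[_iECaL])
    I_to = p[_igto] * a_to * i_to * (V - E_K)
    I_Kur = p[_igKur] * a_kur * i_kur * (V - E_K)
    I_ss = p[_igss] * y[41] * (V - E_K)
    I_Kb = p[_igKb] * (V - E_K)
    I_K1 = (p[_igK1] * (p[_iKo] / (p[_iKo] + 0.21)) * (V - E_K)
            / (1.0 + np.exp(0.0896 * (V - E_K))))

    # NCX, split between a bulk-facing and a junction-facing population
    Cao_mM = p[_iCao] * 1.0e-3
    KmCa_mM = p[_iKmCan] * 1.0e-3
    ef = np.exp(p[_ieta] * V / RTF)
    er = np.exp((p[_ieta] - 1.0) * V / RTF)
    den = ((p[_iKmNan] ** 3 + p[_iNao] ** 3) * (KmCa_mM + Cao_mM)
           * (1.0 + p[_iksat] * er))
    fjn = p[_incxjn]
    num_c = ef * Na_i ** 3 * Cao_mM - er * p[_iNao] ** 3 * (Ca_i * 1.0e-3)
    allo_c = 1.0 / (1.0 + (p[_iKmact] / Ca_i) ** 2)
    I_NCX_cyt = (1.0 - fjn) * p[_ivNCX] * allo_c * num_c / den
    num_j = ef * Na_i ** 3 * Cao_mM - er * p[_iNao] ** 3 * (Ca_jn * 1.0e-3)
    allo_j = 1.0 / (1.0 + (p[_iKmact] / Ca_jn) ** 2)
    I_NCX_jn = fjn * p[_ivNCX] * allo_j * num_j / den
    I_NCX = I_NCX_cyt + I_NCX_jn

    sigma = (np.exp(p[_iNao] / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                   + 0.0365 * sigma * np.exp(-V / RTF))
    I_NaK = (p[_iibarNaK] * f_nak
             * (p[_iKo] / (p[_iKo] + p[_iKmKo]))
             / (1.0 + (p[_iKmNai] / Na_i) ** 2))

    E_Ca = 0.5 * RTF * np.log(p[_iCao] / Ca_i)
    I_Cab = p[_igCab] * (V - E_Ca)
    I_Nab = p[_igNab] * (V - E_Na)
    I_pCa = p[_iibarpCa] * Ca_i * Ca_i / (Ca_i * Ca_i + p[_iKmpCa] * p[_iKmpCa])

    I_probe = -probe_amp  # inward Ca2+ current, magnitude probe_amp

    I_ion = (I_Na + I_NaL + I_CaL + I_to + I_Kur + I_K1 + I_ss + I_Kb + I_NCX + I_NaK
             + I_Cab + I_Nab + I_pCa + i_stim + I_probe)
    dy[0] = -I_ion

    # --- SR release (RyR, luminal-sensitized) ------------------------------
    ec50_eff = p[_iEC50] * np.exp(-p[_iryrslope] * (pR - p[_iph0R]))
    kCaSR = p[_iMaxSR] - (p[_iMaxSR] - p[_iMinSR]) / (
        1.0 + (ec50_eff / Ca_SR) ** p[_ihSR])
    koSRCa = p[_ikoCa] / kCaSR
    kiSRCa = p[_ikiCa]
    # luminal-overload basal opening: negligible at normal load, steeply
    # increasing once Ca_SR exceeds the (phosphorylation-lowered) midpoint
    open_basal = p[_ikob] * (Ca_SR / ec50_eff) ** p[_ibhill]
    # R -> O by cytosolic-side Ca (luminal-sensitized); O -> I by sustained
    # Ca (one-way adaptation); recovery I -> RI -> R.  The one-way O -> I
    # step makes sustained junctional Ca terminate release irreversibly on
    # the release time scale, so the pooled junction cannot latch into a
    # standing leak except under genuine luminal overload.
    RI = 1.0 - R - O - I
    open_ca = koSRCa * Ca_jn * Ca_jn
    open_rate = open_ca + open_basal  # basal path acts on rested channels only
    dy[12] = (p[_ikim] * RI - kiSRCa * Ca_jn * R
              - (open_rate * R - p[_ikom] * O))
    dy[13] = (open_rate * R - p[_ikom] * O
              - (kiSRCa * Ca_jn * O - p[_ikim] * I))
    dy[14] = (kiSRCa * Ca_jn * O - p[_ikim] * I
              - (p[_ikom] * I - open_ca * RI))
    J_rel_jn = p[_iks] * O * (Ca_SR - Ca_jn)  # uM/ms junctional basis
    J_rel = J_rel_jn * vjnf  # cytosolic basis (reported)

    # --- SERCA and leak -----------------------------------------------------
    km_fac = 1.0 + p[_iplbslope] * (p[_iph0P] - pP)
    if km_fac < 0.15:
        km_fac = 0.15
    Km_f = p[_iKmupf] * km_fac
    fw = (Ca_i / Km_f) ** 2
    rv = (Ca_SR / p[_iKmupr]) ** 2
    J_up = p[_ivup] * (fw - rv) / (1.0 + fw + rv)
    J_leak = p[_ikleak] * (Ca_SR - Ca_i)

    # --- buffers ------------------------------------------------------------
    dB_tnc = p[_ikontnc] * Ca_i * (p[_iBtnc] - B_TnC) - p[_ikofftnc] * B_TnC
    dB_jn = p[_ikonjn] * Ca_jn * (p[_iBjn] - B_jn) - p[_ikoffjn] * B_jn
    dy[20] = dB_tnc
    dy[21] = dB_jn

    # --- Ca compartments ----------------------------------------------------
    J_diff = (Ca_jn - Ca_i) / p[_itaujn]  # junctional basis
    dy[18] = (-(I_CaL + I_probe) * conv2 / vjnf + 2.0 * I_NCX_jn * conv2 / vjnf
              + J_rel_jn - J_diff - dB_jn)
    dy[17] = (-(I_Cab + I_pCa) * conv2 + 2.0 * I_NCX_cyt * conv2
              + J_diff * vjnf - J_up + J_leak - dB_tnc)
    beta_csqn = 1.0 / (1.0 + p[_iBcsqn] * p[_iKmcsqn]
                       / ((p[_iKmcsqn] + Ca_SR) * (p[_iKmcsqn] + Ca_SR)))
    dy[19] = beta_csqn * (J_up - J_leak - J_rel_jn * vjnf) / vsrf

    # --- Na+ / K+ -----------------------------------------------------------
    dy[15] = -(I_Na + I_NaL + I_Nab + 3.0 * I_NCX + 3.0 * I_NaK) * conv1_mM
    dy[16] = -(I_to + I_Kur + I_K1 + I_ss + I_Kb - 2.0 * I_NaK + i_stim) * conv1_mM

    # --- CaM pools and kinase compartments ----------------------------------
    cj2 = Ca_jn * Ca_jn
    fC = cj2 / (cj2 + p[_iKdC] * p[_iKdC])
    fN = cj2 / (cj2 + p[_iKdN] * p[_iKdN])
    ca4_jn = p[_iCaMjn] * fC * fN
    ca2_jn = p[_iCaMjn] * fC * (1.0 - fN)
    ci2 = Ca_i * Ca_i
    fCc = ci2 / (ci2 + p[_iKdC] * p[_iKdC])
    fNc = ci2 / (ci2 + p[_iKdN] * p[_iKdN])
    ca4_cyt = p[_iCaMcyt] * fCc * fNc
    ca2_cyt = p[_iCaMcyt] * fCc * (1.0 - fNc)

    cktot_jn = p[_icktot]
    cktot_cyt = p[_icktot] * p[_ickcytf]
    T_jn = _kinase_block(y, 25, ca4_jn, ca2_jn, p[_iros], p,
                         cktot_jn, p[_ipp1jn], dy)
    T_cyt = _kinase_block(y, 33, ca4_cyt, ca2_cyt, p[_iros], p,
                          cktot_cyt, p[_ipp1cyt], dy)
    act_jn = T_jn * cktot_jn
    act_cyt = T_cyt * cktot_cyt

    # --- phosphorylation of LTCC / PLB / RyR --------------------------------
    hx = act_jn * act_jn
    hL_drive = hx / (hx + p[_iKmL] * p[_iKmL])
    hP_drive = hx / (hx + p[_iKmP] * p[_iKmP])
    hR_drive = hx / (hx + p[_iKmR] * p[_iKmR])
    dy[22] = p[_ikfL] * hL_drive * (1.0 - pL) - p[_ikbL] * pL
    dy[23] = p[_ikfP] * hP_drive * (1.0 - pP) - p[_ikbP] * pP
    dy[24] = p[_ikfR] * hR_drive * (1.0 - pR) - p[_ikbR] * pR

    # gate dy entries (for callers that want a plain derivative)
    for gi in range(NGATE):
        si = GATE_IDX[gi]
        dy[si] = (ginf[gi] - y[si]) / gtau[gi]

    aux[0] = I_Na
    aux[1] = I_NaL
    aux[2] = I_CaL
    aux[3] = I_to
    aux[4] = I_Kur
    aux[5] = I_K1
    aux[6] = I_NCX
    aux[7] = I_NaK
    aux[8] = I_pCa
    aux[9] = I_Cab
    aux[10] = I_Nab
    aux[11] = J_rel
    aux[12] = J_up
    aux[13] = J_leak
    aux[14] = act_jn
    aux[15] = act_cyt
    # net sarcolemmal Ca influx, cytosolic basis (uM/ms)
    aux[16] = -(I_CaL + I_Cab + I_pCa - 2.0 * I_NCX + I_probe) * conv2
    aux[17] = i_stim


@njit(cache=True)
def total_calcium(y, p):
    """Total cell Ca2+ on the cytosolic-volume basis (uM)."""
    Ca_SR = y[19]
    csqn_bound = p[_iBcsqn] * Ca_SR / (p[_iKmcsqn] + Ca_SR)
    return (y[17] + y[20]
            + (y[18] + y[21]) * p[_ivjnf]
            + (Ca_SR + csqn_bound) * p[_ivsrf])


@njit(cache=True)
def sr_content(y, p):
    """Total SR Ca2+ (free + calsequestrin-bound), cytosolic basis (uM)."""
    Ca_SR = y[19]
    csqn_bound = p[_iBcsqn] * Ca_SR / (p[_iKmcsqn] + Ca_SR)
    return (Ca_SR + csqn_bound) * p[_ivsrf]


@njit(cache=True)
def integrate(y, p, duration, stim_times, stim_amp, stim_dur,
              probe_amp, probe_start, probe_dur, icals_on,
              clamp_idx, clamp_val, record_dt, rec):
    """Advance the state in place for ``duration`` ms.

    ``stim_times`` are stimulus onsets (ms, relative to segment start).
    ``rec`` is a preallocated (n, NREC) buffer sampled every ``record_dt``
    ms (row 0 at t=0); pass a (0, NREC) array to skip recording.
    Returns the stats vector (see STAT_NAMES).
    """
    dy = np.zeros(NSTATE)
    aux = np.zeros(NAUX)
    ginf = np.zeros(NGATE)
    gtau = np.zeros(NGATE)

    stats = np.zeros(NSTAT)
    stats[0] = -1.0e30
    stats[1] = -1.0e30
    stats[2] = 1.0e30
    stats[3] = -1.0e30
    stats[4] = 1.0e30
    stats[5] = -1.0e30
    stats[6] = 1.0e30
    stats[7] = -1.0e30
    stats[8] = -1.0e30
    stats[9] = 1.0e30
    sr0 = sr_content(y, p)
    stats[10] = sr0
    stats[11] = sr0
    stats[12] = total_calcium(y, p)
    stats[14] = 0.0

    nclamp = clamp_idx.shape[0]
    for c in range(nclamp):
        y[clamp_idx[c]] = clamp_val[c]

    nrec = rec.shape[0]
    irec = 0
    t = 0.0
    k_stim = 0
    n_stim = stim_times.shape[0]
    last_stim = -1.0e30

    while t < duration - 1.0e-9:
        # currently active stimulus?
        while k_stim < n_stim and stim_times[k_stim] <= t + 1.0e-12:
            last_stim = stim_times[k_stim]
            k_stim += 1
        stim_on = (t - last_stim) < stim_dur and (t - last_stim) >= -1.0e-12
        i_stim = stim_amp if stim_on else 0.0
        probe_on = (probe_dur > 0.0 and t >= probe_start - 1.0e-12
                    and t < probe_start + probe_dur - 1.0e-12)
        pr = probe_amp if probe_on else 0.0

        # step-size selection
        tsl = t - last_stim
        if (tsl >= 0.0 and tsl < 10.0) or y[18] > 2.0 or probe_on:
            dt = 0.01
        elif tsl >= 0.0 and tsl < 150.0:
            dt = 0.02
        else:
            dt = 0.05

        # do not step across events or sample times
        if k_stim < n_stim and stim_times[k_stim] - t < dt:
            dtl = stim_times[k_stim] - t
            if dtl > 1.0e-12:
                dt = dtl
        if stim_on and (last_stim + stim_dur) - t < dt:
            dtl = (last_stim + stim_dur) - t
            if dtl > 1.0e-12:
                dt = dtl
        if probe_dur > 0.0:
            if t < probe_start and probe_start - t < dt:
                dt = probe_start - t
            elif probe_on and (probe_start + probe_dur) - t < dt:
                dtl = (probe_start + probe_dur) - t
                if dtl > 1.0e-12:
                    dt = dtl
        if nrec > 0:
            t_next_rec = irec * record_dt
            if t_next_rec - t < dt and t_next_rec - t > 1.0e-12:
                dt = t_next_rec - t
        if duration - t < dt:
            dt = duration - t

        rhs(y, p, i_stim, pr, icals_on, dy, aux, ginf, gtau)

        # record on the fixed grid
        if nrec > 0 and irec < nrec and t >= irec * record_dt - 1.0e-9:
            rec[irec, 0] = t
            rec[irec, 1] = y[0]
            rec[irec, 2] = y[17]
            rec[irec, 3] = y[18]
            rec[irec, 4] = y[19]
            rec[irec, 5] = y[15]
            rec[irec, 6] = y[16]
            rec[irec, 7] = aux[14]
            rec[irec, 8] = y[22]
            rec[irec, 9] = y[23]
            rec[irec, 10] = y[24]
            rec[irec, 11] = aux[11]
            rec[irec, 12] = aux[12]
            rec[irec, 13] = aux[6]
            rec[irec, 14] = dy[0]
            irec += 1

        # stats
        if dy[0] > stats[0]:
            stats[0] = dy[0]
        if y[0] > stats[1]:
            stats[1] = y[0]
        if y[0] < stats[2]:
            stats[2] = y[0]
        if y[17] > stats[3]:
            stats[3] = y[17]
        if y[17] < stats[4]:
            stats[4] = y[17]
        if y[19] > stats[5]:
            stats[5] = y[19]
        if y[19] < stats[6]:
            stats[6] = y[19]
        if aux[11] > stats[7]:
            stats[7] = aux[11]
        if aux[14] > stats[8]:
            stats[8] = aux[14]
        if aux[14] < stats[9]:
            stats[9] = aux[14]
        stats[14] += aux[16] * dt

        # advance: Rush-Larsen gates, Euler elsewhere
        for gi in range(NGATE):
            si = GATE_IDX[gi]
            y[si] = ginf[gi] + (y[si] - ginf[gi]) * np.exp(-dt / gtau[gi])
        y[0] += dt * dy[0]
        for si in range(12, 41):
            y[si] += dt * dy[si]

        # floors (numerical safety, never binding in healthy runs)
        if y[17] < 1.0e-6:
            y[17] = 1.0e-6
        if y[18] < 1.0e-6:
            y[18] = 1.0e-6
        if y[19] < 1.0e-3:
            y[19] = 1.0e-3

        for c in range(nclamp):
            y[clamp_idx[c]] = clamp_val[c]

        t += dt
        src = sr_content(y, p)
        if src < stats[11]:
            stats[11] = src

    # final sample
    if nrec > 0 and irec < nrec:
        rhs(y, p, 0.0, 0.0, icals_on, dy, aux, ginf, gtau)
        rec[irec, 0] = t
        rec[irec, 1] = y[0]
        rec[irec, 2] = y[17]
        rec[irec, 3] = y[18]
        rec[irec, 4] = y[19]
        rec[irec, 5] = y[15]
        rec[irec, 6] = y[16]
        rec[irec, 7] = aux[14]
        rec[irec, 8] = y[22]
        rec[irec, 9] = y[23]
        rec[irec, 10] = y[24]
        rec[irec, 11] = aux[11]
        rec[irec, 12] = aux[12]
        rec[irec, 13] = aux[6]
        rec[irec, 14] = dy[0]

    stats[13] = total_calcium(y, p)
    return stats
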