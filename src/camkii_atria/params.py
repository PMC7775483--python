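"""Parameter registry for the mouse atrial myocyte model.

Every scalar model parameter has a name, a default and a unit.  Parameter
sets are plain ``dict[str, float]`` snapshots of the registry; the engine
consumes them as a flat numpy vector in registry order.  Remodeling recipes
(e.g. CaMKII overexpression) are expressed as small, auditable diffs of
these dicts.

Units convention: time ms, voltage mV, Ca in uM, Na/K in mM, currents
pA/pF, SR fluxes uM/ms (cytosolic-volume basis).  Kinase-chain rates are
stored per second (their native scale) and converted inside the engine.
"""

from __future__ import annotations

import json
from collections import OrderedDict

import numpy as np

# (name, default, unit, description)
_REGISTRY: list[tuple[str, float, str, str]] = [
    # --- geometry & milieu -------------------------------------------------
    ("Cm", 50.0, "pF", "membrane capacitance"),
    ("v_cyto", 1.0e-11, "L", "bulk cytosolic volume"),
    ("v_jn_frac", 2.0e-3, "-", "junctional volume / cytosolic volume"),
    ("v_sr_frac", 0.06, "-", "SR volume / cytosolic volume"),
    ("Na_o", 140.0, "mM", "extracellular Na+"),
    ("K_o", 5.4, "mM", "extracellular K+"),
    ("Ca_o", 1800.0, "uM", "extracellular Ca2+"),
    ("temperature", 310.0, "K", "absolute temperature"),
    # --- fast Na+ current --------------------------------------------------
    ("g_Na", 16.0, "mS/uF", "I_Na maximal conductance"),
    # --- late Na+ current --------------------------------------------------
    ("g_NaL", 1.05, "mS/uF", "I_NaL maximal conductance"),
    ("vh_NaL_inact", -91.0, "mV", "I_NaL steady-state inactivation midpoint"),
    ("k_NaL_inact", 6.1, "mV", "I_NaL inactivation slope"),
    ("tau_hL", 600.0, "ms", "I_NaL inactivation time constant"),
    ("shift_NaL_inact", 0.0, "mV", "shift of I_NaL inactivation midpoint (remodeling)"),
    # --- L-type Ca2+ current ----------------------------------------------
    ("g_CaL", 0.20, "mS/uF", "I_CaL maximal conductance"),
    ("E_CaL", 55.0, "mV", "I_CaL apparent reversal potential"),
    ("Km_fCa", 6.0, "uM", "Ca-dependent inactivation Km (junctional Ca)"),
    ("tau_fCa", 15.0, "ms", "Ca-dependent inactivation time constant"),
    ("ltcc_g_slope", 0.35, "-", "g_CaL gain per unit phos_LTCC above anchor"),
    ("ltcc_tauf_slope", 0.6, "-", "f-gate tau slow-down per unit phos_LTCC above anchor"),
    ("phos0_LTCC", 0.60, "-", "WT 1 Hz anchor for phos_LTCC modifiers"),
    # --- transient outward K+ ----------------------------------------------
    ("g_to", 0.25, "mS/uF", "I_to maximal conductance"),
    ("K_f_to", 0.025, "1/ms", "I_to closed/open -> inactivated transition rate"),
    ("K_b_to", 0.033, "1/ms", "I_to recovery-from-inactivation rate"),
    # --- ultrarapid K+ -----------------------------------------------------
    ("g_Kur", 0.10, "mS/uF", "I_Kur maximal conductance"),
    # --- inward rectifier --------------------------------------------------
    ("g_ss", 0.10, "mS/uF", "steady-state K+ current conductance"),
    ("g_Kb", 0.04, "mS/uF", "background (leak) K+ conductance"),
    ("g_K1", 0.18, "mS/uF", "I_K1 maximum conductance scale"),
    # --- NCX ---------------------------------------------------------------
    ("v_NCX", 3000.0, "pA/pF", "I_NCX maximum conductance scale"),
    ("Km_Na_ncx", 87.5, "mM", "NCX Na half-saturation"),
    ("Km_Ca_ncx", 1380.0, "uM", "NCX Ca half-saturation"),
    ("ksat_ncx", 0.27, "-", "NCX saturation factor at negative potentials"),
    ("eta_ncx", 0.35, "-", "NCX energy-barrier position"),
    ("Km_act_ncx", 0.15, "uM", "NCX allosteric Ca activation Km (cytosolic)"),
    ("ncx_jn_frac", 0.02, "-", "fraction of NCX sensing junctional Ca2+"),
    # --- Na/K pump ---------------------------------------------------------
    ("ibar_NaK", 2.648, "pA/pF", "I_NaK maximal current"),
    ("Km_Nai_nak", 12.0, "mM", "I_NaK intracellular Na half-saturation"),
    ("Km_Ko_nak", 1.5, "mM", "I_NaK extracellular K half-saturation"),
    # --- background / pump -------------------------------------------------
    ("g_Nab", 9.505e-3, "mS/uF", "background Na+ conductance"),
    ("g_Cab", 0.0001, "mS/uF", "background Ca2+ conductance"),
    ("ibar_pCa", 0.25, "pA/pF", "sarcolemmal Ca2+ pump maximal current"),
    ("Km_pCa", 0.5, "uM", "sarcolemmal Ca2+ pump Km"),
    # --- SR release (RyR) --------------------------------------------------
    ("ko_Ca", 8.0e-6, "1/(uM^2 ms)", "RyR opening rate constant"),
    ("kom", 0.05, "1/ms", "RyR closing rate"),
    ("ki_Ca", 1.0e-4, "1/(uM ms)", "RyR Ca-inactivation rate constant"),
    ("kim", 0.005, "1/ms", "RyR recovery from inactivation"),
    ("EC50_SR", 330.0, "uM", "luminal Ca sensor midpoint"),
    ("h_SR", 8.0, "-", "luminal Ca sensor Hill coefficient"),
    ("Max_SR", 16.0, "-", "luminal sensor upper plateau"),
    ("Min_SR", 1.0, "-", "luminal sensor lower plateau"),
    ("ks_rel", 60.0, "1/ms", "release flux scale (junctional basis)"),
    ("ryr_phos_slope", 2.0, "-", "log-scale luminal-sensitization per unit phos_RyR"),
    ("ko_basal", 2.0e-8, "1/ms", "basal RyR opening rate scale (luminal-overload driven)"),
    ("basal_hill", 8.0, "-", "Hill exponent of luminal overload on basal opening"),
    ("phos0_RyR", 0.30, "-", "WT 1 Hz anchor for phos_RyR modifiers"),
    # --- SERCA / leak ------------------------------------------------------
    ("v_up", 0.8, "uM/ms", "SERCA maximal uptake rate (cytosolic basis)"),
    ("Km_up_f", 0.30, "uM", "SERCA forward Km at the WT anchor"),
    ("Km_up_r", 2200.0, "uM", "SERCA reverse (luminal) Km"),
    ("plb_km_slope", 1.2, "-", "SERCA Km reduction per unit phos_PLB above anchor"),
    ("phos0_PLB", 0.085, "-", "WT 1 Hz anchor for phos_PLB modifiers"),
    ("k_leak", 8.0e-6, "1/ms", "SR leak rate constant"),
    # --- buffers -----------------------------------------------------------
    ("Btot_TnC", 140.0, "uM", "cytosolic troponin-C sites"),
    ("kon_TnC", 0.0327, "1/(uM ms)", "TnC on-rate"),
    ("koff_TnC", 0.0196, "1/ms", "TnC off-rate"),
    ("Btot_jn", 100.0, "uM", "junctional membrane buffer sites"),
    ("kon_jn", 0.05, "1/(uM ms)", "junctional buffer on-rate"),
    ("koff_jn", 0.65, "1/ms", "junctional buffer off-rate"),
    ("Btot_csqn", 2600.0, "uM", "calsequestrin sites (SR volume basis)"),
    ("Km_csqn", 630.0, "uM", "calsequestrin Kd"),
    ("tau_jn_diff", 0.15, "ms", "junction <-> cytosol Ca transfer time constant"),
    # --- calmodulin pools (equilibrium readout) ----------------------------
    ("CaM_tot_jn", 418.0, "uM", "junctional calmodulin"),
    ("CaM_tot_cyt", 24.0, "uM", "cytosolic calmodulin"),
    ("Kd_CaM_C", 2.0, "uM", "C-lobe Ca half-saturation"),
    ("Kd_CaM_N", 15.0, "uM", "N-lobe Ca half-saturation"),
    # --- CaMKII chain (rates in 1/s; see kinase module) --------------------
    ("camkii_total", 120.0, "uM", "total CaMKII (junctional pool concentration)"),
    ("camkii_cyt_frac", 1.0 / 120.0, "-", "cytosolic CaMKII as fraction of junctional"),
    ("k_bi", 2.2, "1/s", "Ca4CaM unbinding"),
    ("k_ib", 2.2 / 33.5e-3, "1/(uM s)", "Ca4CaM binding"),
    ("k_ib2", 0.10, "1/(uM s)", "Ca2CaM binding"),
    ("k_b2i", 2.2, "1/s", "Ca2CaM unbinding"),
    ("k_cam_ca", 30.0, "1/s", "Ca (de)loading rate of CaMKII-bound CaM (Pb<->Pb2)"),
    ("k_auto", 1.1, "1/s", "autophosphorylation scale"),
    ("k_t_dis", 2.0, "1/s", "trapped-CaM dissociation (Pt->Pa)"),
    ("k_t2_dis", 1.0, "1/s", "Pt2->Pa dissociation"),
    ("pp1_conc_jn", 0.6, "uM", "junctional PP1"),
    ("pp1_conc_cyt", 0.6, "uM", "cytosolic PP1"),
    ("pp1_kcat", 80.0, "1/s", "PP1 turnover"),
    ("pp1_Km", 12.0, "uM", "PP1 Michaelis constant"),
    # The oxidation rate constant is the dose-response table value read on the
    # cell model's millisecond time base (6.48e-6 / ms = 6.48e-3 / s); the MsrA
    # level is set so the effective reduction rate is half the oxidation rate,
    # keeping the dose-response half-maximum at Km_ROS.
    ("k_ox", 6.48e-3, "1/s", "CaMKII oxidation rate (cell-model scale)"),
    ("Km_ROS", 60.0, "uM", "oxidation Michaelis constant"),
    ("k_redox", 0.28, "1/s", "MsrA reduction rate"),
    ("Km_MsrA", 0.34, "mM", "MsrA Michaelis constant"),
    ("MsrA_conc", 7.0e-5, "mM", "MsrA concentration"),
    ("ros_conc", 0.0, "uM", "constant [ROS] seen by every kinase compartment"),
    ("ox_timescale", 1.0, "-", "oxidation/reduction rate multiplier (equilibration aid)"),
    # --- phosphorylation dynamics -----------------------------------------
    ("kf_phos_LTCC", 2.2225e-2, "1/ms", "LTCC phosphorylation rate scale"),
    ("kb_phos_LTCC", 3.0e-4, "1/ms", "LTCC dephosphorylation rate"),
    ("Km_phos_LTCC", 100.0, "uM", "active-CaMKII half-saturation for LTCC"),
    ("kf_phos_PLB", 8.4806e-4, "1/ms", "PLB phosphorylation rate scale"),
    ("kb_phos_PLB", 6.0e-5, "1/ms", "PLB dephosphorylation rate"),
    ("Km_phos_PLB", 200.0, "uM", "active-CaMKII half-saturation for PLB"),
    ("kf_phos_RyR", 1.4420e-4, "1/ms", "RyR phosphorylation rate scale"),
    ("kb_phos_RyR", 1.0e-4, "1/ms", "RyR dephosphorylation rate"),
    ("Km_phos_RyR", 6.5, "uM", "active-CaMKII half-saturation for RyR"),
    # --- stimulus ----------------------------------------------------------
    ("stim_amp", -30.0, "pA/pF", "stimulus amplitude (rectangular, K+-carried)"),
    ("stim_dur", 1.5, "ms", "stimulus duration"),
]

PARAM_NAMES: tuple[str, ...] = tuple(n for n, *_ in _REGISTRY)
PARAM_UNITS: dict[str, str] = {n: u for n, _, u, _ in _REGISTRY}
PARAM_DESCRIPTIONS: dict[str, str] = {n: d for n, _, _, d in _REGISTRY}
PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}


def baseline_params() -> "OrderedDict[str, float]":
    """Wild-type parameter set (fresh copy)."""
    return OrderedDict((n, float(v)) for n, v, *_ in _REGISTRY)


def params_vector(params: dict) -> np.ndarray:
    """Flatten a parameter dict to the engine's vector layout."""
    unknown = set(params) - set(PARAM_NAMES)
    if unknown:
        raise KeyError(f"unknown parameters: {sorted(unknown)}")
    missing = set(PARAM_NAMES) - set(params)
    if missing:
        raise KeyError(f"missing parameters: {sorted(missing)}")
    return np.array([params[n] for n in PARAM_NAMES], dtype=np.float64)


def diff_params(a: dict, b: dict) -> dict:
    """Entries changed between two parameter sets, as name -> (a, b)."""
    return {
        n: (a[n], b[n]) for n in PARAM_NAMES if a[n] != b[n]
    }


def dump_params(params: dict, path) -> None:
    """Write a parameter set as JSON with units metadata."""
    payload = {
        n: {"value": params[n], "unit": PARAM_UNITS[n]} for n in PARAM_NAMES
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_params(path) -> "OrderedDict[str, float]":
    with open(path) as fh:
        payload = json.load(fh)
    out = baseline_params()
    for n, entry in payload.items():
        if n not in PARAM_INDEX:
            raise KeyError(f"unknown parameter in file: {n}")
        out[n] = float(entry["value"] if isinstance(entry, dict) else entry)
    return out
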