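"""Electrophysiology core: resting stability, bookkeeping, coupling."""

import numpy as np
import pytest

from camkii_atria.cell import (calcium_conservation_audit, cell_derivatives,
                               initial_state, phosphorylation_derivatives,
                               phosphorylation_effects, run_segment)
from camkii_atria.engine import AUX_INDEX, STATE_INDEX
from camkii_atria.kinase import (KinaseDrive, KinaseParams, KinaseState,
                                 kinase_derivatives)
from camkii_atria.params import baseline_params, params_vector
from camkii_atria.remodeling import apply_overexpression, apply_ros
from camkii_atria._steady_states import STEADY_STATES


@pytest.fixture(scope="module")
def wt_pv():
    return params_vector(baseline_params())


def test_rest_is_a_fixed_point(wt_pv):
    """Unstimulated, the relaxed cell has a negligible voltage derivative."""
    y = STEADY_STATES["wt"].copy()
    run_segment(y, wt_pv, 5000.0, record_dt=0.0)  # relax post-beat transients
    dy, _ = cell_derivatives(y, 0.0, wt_pv)
    assert abs(dy[0]) < 1e-3


def test_resting_potential_stable_for_sixty_seconds(wt_pv):
    y = STEADY_STATES["wt"].copy()
    run_segment(y, wt_pv, 30000.0, record_dt=0.0)  # quiescent relaxation
    v0 = y[0]
    trace, _ = run_segment(y, wt_pv, 60000.0, record_dt=5.0)
    assert np.max(np.abs(trace["V"] - v0)) < 0.5


@pytest.mark.parametrize("variant", ["wt", "oe", "oe_ros"])
def test_calcium_bookkeeping_audit(variant):
    """Total cell Ca2+ change over a paced beat equals the integrated
    sarcolemmal Ca2+ flux to within 0.1%."""
    p = baseline_params()
    if variant.startswith("oe"):
        p = apply_overexpression(p)
    if variant.endswith("ros"):
        p = apply_ros(p, 200.0)
    y = STEADY_STATES[variant].copy()
    audit = calcium_conservation_audit(y, params_vector(p), duration=1000.0,
                                       stim_times=[20.0])
    assert audit["rel_error"] < 1e-3


def test_nan_state_raises_named_error(wt_pv):
    y = STEADY_STATES["wt"].copy()
    y[STATE_INDEX["Ca_i"]] = np.nan
    with pytest.raises(FloatingPointError):
        cell_derivatives(y, 0.0, wt_pv)


def test_engine_kinase_block_matches_reference_module(wt_pv):
    """The jitted junctional kinase block reproduces the reference kinase
    module's derivative field (same equations, two implementations)."""
    p = baseline_params()
    y = STEADY_STATES["wt"].copy()
    rng = np.random.default_rng(1)
    occ = rng.random(8)
    occ /= occ.sum()
    y[25:33] = occ
    dy, _ = cell_derivatives(y, 0.0, wt_pv)
    # reconstruct the drive the engine saw
    ca = y[STATE_INDEX["Ca_jn"]]
    fc = ca ** 2 / (ca ** 2 + p["Kd_CaM_C"] ** 2)
    fn = ca ** 2 / (ca ** 2 + p["Kd_CaM_N"] ** 2)
    drive = KinaseDrive(Ca4CaM_conc=p["CaM_tot_jn"] * fc * fn,
                        Ca2CaM_conc=p["CaM_tot_jn"] * fc * (1 - fn),
                        ROS_conc=p["ros_conc"])
    kp = KinaseParams(
        k_bi=p["k_bi"], k_ib=p["k_ib"], k_ox=p["k_ox"], Km_ROS=p["Km_ROS"],
        k_redox=p["k_redox"], Km_MsrA=p["Km_MsrA"], MsrA_conc=p["MsrA_conc"],
        camkii_total=p["camkii_total"], k_ib2=p["k_ib2"], k_b2i=p["k_b2i"],
        k_cam_ca=p["k_cam_ca"], k_auto=p["k_auto"], k_t_dis=p["k_t_dis"],
        k_t2_dis=p["k_t2_dis"])
    from camkii_atria.kinase import PP1Params
    kp = KinaseParams(**{**{f: getattr(kp, f) for f in (
        "k_bi", "k_ib", "k_ox", "Km_ROS", "k_redox", "Km_MsrA", "MsrA_conc",
        "camkii_total", "k_ib2", "k_b2i", "k_cam_ca", "k_auto", "k_t_dis",
        "k_t2_dis")},
        "pp1": PP1Params(conc=p["pp1_conc_jn"], k_cat=p["pp1_kcat"],
                         Km=p["pp1_Km"])})
    ref = kinase_derivatives(KinaseState.from_array(occ), drive, kp)
    # engine works per millisecond; reference per second
    assert np.allclose(dy[25:33], ref.as_array() * 1e-3, rtol=1e-10,
                       atol=1e-15)


def test_phosphorylation_decays_without_kinase(wt_pv):
    d = phosphorylation_derivatives(0.0, [0.5, 0.5, 0.5], wt_pv)
    assert np.all(d < 0)
    d0 = phosphorylation_derivatives(0.0, [0.0, 0.0, 0.0], wt_pv)
    assert np.allclose(d0, 0.0)


def test_phosphorylation_steady_state_monotone_in_kinase(wt_pv):
    """Steady-state fraction rises monotonically with active CaMKII."""
    p = baseline_params()
    for tgt in ("LTCC", "PLB", "RyR"):
        kf, kb, km = (p[f"kf_phos_{tgt}"], p[f"kb_phos_{tgt}"],
                      p[f"Km_phos_{tgt}"])
        prev = -1.0
        for a in np.linspace(0.0, 1000.0, 21):
            h = a * a / (a * a + km * km)
            pss = kf * h / (kf * h + kb)
            assert pss >= prev - 1e-12
            prev = pss


def test_phosphorylation_effects_anchored_identity(wt_pv):
    p = baseline_params()
    eff = phosphorylation_effects(
        [p["phos0_LTCC"], p["phos0_PLB"], p["phos0_RyR"]], wt_pv)
    for v in eff.values():
        assert v == pytest.approx(1.0)


def test_phosphorylation_effects_monotone_directions(wt_pv):
    p = baseline_params()
    lo = phosphorylation_effects([0.1, 0.05, 0.1], wt_pv)
    hi = phosphorylation_effects([0.9, 0.5, 0.8], wt_pv)
    assert hi["ltcc_conductance_scale"] > lo["ltcc_conductance_scale"]
    assert hi["serca_km_scale"] < lo["serca_km_scale"]  # higher affinity
    assert hi["ryr_luminal_ec50_scale"] < lo["ryr_luminal_ec50_scale"]


def test_raising_plb_phosphorylation_increases_uptake(wt_pv):
    """At fixed Ca2+, ten-fold PLB phosphorylation raises J_up."""
    y = STEADY_STATES["wt"].copy()
    p = baseline_params()
    y[STATE_INDEX["phos_PLB"]] = p["phos0_PLB"]
    _, aux_lo = cell_derivatives(y, 0.0, wt_pv)
    y[STATE_INDEX["phos_PLB"]] = min(1.0, 10 * p["phos0_PLB"])
    _, aux_hi = cell_derivatives(y, 0.0, wt_pv)
    assert aux_hi[AUX_INDEX["J_up"]] > aux_lo[AUX_INDEX["J_up"]]


def test_integration_is_deterministic(wt_pv):
    y1 = STEADY_STATES["wt"].copy()
    y2 = STEADY_STATES["wt"].copy()
    run_segment(y1, wt_pv, 2000.0, stim_times=[20.0, 1020.0], record_dt=0.0)
    run_segment(y2, wt_pv, 2000.0, stim_times=[20.0, 1020.0], record_dt=0.0)
    assert np.array_equal(y1, y2)


def test_overexpression_raises_phosphorylation_and_sodium():
    """Six-fold CaMKII raises steady phosphorylation of all three targets
    and intracellular Na+ (direction check)."""
    wt = STEADY_STATES["wt"]
    oe = STEADY_STATES["oe"]
    for idx in (STATE_INDEX["phos_LTCC"], STATE_INDEX["phos_PLB"],
                STATE_INDEX["phos_RyR"]):
        assert oe[idx] > wt[idx]
    assert oe[STATE_INDEX["Na_i"]] > wt[STATE_INDEX["Na_i"]]


def test_rate_adaptation_shortens_apd(wt_pv):
    """APD90 at 10 Hz is shorter than at 1 Hz (restitution direction)."""
    from camkii_atria.metrics import compute_beat_metrics

    def apd90(freq):
        y = STEADY_STATES["wt"].copy()
        period = 1000.0 / freq
        for _ in range(20):
            run_segment(y, wt_pv, period, stim_times=[20.0], record_dt=0.0)
        tr, _ = run_segment(y, wt_pv, period, stim_times=[20.0],
                            record_dt=0.5)
        return compute_beat_metrics(tr, 20.0).apd90

    assert apd90(10.0) < apd90(1.0)
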