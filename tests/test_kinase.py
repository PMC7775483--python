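"""CaMKII chain: conservation, reductions, closed forms, fitting."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from camkii_atria.kinase import (KinaseDrive, KinaseParams, KinaseState,
                                 active_fraction, fit_oxidation_params,
                                 kinase_derivatives, kinase_steady_state,
                                 two_state_oxidized_fraction, _rates_array)


def rand_state(rng):
    y = rng.random(8)
    return KinaseState.from_array(y / y.sum())


def test_shipped_rate_constants():
    p = KinaseParams()
    assert p.k_bi == 2.2
    assert p.k_ib == pytest.approx(2.2 / 33.5e-3)
    assert p.k_ox == 6.48e-6
    assert p.Km_ROS == 60.0
    assert p.Km_MsrA == 0.34
    assert p.k_redox == 0.28


def test_derivatives_sum_to_zero_on_random_states():
    """Closed chain: total occupancy is conserved by the derivative field."""
    rng = np.random.default_rng(7)
    p = KinaseParams()
    for _ in range(1000):
        s = rand_state(rng)
        d = kinase_derivatives(
            s, KinaseDrive(Ca4CaM_conc=float(10 ** rng.uniform(-3, 2)),
                           Ca2CaM_conc=float(10 ** rng.uniform(-3, 2)),
                           ROS_conc=float(10 ** rng.uniform(-1, 3))), p)
        assert abs(sum(d.as_array())) < 1e-10


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10 ** 9))
def test_active_fraction_is_complement_of_inactive(seed):
    rng = np.random.default_rng(seed)
    s = rand_state(rng)
    assert active_fraction(s) == pytest.approx(1.0 - s.Pi - s.Pb2, abs=1e-12)


def test_active_fraction_limits():
    assert active_fraction(KinaseState()) == 0.0          # all inactive
    assert active_fraction(KinaseState(Pi=0.0, Po=1.0)) == 1.0  # oxidized


def test_zero_drive_steady_state_is_fully_inactive():
    st_ = kinase_steady_state(KinaseDrive(), KinaseParams())
    assert st_.Pi == pytest.approx(1.0, abs=1e-9)


def test_oxidation_flux_half_saturates_at_km_ros():
    """With Pb = 1 and [ROS] = Km_ROS, influx into Pot is k_ox / 2."""
    p = KinaseParams()
    s = KinaseState(Pi=0.0, Pb=1.0)
    d = kinase_derivatives(s, KinaseDrive(ROS_conc=p.Km_ROS), p)
    assert d.Pot == pytest.approx(0.5 * p.k_ox, rel=1e-12)
    assert d.Pot == pytest.approx(3.24e-6, rel=1e-12)


def test_oxidation_flux_saturates_at_high_ros():
    p = KinaseParams()
    s = KinaseState(Pi=0.0, Pb=1.0)
    d = kinase_derivatives(s, KinaseDrive(ROS_conc=1e9), p)
    assert d.Pot == pytest.approx(p.k_ox, rel=1e-6)


def test_ros_zero_matches_oxidation_free_chain():
    """With no ROS and empty oxidized states, the 8-state model follows the
    6-state activation chain exactly (trajectories, not just derivatives)."""
    p = KinaseParams()
    p_no_ox = replace(p, k_ox=0.0)
    y0 = np.array([0.7, 0.1, 0.05, 0.05, 0.05, 0.05, 0.0, 0.0])
    drive = (0.5, 0.2, 0.0)

    def rhs(pp):
        return lambda t, y: _rates_array(y, *drive, pp)

    sol_a = solve_ivp(rhs(p), (0, 100.0), y0, rtol=1e-10, atol=1e-12)
    sol_b = solve_ivp(rhs(p_no_ox), (0, 100.0), y0, rtol=1e-10, atol=1e-12)
    assert np.allclose(sol_a.y[:, -1], sol_b.y[:, -1], atol=1e-8)
    assert sol_a.y[6:, -1].max() == 0.0  # oxidized states never populated


def test_occupancy_conserved_over_hundred_seconds():
    p = KinaseParams()
    y0 = np.zeros(8)
    y0[0] = 1.0
    sol = solve_ivp(lambda t, y: _rates_array(y, 0.3, 0.1, 200.0, p),
                    (0, 100.0), y0, rtol=1e-10, atol=1e-12)
    assert np.all(np.abs(sol.y.sum(axis=0) - 1.0) < 1e-8)


def test_two_state_balance_matches_integration():
    """Reduced Pb<->Pot subsystem equilibrium equals a/(a+b) closed form."""
    p = replace(KinaseParams(), k_auto=0.0, k_ib=0.0, k_bi=0.0, k_ib2=0.0,
                k_cam_ca=0.0)
    for ros in (10.0, 60.0, 300.0):
        y0 = np.array([0.0, 1.0, 0, 0, 0, 0, 0, 0])
        sol = solve_ivp(lambda t, y: _rates_array(y, 0.0, 0.0, ros, p),
                        (0, 5e7), y0, method="LSODA", rtol=1e-12, atol=1e-14)
        pot = sol.y[6, -1]
        pb = sol.y[1, -1]
        assert pot / (pot + pb) == pytest.approx(
            two_state_oxidized_fraction(ros, p), abs=1e-6)


def test_cam_binding_mirrors_between_pairs():
    """The Pot<->Po CaM pair uses exactly the Pi<->Pb binding rates: the
    forward/backward flux ratio is k_ib*[Ca4CaM]/k_bi for both pairs."""
    p = KinaseParams()
    cam = 0.37
    s = KinaseState(Pi=0.25, Pb=0.25, Pot=0.25, Po=0.25)
    d_ref = p.k_ib * cam / p.k_bi
    # fluxes read off the rate expressions
    f_pi_pb = p.k_ib * cam * s.Pi
    f_pb_pi = p.k_bi * s.Pb
    f_po_pot = p.k_ib * cam * s.Po
    f_pot_po = p.k_bi * s.Pot
    assert f_pi_pb / f_pb_pi == pytest.approx(d_ref)
    assert f_po_pot / f_pot_po == pytest.approx(d_ref)


@pytest.mark.parametrize("cam", [0.01, 0.1])
def test_steady_active_fraction_monotone_in_ros(cam):
    p = KinaseParams()
    vals = []
    for ros in (0.0, 10.0, 60.0, 200.0, 1000.0):
        s = kinase_steady_state(KinaseDrive(Ca4CaM_conc=cam, ROS_conc=ros),
                                p, tol=1e-9)
        vals.append(active_fraction(s))
    assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))


def test_steady_active_fraction_monotone_in_cam_drive():
    p = KinaseParams()
    vals = []
    for cam in (0.0, 0.003, 0.01, 0.05, 0.3):
        s = kinase_steady_state(KinaseDrive(Ca4CaM_conc=cam), p, tol=1e-9)
        vals.append(active_fraction(s))
    assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))


def test_fit_recovers_generating_parameters():
    """Noise-free self-consistency: the fit returns the generating
    (k_ox, Km_ROS) to better than 1% from a wrong starting point."""
    from camkii_atria.kinase import _dose_response

    p = KinaseParams()
    ros = np.array([0.0, 10.0, 30.0, 60.0, 120.0, 250.0, 500.0, 1000.0])
    table = np.column_stack([ros, _dose_response(ros, p, 0.01)])
    start = replace(p, k_ox=3e-6, Km_ROS=40.0)
    k_ox, km, resid, flags = fit_oxidation_params(table, start)
    assert k_ox == pytest.approx(p.k_ox, rel=0.01)
    assert km == pytest.approx(p.Km_ROS, rel=0.01)
    assert not flags


def test_fit_zero_activity_reports_boundary():
    table = [(0.0, 0.0), (100.0, 0.0), (500.0, 0.0)]
    k_ox, km, resid, flags = fit_oxidation_params(table, KinaseParams())
    assert k_ox == 0.0
    assert "k_ox_boundary" in flags


def test_fit_recovers_km_under_multiplicative_noise():
    """5% multiplicative noise, scenario-grade oxidation rate: the median
    relative error of the recovered Km stays below 25%."""
    from camkii_atria.kinase import _dose_response

    p = replace(KinaseParams(), k_ox=6.48e-3, MsrA_conc=3.934e-3)
    ros = np.array([0.0, 10.0, 30.0, 60.0, 120.0, 250.0, 500.0, 1000.0])
    clean = _dose_response(ros, p, 0.01)
    rng = np.random.default_rng(42)
    errs = []
    for _ in range(8):
        noisy = np.clip(clean * (1 + 0.05 * rng.standard_normal(len(ros))),
                        0, 1)
        _, km, _, _ = fit_oxidation_params(
            np.column_stack([ros, noisy]),
            replace(p, k_ox=3e-3, Km_ROS=40.0))
        errs.append(abs(km - p.Km_ROS) / p.Km_ROS)
    assert np.median(errs) < 0.25


def test_invalid_inputs_raise():
    p = KinaseParams()
    with pytest.raises(ValueError):
        KinaseDrive(Ca4CaM_conc=-1.0)
    with pytest.raises(ValueError):
        kinase_derivatives(KinaseState(Pi=-0.5, Pb=1.5), KinaseDrive(), p)
    with pytest.raises(ValueError):
        fit_oxidation_params([(60.0, 0.5), (60.0, 0.4), (60.0, 0.3)], p)
    with pytest.raises(ValueError):
        fit_oxidation_params([(0.0, 0.5)], p)
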