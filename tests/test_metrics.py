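"""Beat metrics, DAD detection and stability determinations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camkii_atria.engine import NREC, REC_INDEX
from camkii_atria.cell import Trace
from camkii_atria.metrics import (beat_series_stability_time,
                                  compute_beat_metrics, detect_dads,
                                  steady_state_check)


def make_trace(t, V, ca=None, dvdt=None, jrel=None):
    n = len(t)
    data = np.zeros((n, NREC))
    data[:, REC_INDEX["t"]] = t
    data[:, REC_INDEX["V"]] = V
    data[:, REC_INDEX["Ca_i"]] = 0.1 if ca is None else ca
    data[:, REC_INDEX["dVdt"]] = (np.gradient(V, t) if dvdt is None else dvdt)
    if jrel is not None:
        data[:, REC_INDEX["J_rel"]] = jrel
    return Trace(data)


def triangular_ap(rest=-80.0, peak=20.0, upstroke_ms=1.0, repol_ms=100.0,
                  stim=10.0, dt=0.5, total=500.0):
    """Piecewise-linear AP with analytically known APDs."""
    t = np.arange(0.0, total + 1e-9, dt)
    V = np.full_like(t, rest)
    rise = (t >= stim) & (t < stim + upstroke_ms)
    V[rise] = rest + (peak - rest) * (t[rise] - stim) / upstroke_ms
    fall = (t >= stim + upstroke_ms) & (t < stim + upstroke_ms + repol_ms)
    V[fall] = peak - (peak - rest) * (t[fall] - stim - upstroke_ms) / repol_ms
    return t, V


def test_triangular_ap_apds_match_closed_form():
    """For a linear repolarization ramp, APD_x = upstroke + x * repol
    (measured from the dV/dt-max instant at the upstroke)."""
    t, V = triangular_ap()
    m = compute_beat_metrics(make_trace(t, V), 10.0)
    assert m.ap_elicited
    # dV/dt max sits mid-upstroke (0.5 ms); levels are crossed on the ramp
    for frac, apd in ((0.25, m.apd25), (0.50, m.apd50), (0.90, m.apd90)):
        expected = 1.0 + frac * 100.0  # from upstroke start
        assert apd == pytest.approx(expected, abs=1.5)
    m.validate()  # APD ordering holds
    assert m.ap_amplitude == pytest.approx(100.0, abs=1.0)
    assert m.resting_potential == pytest.approx(-80.0)


def test_flat_trace_reports_no_ap():
    t = np.arange(0, 300.0, 0.5)
    V = np.full_like(t, -80.0)
    m = compute_beat_metrics(make_trace(t, V), 10.0)
    assert not m.ap_elicited
    assert np.isnan(m.apd90) and np.isnan(m.ap_amplitude)


def test_apds_insensitive_to_resampling():
    """Halving the sampling interval moves APDs by less than 1 ms."""
    t1, V1 = triangular_ap(dt=0.5)
    t2, V2 = triangular_ap(dt=0.25)
    m1 = compute_beat_metrics(make_trace(t1, V1), 10.0)
    m2 = compute_beat_metrics(make_trace(t2, V2), 10.0)
    for a, b in ((m1.apd25, m2.apd25), (m1.apd50, m2.apd50),
                 (m1.apd90, m2.apd90)):
        assert abs(a - b) < 1.0


def test_flat_diastole_has_no_dads():
    t = np.arange(0, 2000.0, 0.5)
    V = np.full_like(t, -78.0)
    assert detect_dads(make_trace(t, V), [20.0, 1020.0]) == []


@pytest.mark.parametrize("n_bumps", [1, 3])
def test_injected_bumps_detected_exactly(n_bumps):
    """Synthetic diastolic bumps above threshold are all detected, and
    sub-threshold bumps are not (precision = recall = 1)."""
    t = np.arange(0, 5000.0, 0.5)
    V = np.full_like(t, -78.0)
    stims = [20.0]
    true_times = []
    for k in range(n_bumps):
        c = 800.0 + 1200.0 * k
        sel = np.abs(t - c) < 50.0
        V[sel] += 12.0 * np.exp(-((t[sel] - c) / 15.0) ** 2)
        true_times.append(c)
    # one sub-threshold bump (3 mV < 5 mV threshold), must NOT be detected
    sel = np.abs(t - 4500.0) < 50.0
    V[sel] += 3.0 * np.exp(-((t[sel] - 4500.0) / 15.0) ** 2)
    events = detect_dads(make_trace(t, V), stims, dad_threshold_mv=5.0)
    assert len(events) == n_bumps
    for ev, c in zip(events, true_times):
        assert abs(ev.time_ms - c) < 40.0
        assert ev.peak_dv_mv == pytest.approx(12.0, abs=1.0)


def test_steady_state_check_strict_boundary():
    basal = np.array([10.0, 140.0, 0.1, 500.0])
    a = basal.copy()
    exactly_at = a + 1e-5 * basal  # difference exactly at tolerance
    just_below = a + 0.999e-5 * basal
    assert not steady_state_check(a, exactly_at, basal)
    assert steady_state_check(a, just_below, basal)
    assert steady_state_check(a, a, basal)


@settings(max_examples=200, deadline=None)
@given(st.integers(min_value=0, max_value=10 ** 9))
def test_steady_state_check_matches_direct_formula(seed):
    rng = np.random.default_rng(seed)
    basal = rng.uniform(0.01, 100.0, 4)
    a = basal * rng.uniform(0.5, 1.5, 4)
    b = a + basal * rng.uniform(-3e-5, 3e-5, 4)
    expected = bool(np.max(np.abs(b - a) / basal) < 1e-5)
    assert steady_state_check(a, b, basal) == expected


def test_steady_state_check_zero_basal_raises():
    with pytest.raises(ValueError):
        steady_state_check([1.0], [1.0], [0.0])


def test_stability_time_matches_independent_scan():
    """The returned stabilization time equals a brute-force re-scan of the
    stored per-beat series."""
    series = np.array([10.0, 6.0, 4.0, 3.0, 2.95, 2.94, 2.935, 2.934, 2.934])
    got = beat_series_stability_time(series, beat_period_s=1.0)
    # brute force: last k with |v_k - v_{k-1}|/v_{k-1} >= 1%, stable after
    viol = [k for k in range(1, len(series))
            if abs(series[k] - series[k - 1]) / abs(series[k - 1]) >= 0.01]
    # first stable beat (1-based) is the one after the last violating pair
    expected = float(max(viol) + 2) if viol else 2.0
    assert got == expected


def test_stability_time_none_when_never_stable():
    series = np.array([1.0, 2.0] * 20)  # sustained alternans
    assert beat_series_stability_time(series) is None


def test_stability_time_immediate_for_constant_series():
    assert beat_series_stability_time(np.full(50, 3.3)) == 2.0
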