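"""Per-beat action-potential and Ca2+-transient metrics, DAD detection,
steady-state and stability determinations.

Conventions (documented because the literature varies):

* APD_x is measured from the instant of maximal dV/dt to x%
  repolarization, where the repolarization level is referenced to the AP
  amplitude = peak V minus take-off potential (the take-off potential is
  read at the start of the upstroke, operationally the earliest sample
  whose dV/dt exceeds 5% of the upstroke maximum).
* A delayed afterdepolarization (DAD) is a diastolic depolarization that
  (i) starts outside any stimulus-evoked AP window, (ii) rises at least
  ``dad_threshold_mv`` (default 5 mV) above the post-repolarization
  baseline, and (iii) stays below 80% of the preceding AP amplitude
  (otherwise it is a triggered AP, not a DAD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeatMetrics", "DADEvent", "compute_beat_metrics", "detect_dads",
    "steady_state_check", "beat_series_stability_time",
]

STEADY_STATE_REL_TOL = 1e-5  # "one hundred-thousandth of the basal level"
STABILITY_REL_TOL = 0.01     # "<1% beat-to-beat variation"


@dataclass(frozen=True)
class DADEvent:
    time_ms: float
    peak_dv_mv: float
    cycle_index: int


@dataclass
class BeatMetrics:
    """Summary statistics of one paced beat (NaN = no AP elicited)."""

    apd25: float = float("nan")
    apd50: float = float("nan")
    apd90: float = float("nan")
    ap_amplitude: float = float("nan")
    dvdt_max: float = float("nan")
    resting_potential: float = float("nan")
    cat_amplitude: float = float("nan")
    diastolic_ca: float = float("nan")
    peak_jrel: float = float("nan")
    ap_elicited: bool = False
    dad_events: list = field(default_factory=list)

    def validate(self):
        if self.ap_elicited:
            if not (self.apd25 <= self.apd50 <= self.apd90):
                raise ValueError("APD ordering violated")


def compute_beat_metrics(trace, stim_time_ms: float,
                         min_amplitude_mv: float = 40.0) -> BeatMetrics:
    """Metrics for the beat whose stimulus is at ``stim_time_ms``.

    ``trace`` is a cell.Trace spanning (at least) one full cycle.  When the
    stimulus fails to elicit an AP (amplitude below ``min_amplitude_mv``)
    the AP fields are flagged absent (NaN, ``ap_elicited=False``) rather
    than reported as zero.
    """
    t = trace.t
    V = trace["V"]
    ca = trace["Ca_i"]
    if len(t) < 8:
        raise ValueError("trace too short")

    m = BeatMetrics()
    m.resting_potential = float(V.min())
    m.diastolic_ca = float(ca.min())
    m.cat_amplitude = float(ca.max() - ca.min())
    m.peak_jrel = float(trace["J_rel"].max())

    # window from stimulus to end for upstroke search
    sel = t >= stim_time_ms
    if not sel.any():
        raise ValueError("stimulus time outside trace")
    dvdt = trace["dVdt"]
    iup = int(np.argmax(np.where(sel, dvdt, -np.inf)))
    m.dvdt_max = float(dvdt[iup])
    # take-off: earliest sample of the upstroke reaching half the maximal
    # dV/dt (at finite sampling the argmax sits mid-upstroke, which would
    # overestimate the take-off potential)
    i0 = iup
    while i0 > 0 and dvdt[i0 - 1] >= 0.05 * m.dvdt_max:
        i0 -= 1
    takeoff = float(V[i0])
    ipk = iup + int(np.argmax(V[iup:]))
    peak = float(V[ipk])
    amp = peak - takeoff
    m.ap_amplitude = amp
    if amp < min_amplitude_mv:
        m.ap_amplitude = float("nan")
        m.dvdt_max = float("nan")
        return m
    m.ap_elicited = True
    for frac, name in ((0.25, "apd25"), (0.50, "apd50"), (0.90, "apd90")):
        level = peak - frac * amp
        below = np.where(V[ipk:] <= level)[0]
        setattr(m, name,
                float(t[ipk + below[0]] - t[iup]) if len(below) else float("nan"))
    return m


def detect_dads(trace, stim_times_ms, dad_threshold_mv: float = 5.0,
                ap_window_ms: float = 250.0,
                triggered_fraction: float = 0.8) -> list[DADEvent]:
    """Diastolic depolarization events outside stimulus-evoked AP windows.

    Events are timestamped at threshold crossing and attributed to the
    cardiac cycle (index of the preceding stimulus).  Depolarizations
    exceeding ``triggered_fraction`` of the preceding AP amplitude are
    classified as triggered APs and still reported (callers may filter on
    ``peak_dv_mv``).
    """
    t = np.asarray(trace.t)
    V = np.asarray(trace["V"])
    stim_times_ms = np.asarray(sorted(stim_times_ms), dtype=float)

    in_ap = np.zeros(len(t), dtype=bool)
    for s in stim_times_ms:
        in_ap |= (t >= s - 1.0) & (t < s + ap_window_ms)

    dia = ~in_ap
    if dia.sum() < 4:
        return []
    baseline = float(np.percentile(V[dia], 10))

    events: list[DADEvent] = []
    above = False
    i_start = None
    for i in range(len(t)):
        if not dia[i]:
            above = False
            continue
        if V[i] > baseline + dad_threshold_mv:
            if not above:
                above = True
                i_start = i
        else:
            if above and i_start is not None:
                seg = V[i_start:i]
                peak_dv = float(seg.max() - baseline)
                ts = float(t[i_start])
                k = int(np.searchsorted(stim_times_ms, ts) - 1)
                events.append(DADEvent(ts, peak_dv, k))
            above = False
    if above and i_start is not None:
        seg = V[i_start:]
        events.append(DADEvent(float(t[i_start]),
                               float(seg.max() - baseline),
                               int(np.searchsorted(stim_times_ms, t[i_start]) - 1)))
    return events


def steady_state_check(beat_k_ions, beat_k1_ions, basal_ions,
                       rel_tol: float = STEADY_STATE_REL_TOL) -> bool:
    """True iff max_i |c_i(k+1) - c_i(k)| / basal_i < rel_tol (strict)."""
    a = np.asarray(beat_k_ions, dtype=float)
    b = np.asarray(beat_k1_ions, dtype=float)
    basal = np.asarray(basal_ions, dtype=float)
    if a.shape != b.shape or a.shape != basal.shape:
        raise ValueError("ion vectors must have identical shape")
    if np.any(basal == 0):
        raise ValueError("basal ion level of zero is not allowed")
    return bool(np.max(np.abs(b - a) / np.abs(basal)) < rel_tol)


def beat_series_stability_time(values, beat_period_s: float = 1.0,
                               rel_tol: float = STABILITY_REL_TOL):
    """First time (s) at which consecutive-beat variation drops below rel_tol.

    ``values`` is a per-beat series (e.g. J_rel peaks).  Returns the time
    (1-based beat index x period) of the first beat whose variation from
    its predecessor is below ``rel_tol`` **and** stays below the tolerance
    for the rest of the series; returns None if never stable.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return None
    prev = np.abs(v[:-1])
    prev[prev == 0] = np.finfo(float).tiny
    ok = np.abs(np.diff(v)) / prev < rel_tol
    bad = np.where(~ok)[0]  # diff j compares beats j+1 and j+2 (1-based)
    if len(bad) == 0:
        return 2.0 * beat_period_s  # stable at the first comparison
    first_stable = bad[-1] + 3  # beat completing the first sub-tol variation
    if first_stable > len(v):
        return None
    return float(first_stable * beat_period_s)
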