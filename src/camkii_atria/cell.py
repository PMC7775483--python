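"""Single-cell mouse atrial electrophysiology with CaMKII signaling.

The cell couples a compact atrial action-potential / Ca2+-cycling model
(fast and late Na+ currents, L-type Ca2+ current, transient-outward,
ultrarapid and inward-rectifier K+ currents, NCX, Na/K pump, background
currents, a luminal-Ca-sensitized 4-state RyR, SERCA with phospholamban
regulation, two cytosolic Ca2+ compartments plus the SR) bidirectionally to
two CaMKII instances (junctional and bulk-cytosolic), each driven by its
local Ca-calmodulin pools.  Active CaMKII phosphorylates LTCC, PLB and RyR;
the phosphorylated fractions feed back on channel and pump parameters.

All phosphorylation modifiers are anchored to the wild-type 1 Hz operating
point: at the anchor fractions the modifiers are exactly the identity, so
the wild-type model is the unmodified baseline by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine
from .engine import (AUX_NAMES, NAUX, NGATE, NREC, NSTATE, REC_INDEX,
                     REC_NAMES, STAT_INDEX, STATE_INDEX, STATE_NAMES)
from .params import PARAM_INDEX, baseline_params, params_vector

__all__ = [
    "CellState", "Trace", "initial_state", "cell_derivatives",
    "run_segment", "phosphorylation_derivatives", "phosphorylation_effects",
    "calcium_conservation_audit",
]

ION_STATES = ("Na_i", "K_i", "Ca_i", "Ca_SR")  # tracked for steady-state tests


class CellState:
    """Named view over the flat state vector."""

    __slots__ = ("y",)

    def __init__(self, y: np.ndarray):
        if y.shape != (NSTATE,):
            raise ValueError(f"state vector must have length {NSTATE}")
        self.y = y

    def __getattr__(self, name):
        try:
            return self.y[STATE_INDEX[name]]
        except KeyError:
            raise AttributeError(name) from None

    def copy(self) -> "CellState":
        return CellState(self.y.copy())

    def validate(self) -> None:
        y = self.y
        for name in ("Na_i", "K_i", "Ca_i", "Ca_jn", "Ca_SR", "B_TnC", "B_jn"):
            if y[STATE_INDEX[name]] < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("phos_LTCC", "phos_PLB", "phos_RyR"):
            v = y[STATE_INDEX[name]]
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not np.all(np.isfinite(y)):
            raise ValueError("state contains non-finite entries")


@dataclass
class Trace:
    """Fixed-rate samples of a simulated segment (columns = REC_NAMES)."""

    data: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[:, REC_INDEX[name]]

    @property
    def t(self) -> np.ndarray:
        return self.data[:, 0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.data, columns=list(REC_NAMES))


def initial_state(params: dict | None = None) -> np.ndarray:
    """A physiologically sensible resting state (not yet a paced limit cycle)."""
    p = params or baseline_params()
    y = np.zeros(NSTATE)
    y[STATE_INDEX["V"]] = -75.0
    # gates at their resting steady state
    pv = params_vector(p)
    dy = np.zeros(NSTATE)
    aux = np.zeros(NAUX)
    ginf = np.zeros(NGATE)
    gtau = np.zeros(NGATE)
    y[STATE_INDEX["Na_i"]] = 12.0
    y[STATE_INDEX["K_i"]] = 143.0
    y[STATE_INDEX["Ca_i"]] = 0.10
    y[STATE_INDEX["Ca_jn"]] = 0.10
    y[STATE_INDEX["Ca_SR"]] = 500.0
    y[STATE_INDEX["ryr_R"]] = 1.0
    y[STATE_INDEX["B_TnC"]] = p["Btot_TnC"] * 0.1 / (0.1 + p["koff_TnC"] / p["kon_TnC"])
    y[STATE_INDEX["B_jn"]] = p["Btot_jn"] * 0.1 / (0.1 + p["koff_jn"] / p["kon_jn"])
    y[STATE_INDEX["phos_LTCC"]] = p["phos0_LTCC"]
    y[STATE_INDEX["phos_PLB"]] = p["phos0_PLB"]
    y[STATE_INDEX["phos_RyR"]] = p["phos0_RyR"]
    y[STATE_INDEX["kjn_Pi"]] = 1.0
    y[STATE_INDEX["kcyt_Pi"]] = 1.0
    engine.rhs(y, pv, 0.0, 0.0, 1.0, dy, aux, ginf, gtau)
    for gi, si in enumerate(engine.GATE_IDX):
        y[si] = ginf[gi]
    return y


def cell_derivatives(y: np.ndarray, t: float, pv: np.ndarray,
                     i_stim: float = 0.0, probe_amp: float = 0.0,
                     icals_on: float = 1.0):
    """Full derivative field plus auxiliary currents/fluxes.

    Returns ``(dy, aux)``; ``aux`` is indexed by ``engine.AUX_NAMES``.
    Raises on non-finite derivatives, naming the offending state.
    """
    dy = np.zeros(NSTATE)
    aux = np.zeros(NAUX)
    ginf = np.zeros(NGATE)
    gtau = np.zeros(NGATE)
    engine.rhs(np.asarray(y, dtype=float), pv, i_stim, probe_amp, icals_on,
               dy, aux, ginf, gtau)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.where(~np.isfinite(dy))[0]]
        raise FloatingPointError(f"non-finite derivative in {bad}")
    return dy, aux


_EMPTY_CLAMP_IDX = np.zeros(0, dtype=np.int64)
_EMPTY_CLAMP_VAL = np.zeros(0, dtype=np.float64)


def run_segment(y: np.ndarray, pv: np.ndarray, duration: float,
                stim_times=None, stim_amp: float | None = None,
                stim_dur: float | None = None,
                clamps: dict | None = None,
                probe_amp: float = 0.0, probe_start: float = 0.0,
                probe_dur: float = 0.0, icals_on: float = 1.0,
                record_dt: float = 0.5):
    """Integrate ``y`` in place for ``duration`` ms; return (Trace|None, stats).

    ``clamps`` maps state names to held values (derivative forced to zero).
    ``record_dt=0`` skips trace recording (stats are still collected).
    """
    if stim_times is None:
        stim_times = np.zeros(0)
    stim_times = np.asarray(stim_times, dtype=np.float64)
    if stim_amp is None:
        stim_amp = pv[PARAM_INDEX["stim_amp"]]
    if stim_dur is None:
        stim_dur = pv[PARAM_INDEX["stim_dur"]]
    if clamps:
        cidx = np.array([STATE_INDEX[k] for k in clamps], dtype=np.int64)
        cval = np.array([float(v) for v in clamps.values()], dtype=np.float64)
    else:
        cidx, cval = _EMPTY_CLAMP_IDX, _EMPTY_CLAMP_VAL
    if record_dt > 0:
        nrec = int(round(duration / record_dt)) + 1
        rec = np.zeros((nrec, NREC))
    else:
        rec = np.zeros((0, NREC))
    stats_vec = engine.integrate(
        y, pv, float(duration), stim_times, float(stim_amp), float(stim_dur),
        float(probe_amp), float(probe_start), float(probe_dur),
        float(icals_on), cidx, cval, float(record_dt), rec)
    stats = {n: float(stats_vec[i]) for n, i in STAT_INDEX.items()}
    trace = Trace(rec) if record_dt > 0 else None
    return trace, stats


def phosphorylation_derivatives(active_camkii: float, phos, pv: np.ndarray):
    """d/dt of (phos_LTCC, phos_PLB, phos_RyR) in 1/ms.

    Each target follows saturable kinase-driven phosphorylation (Hill
    coefficient 2 in active-CaMKII concentration, reflecting the multimeric
    kinase) minus first-order phosphatase-driven dephosphorylation.
    """
    if active_camkii < 0:
        raise ValueError("active CaMKII concentration must be >= 0")
    phos = np.asarray(phos, dtype=float)
    if np.any((phos < 0) | (phos > 1)):
        raise ValueError("phosphorylated fractions must lie in [0, 1]")
    a2 = active_camkii * active_camkii
    out = np.empty(3)
    for k, tgt in enumerate(("LTCC", "PLB", "RyR")):
        kf = pv[PARAM_INDEX[f"kf_phos_{tgt}"]]
        kb = pv[PARAM_INDEX[f"kb_phos_{tgt}"]]
        km = pv[PARAM_INDEX[f"Km_phos_{tgt}"]]
        h = a2 / (a2 + km * km)
        out[k] = kf * h * (1.0 - phos[k]) - kb * phos[k]
    return out


def phosphorylation_effects(phos, pv: np.ndarray) -> dict:
    """Channel/pump modifiers implied by the phosphorylated fractions.

    Anchored identity: at the WT 1 Hz anchor fractions every modifier is 1
    (or a 1x scale), so the unphosphorylated baseline never needs separate
    bookkeeping.  All modifiers are continuous and monotone in their
    fraction.
    """
    pL, pP, pR = (float(x) for x in phos)
    g_scale = max(0.0, 1.0 + pv[PARAM_INDEX["ltcc_g_slope"]]
                  * (pL - pv[PARAM_INDEX["phos0_LTCC"]]))
    tauf_scale = 1.0 + pv[PARAM_INDEX["ltcc_tauf_slope"]] \
        * (pL - pv[PARAM_INDEX["phos0_LTCC"]])
    km_fac = max(0.15, 1.0 + pv[PARAM_INDEX["plb_km_slope"]]
                 * (pv[PARAM_INDEX["phos0_PLB"]] - pP))
    ec50_scale = float(np.exp(-pv[PARAM_INDEX["ryr_phos_slope"]]
                              * (pR - pv[PARAM_INDEX["phos0_RyR"]])))
    return {
        "ltcc_conductance_scale": g_scale,
        "ltcc_inactivation_tau_scale": tauf_scale,
        "serca_km_scale": km_fac,
        "ryr_luminal_ec50_scale": ec50_scale,
    }


def calcium_conservation_audit(y: np.ndarray, pv: np.ndarray,
                               duration: float = 1000.0,
                               stim_times=None) -> dict:
    """Book-keeping audit over one (or more) beats.

    Integrates the cell and compares the change in total cell Ca2+
    (free + buffered + SR, volume-weighted, cytosolic basis) with the
    time-integral of the net sarcolemmal Ca2+ flux.  Returns the absolute
    and relative mismatch; the relative error is normalized by total Ca.
    """
    y = y.copy()
    _, stats = run_segment(y, pv, duration, stim_times=stim_times,
                           record_dt=0.0)
    d_total = stats["ca_total_end"] - stats["ca_total_start"]
    influx = stats["ca_influx_integral"]
    denom = max(abs(stats["ca_total_start"]), 1e-12)
    return {
        "delta_total_uM": d_total,
        "influx_integral_uM": influx,
        "abs_error_uM": abs(d_total - influx),
        "rel_error": abs(d_total - influx) / denom,
    }
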