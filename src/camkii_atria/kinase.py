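"""CaMKII signaling subsystem.

The kinase is modelled as a closed Markov chain over eight subunit states:

* six activation states — ``Pi`` (inactive), ``Pb`` (Ca4CaM-bound, active),
  ``Pt`` (autophosphorylated, CaM-trapped), ``Pt2`` (autophosphorylated,
  Ca2CaM-bound), ``Pa`` (autonomous, CaM-free), ``Pb2`` (Ca2CaM-bound,
  inactive) — following the classic monomer-level activation scheme;
* two oxidation states — ``Pot`` (oxidized, Ca4CaM-bound) and ``Po``
  (oxidized, CaM-free) — reachable only from ``Pb``: autophosphorylated
  subunits are assumed not to be oxidizable.

Oxidation follows Michaelis-Menten kinetics in [ROS]; the reverse reaction is
catalysed by methionine sulfoxide reductase (MsrA), again Michaelis-Menten.
The ``Pot``/``Po`` pair exchanges Ca4CaM with exactly the same binding
(``k_ib``) and unbinding (``k_bi``) rates as ``Pi``/``Pb``.

All rates are per second; Ca-CaM species in uM, MsrA in mM.  Occupancies are
fractions of total CaMKII, so ``sum(state) == 1`` is conserved exactly by the
derivative field (the chain is closed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "STATE_NAMES",
    "ACTIVE_STATES",
    "PP1Params",
    "KinaseParams",
    "KinaseState",
    "KinaseDrive",
    "kinase_derivatives",
    "active_fraction",
    "kinase_steady_state",
    "fit_oxidation_params",
    "two_state_oxidized_fraction",
]

STATE_NAMES = ("Pi", "Pb", "Pt", "Pt2", "Pa", "Pb2", "Pot", "Po")
ACTIVE_STATES = ("Pb", "Pt", "Pt2", "Pa", "Pot", "Po")

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class PP1Params:
    """Protein phosphatase 1 acting on the autophosphorylated states.

    Dephosphorylation is Michaelis-Menten in the *concentration* of
    phosphorylated substrate (``(Pa + Pt2) * camkii_total``), so a cell
    overexpressing CaMKII saturates a fixed phosphatase pool and keeps a
    larger autonomous fraction -- the phosphatase-saturation effect.
    """

    conc: float = 0.6  # uM
    k_cat: float = 6.0  # s^-1
    Km: float = 12.0  # uM


@dataclass(frozen=True)
class KinaseParams:
    """Rate constants of the 8-state CaMKII chain.

    The oxidation block defaults (``k_ox``, ``Km_ROS``, ``k_redox``,
    ``Km_MsrA``) are the shipped dose-response constants; ``k_bi``/``k_ib``
    are the canonical Ca4CaM unbinding/binding rates (Kd = 33.5 nM).
    ``MsrA_conc`` is a configuration parameter: only the saturated product
    ``k_redox * [MsrA] / ([MsrA] + Km_MsrA)`` ever enters the equations, and
    the default is chosen so that effective reduction rate equals k_ox/2,
    which places the half-maximum of the shipped dose-response curve at
    [ROS] = Km_ROS.
    """

    k_bi: float = 2.2  # s^-1, Ca4CaM unbinding (Pb->Pi, Pot->Po)
    k_ib: float = 2.2 / 33.5e-3  # uM^-1 s^-1, Ca4CaM binding
    k_ox: float = 6.48e-6  # s^-1, maximal oxidation rate of Pb
    Km_ROS: float = 60.0  # uM
    k_redox: float = 0.28  # s^-1, maximal MsrA reduction rate
    Km_MsrA: float = 0.34  # mM
    MsrA_conc: float = 3.934e-6  # mM; see class docstring
    camkii_total: float = 120.0  # uM (junctional pool of the WT cell)
    # inherited activation-chain transitions
    k_ib2: float = 0.10  # uM^-1 s^-1, Ca2CaM binding (Pi->Pb2, Pa->Pt2)
    k_b2i: float = 2.2  # s^-1, Ca2CaM unbinding (Pb2->Pi)
    k_cam_ca: float = 30.0  # s^-1, Ca (de)loading of bound CaM (Pb<->Pb2)
    k_auto: float = 1.0  # s^-1, Pb->Pt autophosphorylation scale (x active fraction)
    k_t_dis: float = 0.08  # s^-1, Pt->Pa trapped-CaM dissociation
    k_t2_dis: float = 1.0  # s^-1, Pt2->Pa Ca2CaM dissociation
    pp1: PP1Params = field(default_factory=PP1Params)

    def __post_init__(self) -> None:
        for name in (
            "k_bi", "k_ib", "k_ox", "Km_ROS", "k_redox", "Km_MsrA",
            "MsrA_conc", "camkii_total", "k_ib2", "k_b2i", "k_cam_ca",
            "k_auto", "k_t_dis", "k_t2_dis",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"KinaseParams.{name} must be >= 0")

    @property
    def reduction_rate(self) -> float:
        """Effective MsrA reduction rate k_redox*[MsrA]/([MsrA]+Km_MsrA), s^-1."""
        return self.k_redox * self.MsrA_conc / (self.MsrA_conc + self.Km_MsrA)


@dataclass(frozen=True)
class KinaseDrive:
    """Constant chemical environment seen by the chain."""

    Ca4CaM_conc: float = 0.0  # uM
    Ca2CaM_conc: float = 0.0  # uM
    ROS_conc: float = 0.0  # uM

    def __post_init__(self) -> None:
        if min(self.Ca4CaM_conc, self.Ca2CaM_conc, self.ROS_conc) < 0:
            raise ValueError("drive concentrations must be >= 0")
        if not all(np.isfinite([self.Ca4CaM_conc, self.Ca2CaM_conc, self.ROS_conc])):
            raise ValueError("drive concentrations must be finite")


@dataclass(frozen=True)
class KinaseState:
    """Occupancy fractions of the eight subunit states (sum to 1)."""

    Pi: float = 1.0
    Pb: float = 0.0
    Pt: float = 0.0
    Pt2: float = 0.0
    Pa: float = 0.0
    Pb2: float = 0.0
    Pot: float = 0.0
    Po: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "KinaseState":
        return cls(**{n: float(y[i]) for i, n in enumerate(_IDX)})

    def validate(self) -> None:
        y = self.as_array()
        if np.any(y < -1e-12):
            raise ValueError("occupancies must be >= 0")
        if abs(float(y.sum()) - 1.0) > 1e-6:
            raise ValueError("occupancies must sum to 1")


def _rates_array(
    y: np.ndarray, ca4cam: float, ca2cam: float, ros: float, p: KinaseParams
) -> np.ndarray:
    """Derivative of the occupancy vector (order = STATE_NAMES), s^-1."""
    Pi, Pb, Pt, Pt2, Pa, Pb2, Pot, Po = y
    ox = p.k_ox * ros / (ros + p.Km_ROS) if ros > 0 else 0.0
    red = p.reduction_rate
    T = Pb + Pt + Pt2 + Pa + Pot + Po  # active fraction, drives autophosphorylation

    # unidirectional fluxes (fraction / s)
    f_pi_pb = p.k_ib * ca4cam * Pi
    f_pb_pi = p.k_bi * Pb
    f_pi_pb2 = p.k_ib2 * ca2cam * Pi
    f_pb2_pi = p.k_b2i * Pb2
    tot_cam = ca4cam + ca2cam
    fN = ca4cam / tot_cam if tot_cam > 0 else 0.0
    f_pb_pb2 = p.k_cam_ca * (1.0 - fN) * Pb
    f_pb2_pb = p.k_cam_ca * fN * Pb2
    f_pb_pt = p.k_auto * T * Pb
    f_pt_pa = p.k_t_dis * Pt
    f_pa_pt = p.k_ib * ca4cam * Pa
    f_pa_pt2 = p.k_ib2 * ca2cam * Pa
    f_pt2_pa = p.k_t2_dis * Pt2
    # PP1, Michaelis-Menten in absolute substrate concentration
    sub = (Pa + Pt2) * p.camkii_total
    # oxidation block
    f_pb_pot = ox * Pb
    f_pot_pb = red * Pot
    f_pot_po = p.k_bi * Pot
    f_po_pot = p.k_ib * ca4cam * Po
    f_po_pi = red * Po

    # PP1 fluxes split between Pa->Pi and Pt2->Pb2 by substrate share
    if sub > 0:
        v_total = p.pp1.k_cat * p.pp1.conc * sub / (p.pp1.Km + sub)  # uM/s
        f_pa_pi = v_total * (Pa / (Pa + Pt2)) / p.camkii_total
        f_pt2_pb2 = v_total * (Pt2 / (Pa + Pt2)) / p.camkii_total
    else:
        f_pa_pi = 0.0
        f_pt2_pb2 = 0.0

    d = np.zeros(8)
    d[_IDX["Pi"]] = f_pb_pi + f_pb2_pi + f_po_pi + f_pa_pi - f_pi_pb - f_pi_pb2
    d[_IDX["Pb"]] = (f_pi_pb + f_pot_pb + f_pb2_pb
                     - f_pb_pi - f_pb_pt - f_pb_pot - f_pb_pb2)
    d[_IDX["Pt"]] = f_pb_pt + f_pa_pt - f_pt_pa
    d[_IDX["Pt2"]] = f_pa_pt2 - f_pt2_pa - f_pt2_pb2
    d[_IDX["Pa"]] = f_pt_pa + f_pt2_pa - f_pa_pt - f_pa_pt2 - f_pa_pi
    d[_IDX["Pb2"]] = f_pi_pb2 + f_pt2_pb2 + f_pb_pb2 - f_pb2_pi - f_pb2_pb
    d[_IDX["Pot"]] = f_pb_pot + f_po_pot - f_pot_pb - f_pot_po
    d[_IDX["Po"]] = f_pot_po - f_po_pot - f_po_pi
    return d


def kinase_derivatives(
    state: KinaseState, drive: KinaseDrive, params: KinaseParams
) -> KinaseState:
    """Time derivative of every occupancy, in fraction/s.

    The chain is closed, so the returned derivatives sum to zero exactly.
    """
    state.validate()
    y = state.as_array()
    d = _rates_array(y, drive.Ca4CaM_conc, drive.Ca2CaM_conc, drive.ROS_conc, params)
    return KinaseState.from_array(d)


def active_fraction(state: KinaseState) -> float:
    """Fraction of CaMKII in any catalytically active state.

    Active states: Pb, Pt, Pt2, Pa (activation chain) plus Pot and Po
    (oxidized subunits remain active even after Ca4CaM dissociates).
    Multiply by ``camkii_total`` for a concentration.
    """
    state.validate()
    return state.Pb + state.Pt + state.Pt2 + state.Pa + state.Pot + state.Po


def kinase_steady_state(
    drive: KinaseDrive,
    params: KinaseParams,
    tol: float = 1e-10,
    max_time: float = 1e9,
) -> KinaseState:
    """Steady state under a constant drive, by pseudo-time integration.

    Integrates from the fully inactive state (Pi = 1) with a stiff solver,
    doubling the horizon until the derivative field's max-norm drops below
    ``tol`` (per second).  Raises ``RuntimeError`` with diagnostics when the
    iteration budget is exhausted.
    """
    y = np.zeros(8)
    y[0] = 1.0
    args = (drive.Ca4CaM_conc, drive.Ca2CaM_conc, drive.ROS_conc, params)

    def rhs(t, yy):
        return _rates_array(yy, *args)

    horizon = 10.0
    while horizon <= max_time:
        sol = solve_ivp(rhs, (0.0, horizon), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"kinase steady-state integration failed: {sol.message}")
        y = sol.y[:, -1]
        y = np.clip(y, 0.0, None)
        y = y / y.sum()
        resid = float(np.max(np.abs(_rates_array(y, *args))))
        if resid < tol:
            return KinaseState.from_array(y)
        horizon *= 4.0
    raise RuntimeError(
        f"kinase steady state did not converge: residual "
        f"{float(np.max(np.abs(_rates_array(y, *args)))):.3e} /s after {max_time:.1e} s"
    )


def two_state_oxidized_fraction(ros: float, params: KinaseParams) -> float:
    """Closed-form Pb<->Pot balance: Pot/(Pb+Pot) = a/(a+b).

    ``a = k_ox*[ROS]/([ROS]+Km_ROS)``, ``b = k_redox*[MsrA]/([MsrA]+Km_MsrA)``.
    Independent oracle for the reduced two-state subsystem.
    """
    a = params.k_ox * ros / (ros + params.Km_ROS) if ros > 0 else 0.0
    b = params.reduction_rate
    if a + b == 0:
        return 0.0
    return a / (a + b)


_ASSAY_DRIVE = KinaseDrive(Ca4CaM_conc=0.01, Ca2CaM_conc=0.0, ROS_conc=0.0)


def _dose_response(ros_grid: np.ndarray, params: KinaseParams,
                   ca4cam: float) -> np.ndarray:
    """Steady-state active fraction vs [ROS] in the oxidation assay.

    The assay isolates oxidation from autophosphorylation (ATP-free), so the
    chain reduces to the linear subsystem {Pi, Pb, Pot, Po}, whose steady
    state is solved exactly.
    """
    c = params.k_ib * ca4cam
    u = params.k_bi
    b = params.reduction_rate
    out = np.empty(len(ros_grid))
    for i, r in enumerate(ros_grid):
        a = params.k_ox * r / (r + params.Km_ROS) if r > 0 else 0.0
        A = np.array([
            [-c, u, 0.0, b],
            [c, -(u + a), b, 0.0],
            [0.0, a, -(b + u), c],
            [0.0, 0.0, u, -(c + b)],
        ])
        M = np.vstack([A, np.ones(4)])
        rhs = np.zeros(5)
        rhs[-1] = 1.0
        y, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        out[i] = y[1] + y[2] + y[3]  # Pb + Pot + Po
    return out


def fit_oxidation_params(
    activity_table,
    params: KinaseParams,
    ca4cam_assay: float = _ASSAY_DRIVE.Ca4CaM_conc,
):
    """Fit (k_ox, Km_ROS) to a (ROS uM, normalized activity) dose-response table.

    The forward model is the steady-state active fraction of the full chain
    under the assay CaM drive; the fit is least-squares in (log k_ox,
    log Km_ROS).  Returns ``(k_ox, Km_ROS, residual_norm, flags)`` where
    ``flags`` contains ``"k_ox_boundary"`` when no oxidation signal is
    detectable (all-zero activities drive k_ox to its lower bound).
    """
    table = np.asarray(activity_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 3:
        raise ValueError("activity table must have >= 3 rows of (ROS, activity)")
    ros = table[:, 0]
    act = table[:, 1]
    if np.any((act < -1e-9) | (act > 1 + 1e-9)):
        raise ValueError("activities must lie in [0, 1]")
    if np.ptp(ros) == 0:
        raise ValueError("degenerate table: all rows share one ROS value")

    flags: list[str] = []
    if np.all(act < 1e-12):
        return 0.0, params.Km_ROS, 0.0, ["k_ox_boundary"]

    def resid(theta):
        p = replace(params, k_ox=float(np.exp(theta[0])),
                    Km_ROS=float(np.exp(theta[1])))
        return _dose_response(ros, p, ca4cam_assay) - act

    theta0 = np.log([max(params.k_ox, 1e-12), params.Km_ROS])
    fit = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    k_ox = float(np.exp(fit.x[0]))
    km = float(np.exp(fit.x[1]))
    if k_ox < 1e-10:
        flags.append("k_ox_boundary")
    return k_ox, km, float(np.linalg.norm(fit.fun)), flags
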