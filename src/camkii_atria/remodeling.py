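"""Scenario construction: wild-type, CaMKII-overexpression, and ROS variants.

The overexpression recipe changes exactly five parameters of the wild-type
set: total CaMKII x6, the late-Na inactivation midpoint +6.8 mV, the I_to
inactivation transition rate x5, the I_K1 maximum conductance x0.6 and the
NCX maximum conductance x1.3.  ROS is a constant concentration seen by every
kinase compartment; 0 disables oxidation exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

from .params import PARAM_NAMES, baseline_params, diff_params  # noqa: F401

__all__ = [
    "ScenarioConfig", "PacingSegment", "ClampSpec",
    "apply_overexpression", "apply_ros", "make_scenario", "PRESETS",
    "OVEREXPRESSION_FOLD", "PATHOLOGICAL_ROS_UM",
]

OVEREXPRESSION_FOLD = 6.0
PATHOLOGICAL_ROS_UM = 200.0

#: State names a clamp may target, with physiological bounds.
CLAMP_BOUNDS = {
    "Na_i": (2.0, 30.0),        # mM
    "Ca_SR": (50.0, 1500.0),    # uM
    "phos_LTCC": (0.0, 1.0),
    "phos_PLB": (0.0, 1.0),
    "phos_RyR": (0.0, 1.0),
    "V": (-120.0, 60.0),        # mV (threshold-probe protocol)
}


@dataclass(frozen=True)
class PacingSegment:
    """A stretch of constant-frequency pacing."""

    freq_hz: float
    duration_s: float

    def __post_init__(self):
        if self.freq_hz < 0 or self.duration_s <= 0:
            raise ValueError("invalid pacing segment")


@dataclass(frozen=True)
class ClampSpec:
    """Hold one state variable at a level (derivative forced to zero)."""

    target: str
    level: float
    t_start_ms: float = 0.0
    t_stop_ms: float = float("inf")

    def __post_init__(self):
        if self.target not in CLAMP_BOUNDS:
            raise ValueError(f"unknown clamp target {self.target!r}")
        lo, hi = CLAMP_BOUNDS[self.target]
        if not (lo <= self.level <= hi):
            raise ValueError(
                f"clamp level {self.level} for {self.target} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved simulation scenario."""

    variant: str = "WT"  # "WT" or "CaMKII-OE"
    ros_um: float = 0.0
    clamps: tuple = ()
    pacing: tuple = (PacingSegment(1.0, 300.0),)
    seed: int = 0
    record_dt_ms: float = 0.5
    name: str = "wt"

    def __post_init__(self):
        if self.variant not in ("WT", "CaMKII-OE"):
            raise ValueError("variant must be 'WT' or 'CaMKII-OE'")
        if self.ros_um < 0:
            raise ValueError("ros_um must be >= 0")

    def params(self) -> dict:
        """Materialize the parameter set for this scenario."""
        p = baseline_params()
        if self.variant == "CaMKII-OE":
            p = apply_overexpression(p)
        p = apply_ros(p, self.ros_um)
        return p

    def config_hash(self) -> str:
        payload = json.dumps({
            "variant": self.variant, "ros_um": self.ros_um,
            "clamps": [(c.target, c.level, c.t_start_ms, c.t_stop_ms)
                       for c in self.clamps],
            "pacing": [(s.freq_hz, s.duration_s) for s in self.pacing],
            "seed": self.seed, "record_dt_ms": self.record_dt_ms,
            "params": self.params(),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant, "ros_um": self.ros_um,
            "clamps": [vars(c) for c in self.clamps],
            "pacing": [vars(s) for s in self.pacing],
            "seed": self.seed, "record_dt_ms": self.record_dt_ms,
            "name": self.name,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        d = json.loads(text)
        d["clamps"] = tuple(ClampSpec(**c) for c in d.get("clamps", ()))
        d["pacing"] = tuple(PacingSegment(**s) for s in d.get("pacing", ()))
        return cls(**d)


def apply_overexpression(base_params: dict) -> dict:
    """Apply the CaMKII-overexpression recipe (exactly five changes).

    Refuses to run twice on the same set (the recipe is not idempotent and
    double remodeling would be silently wrong).
    """
    wt = baseline_params()
    changed = diff_params(wt, base_params)
    if "camkii_total" in changed:
        raise ValueError("parameter set already carries a camkii_total "
                         "modification; refusing to remodel twice")
    p = dict(base_params)
    p["camkii_total"] = p["camkii_total"] * OVEREXPRESSION_FOLD
    p["shift_NaL_inact"] = p["shift_NaL_inact"] + 6.8
    p["K_f_to"] = p["K_f_to"] * 5.0
    p["g_K1"] = p["g_K1"] * 0.6
    p["v_NCX"] = p["v_NCX"] * 1.3
    return p


def apply_ros(params: dict, ros_um: float) -> dict:
    """Set the constant [ROS] seen by every kinase compartment (uM)."""
    if ros_um < 0:
        raise ValueError("ros_um must be >= 0")
    p = dict(params)
    p["ros_conc"] = float(ros_um)
    return p


def make_scenario(name: str, **overrides) -> ScenarioConfig:
    """Named presets: wt, wt_ros, oe, oe_ros (ROS presets use 200 uM)."""
    presets = {
        "wt": dict(variant="WT", ros_um=0.0),
        "wt_ros": dict(variant="WT", ros_um=PATHOLOGICAL_ROS_UM),
        "oe": dict(variant="CaMKII-OE", ros_um=0.0),
        "oe_ros": dict(variant="CaMKII-OE", ros_um=PATHOLOGICAL_ROS_UM),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kw = dict(presets[name])
    kw["name"] = name
    kw.update(overrides)
    return ScenarioConfig(**kw)


PRESETS = ("wt", "wt_ros", "oe", "oe_ros")
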