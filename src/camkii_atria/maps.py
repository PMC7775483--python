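"""RyR stability maps over the ([Ca2+]_SR x phos_RyR) plane.

Two products:

* the activation-threshold map — minimal square 5-ms Ca2+ probe amplitude
  per grid cell, with the always-open regime marked where release occurs
  with zero probe;
* the first-beat release map — J_rel amplitude of the first paced beat
  after the SR clamp is released, the balance-region mask (amplitude >
  5 uM/ms) and the time to <1% beat-to-beat stability.

Both maps are deterministic: same configuration, same maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import (ALWAYS_OPEN, _conditioned_state, release_after_unclamp,
                        ryr_threshold_search)
from .remodeling import ScenarioConfig

__all__ = ["RyRMap", "build_threshold_map", "build_release_map",
           "default_grid", "BALANCE_JREL_UM_MS"]

BALANCE_JREL_UM_MS = 5.0


def default_grid(ca_step: float = 50.0, phos_step: float = 0.10):
    """Grid spanning 200-800 uM [Ca2+]_SR and 10-80% RyR phosphorylation."""
    ca = np.arange(200.0, 800.0 + 1e-9, ca_step)
    ph = np.arange(0.10, 0.80 + 1e-9, phos_step)
    return ca, ph


@dataclass
class RyRMap:
    """Grid results; arrays indexed [i_phos, i_ca]."""

    ca_sr_um: np.ndarray
    phos_ryr: np.ndarray
    threshold: np.ndarray | None = None      # pA/pF; inf = always open
    always_open: np.ndarray | None = None    # bool
    jrel_first: np.ndarray | None = None     # uM/ms
    in_balance: np.ndarray | None = None     # bool
    t_stab_s: np.ndarray | None = None       # s; nan = not stable in window
    failures: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.diff(self.ca_sr_um) <= 0) or np.any(np.diff(self.phos_ryr) <= 0):
            raise ValueError("grid axes must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        rows = []
        for j, ph in enumerate(self.phos_ryr):
            for i, ca in enumerate(self.ca_sr_um):
                rows.append({
                    "ca_sr_um": ca, "phos_ryr": ph,
                    "threshold_pApF": (None if self.threshold is None
                                       else self.threshold[j, i]),
                    "always_open": (None if self.always_open is None
                                    else bool(self.always_open[j, i])),
                    "jrel_first_uM_ms": (None if self.jrel_first is None
                                         else self.jrel_first[j, i]),
                    "in_balance": (None if self.in_balance is None
                                   else bool(self.in_balance[j, i])),
                    "t_stab_s": (None if self.t_stab_s is None
                                 else self.t_stab_s[j, i]),
                })
        return pd.DataFrame(rows)

    def balance_width_per_row(self):
        """Count of in-balance cells per phosphorylation level."""
        if self.in_balance is None:
            raise ValueError("release map not built")
        return self.in_balance.sum(axis=1)


def build_threshold_map(config: ScenarioConfig, ca_grid=None,
                        phos_grid=None) -> RyRMap:
    """Activation-threshold map; per-cell failures recorded, map returned."""
    if ca_grid is None or phos_grid is None:
        ca_grid, phos_grid = default_grid()
    ca_grid = np.asarray(ca_grid, dtype=float)
    phos_grid = np.asarray(phos_grid, dtype=float)
    thr = np.full((len(phos_grid), len(ca_grid)), np.nan)
    ao = np.zeros_like(thr, dtype=bool)
    m = RyRMap(ca_grid, phos_grid, threshold=thr, always_open=ao)
    for j, ph in enumerate(phos_grid):
        for i, ca in enumerate(ca_grid):
            try:
                t = ryr_threshold_search(config, float(ca), float(ph))
            except RuntimeError as exc:
                m.failures.append((float(ca), float(ph), str(exc)))
                continue
            thr[j, i] = t
            ao[j, i] = not np.isfinite(t)
    return m


def build_release_map(config: ScenarioConfig, ca_grid=None, phos_grid=None,
                      n_beats: int = 5) -> RyRMap:
    """First-beat release map with balance mask.

    ``n_beats`` controls how many post-unclamp beats are simulated per
    cell; the first beat determines the release amplitude and the series
    (if long enough) the stabilization time.  Use ``n_beats=200`` to
    reproduce the full stabilization analysis for selected cells.
    """
    if ca_grid is None or phos_grid is None:
        ca_grid, phos_grid = default_grid()
    ca_grid = np.asarray(ca_grid, dtype=float)
    phos_grid = np.asarray(phos_grid, dtype=float)
    shape = (len(phos_grid), len(ca_grid))
    jrel = np.full(shape, np.nan)
    bal = np.zeros(shape, dtype=bool)
    tst = np.full(shape, np.nan)
    m = RyRMap(ca_grid, phos_grid, jrel_first=jrel, in_balance=bal, t_stab_s=tst)
    for j, ph in enumerate(phos_grid):
        for i, ca in enumerate(ca_grid):
            try:
                res = release_after_unclamp(config, float(ca), float(ph),
                                            n_beats=n_beats)
            except Exception as exc:  # pragma: no cover - diagnostic path
                m.failures.append((float(ca), float(ph), str(exc)))
                continue
            jrel[j, i] = res.extras["first_beat_jrel"]
            bal[j, i] = jrel[j, i] > BALANCE_JREL_UM_MS
            ts = res.extras["time_to_stability_s"]
            tst[j, i] = np.nan if ts is None else ts
    return m
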