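"""Regression-fixture generator.

Produces short (5-beat) reference traces for the four scenario presets,
kinase-only steady-state tables at [ROS] in {0, 60, 200} uM, and the
preset parameter diffs.  Regenerating on unchanged code yields
byte-identical files; the test suite uses these to pin behavior.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cell import run_segment
from .kinase import (KinaseDrive, KinaseParams, active_fraction,
                     kinase_steady_state, two_state_oxidized_fraction)
from .params import baseline_params, diff_params, params_vector
from .remodeling import PRESETS, make_scenario
from ._steady_states import STEADY_STATES

__all__ = ["generate_fixtures", "kinase_reference_table"]


def kinase_reference_table(ros_levels=(0.0, 60.0, 200.0),
                           params: KinaseParams | None = None):
    """Steady-state occupancies and the two-state closed-form balance.

    Rows: (ros_um, active_fraction, oxidized_fraction, closed_form_balance).
    """
    p = params or KinaseParams()
    rows = []
    for ros in ros_levels:
        st = kinase_steady_state(KinaseDrive(Ca4CaM_conc=0.1, ROS_conc=ros), p)
        rows.append([ros, active_fraction(st), st.Pot + st.Po,
                     two_state_oxidized_fraction(ros, p)])
    return np.array(rows)


def generate_fixtures(outdir) -> list[Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in PRESETS:
        cfg = make_scenario(name)
        pv = params_vector(cfg.params())
        y = STEADY_STATES[name].copy()
        stims = np.arange(20.0, 5000.0, 1000.0)
        trace, _ = run_segment(y, pv, 5000.0, stim_times=stims, record_dt=1.0)
        path = out / f"trace_{name}.csv"
        trace.to_frame().to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    tab = kinase_reference_table()
    path = out / "kinase_steady_states.csv"
    np.savetxt(path, tab, delimiter=",", fmt="%.10g",
               header="ros_um,active_fraction,oxidized_fraction,two_state_balance",
               comments="")
    written.append(path)
    wt = baseline_params()
    for name in PRESETS:
        d = diff_params(wt, make_scenario(name).params())
        path = out / f"param_diff_{name}.csv"
        with open(path, "w") as fh:
            fh.write("name,wt,scenario\n")
            for k, (a, b) in sorted(d.items()):
                fh.write(f"{k},{a:.10g},{b:.10g}\n")
        written.append(path)
    return written
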