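"""Pace the wild-type and CaMKII-overexpressing cells to their 1 Hz limit
behavior and compare the quantities the signaling layer controls.

The overexpressing cell gains ~3 mM intracellular Na+ (late-Na window +
NCX remodeling), runs its junctional kinase at hundreds of uM activity in
diastole (phosphatase saturation), and pushes LTCC/PLB/RyR
phosphorylation toward saturation.
"""
from camkii_atria import make_scenario, pace_to_steady_state
from camkii_atria.engine import STATE_INDEX

for name in ("wt", "oe"):
    res = pace_to_steady_state(make_scenario(name), max_beats=120)
    y = res.state
    act = res.trace["act_jn"]
    beat = res.beats[0]
    print(f"[{name}]")
    print(f"  [Na+]i = {y[STATE_INDEX['Na_i']]:.2f} mM, "
          f"[Ca2+]SR (diastolic) = {res.trace['Ca_SR'].min():.0f} uM")
    print(f"  junctional CaMKII_act: diastolic {act.min():.0f} uM, "
          f"systolic {act.max():.0f} uM")
    print(f"  phosphorylation LTCC/PLB/RyR = "
          f"{y[STATE_INDEX['phos_LTCC']]:.2f}/"
          f"{y[STATE_INDEX['phos_PLB']]:.2f}/{y[STATE_INDEX['phos_RyR']]:.2f}")
    print(f"  APD25/50/90 = {beat.apd25:.0f}/{beat.apd50:.0f}/{beat.apd90:.0f} ms, "
          f"CaT amplitude {beat.cat_amplitude:.3f} uM")
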