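# camkii-atria

A single-cell mouse atrial myocyte simulator built around CaMKII
(Ca²⁺/calmodulin-dependent protein kinase II) signaling.  The package is
for cardiac electrophysiology modellers studying how CaMKII
*overexpression* and *oxidation* destabilize intracellular Ca²⁺ cycling in
atrial cells — the substrate of delayed afterdepolarizations (DADs) and
atrial fibrillation.

## The model in brief

CaMKII subunits occupy an 8-state Markov chain: the classic activation
states — inactive `Pi`, Ca₄CaM-bound `Pb`, autophosphorylated `Pt`/`Pt2`,
autonomous `Pa`, Ca₂CaM-bound `Pb2` — extended by an oxidation pair
`Pot`/`Po` reachable only from `Pb`:

```
d[Pot]/dt = +k_ox·[ROS]/([ROS]+Km_ROS)·Pb − k_redox·[MsrA]/([MsrA]+Km_MsrA)·Pot
            + k_ib·[Ca₄CaM]·Po − k_bi·Pot
```

with `k_bi = 2.2 s⁻¹`, `k_ib = 2.2/0.0335 µM⁻¹s⁻¹`, `Km_ROS = 60 µM`,
`Km_MsrA = 0.34 mM`, `k_redox = 0.28 s⁻¹`.  Oxidized subunits stay active
after CaM dissociates; autophosphorylated subunits cannot be oxidized.
Active CaMKII phosphorylates the L-type Ca²⁺ channel, phospholamban and
the ryanodine receptor (RyR); the phosphorylated fractions feed back on
channel gating, SERCA affinity and the RyR's luminal Ca²⁺ sensitivity.
The kinase lives inside a compact mouse atrial cell model (I_Na, I_NaL,
I_CaL, I_to, I_Kur, I_K1, I_ss, NCX, Na/K pump, a luminal-regulated
4-state RyR, SERCA, two cytosolic Ca²⁺ compartments plus SR).  The
CaMKII-overexpressing phenotype is a five-parameter recipe: CaMKII ×6,
I_NaL inactivation shifted +6.8 mV, I_to inactivation rate ×5, I_K1 ×0.6,
NCX ×1.3; oxidative stress is a constant 200 µM [ROS].

See `docs/methods.md` for the full model description and its limitations.

## Worked example

```python
from camkii_atria import make_scenario, pace_to_steady_state

wt = pace_to_steady_state(make_scenario("wt"), max_beats=120)
oe = pace_to_steady_state(make_scenario("oe"), max_beats=120)

print(f"[Na+]i      WT {wt.state[15]:.2f} mM   OE {oe.state[15]:.2f} mM")
print(f"CaMKII_act  OE diastolic {oe.trace['act_jn'].min():.0f} uM, "
      f"systolic {oe.trace['act_jn'].max():.0f} uM")
print(f"phos (LTCC/PLB/RyR)  WT {wt.state[22]:.2f}/{wt.state[23]:.2f}/{wt.state[24]:.2f}"
      f"   OE {oe.state[22]:.2f}/{oe.state[23]:.2f}/{oe.state[24]:.2f}")
```

prints

```
[Na+]i      WT 11.97 mM   OE 15.13 mM
CaMKII_act  OE diastolic 179 uM, systolic 668 uM
phos (LTCC/PLB/RyR)  WT 0.61/0.17/0.40   OE 0.98/0.89/0.59
```

— the overexpressing cell gains ~3 mM Na⁺, runs its junctional kinase at
hundreds of µM of activity through the whole cycle, and drives its
targets toward saturation.  More narrative walk-throughs live in
`examples/` (steady-state comparison, oxidation dose-response fitting,
burst pacing with DAD detection, RyR threshold mapping), and the same
protocols are scriptable from the shell:

```bash
camkii-atria run oe_ros --protocol burst --out out/
camkii-atria map threshold --ca-step 100 --phos-step 0.1 --out out/
```

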