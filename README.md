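# cryonet

Coupled modelling of cell cryo-dehydration and intracellular ice formation
(IIF) in a nucleated oocyte.

When a cell is cooled in a partly frozen cryoprotectant solution, external
ice concentrates the bath, osmotic water efflux shrinks the cell, and a
water/CPA concentration gradient builds from the nucleus out to the
membrane as the cytoplasm approaches a glassy state.  If ice is triggered
at one point on the membrane (the exogenous-IIF hypothesis), it spreads
inward — and cryomicroscopy shows it filling the nucleus before the rest
of the cytoplasm.  `cryonet` is a research tool for studying that spatial
pattern: which parts of the cell ice first, and whether water content or
regional diffusivity controls the order.

Two coupled components:

* **Transport** — an axisymmetric moving-boundary finite-volume model of
  water/glycerol/salt diffusion in a porous cytoplasm and nucleus
  (free-volume theory for the glycerol–water mutual diffusivity
  `D_W = D0·exp(-dE/RT)·exp(-(w_w V*_w + w_g ξ V*_g)/V_FH)`, regional
  modification factors, nuclear-envelope film conductance, Arrhenius
  membrane permeability `L_p(T)` with efflux
  `J_w = L_p RT/ν_w (ln a_w^in − ln a_w^ext)`).
* **IIF network** — nine labelled nodes (A, F, I at the membrane; B, E, H
  in the cytoplasm near the nuclear envelope; C, D, G in the nucleus)
  running diffusion-limited nucleation and crystal growth
  (`J = Ω (c_w ν_w) exp(-κ'/(T³ΔT²))`, `dr²/dt = 2αD_eff S`) on locally
  sampled compositions, with heterogeneous nucleation area entering
  exogenously at node A and spreading between neighbours as
  `Ae(i→j) = Ae_sal (X_i^M + C) e^{-r_ij/d}`.

The default parameter registry reproduces the reference oocyte parameter tables
(geometry, free-volume constants, regional porosities and diffusion
factors, membrane and nucleation coefficients).  See `docs/methods.md`
for the model description, numerical choices and limitations.

## Worked example

```python
from cryonet.driver import experiment_network_trigger, run

cfg = experiment_network_trigger(resolution=20)   # 4.8 mol/L, 0.02 K/s
res = run(cfg)

for lab, T in res.events["first_ice"].items():
    print(f"{lab}: first ice at {T - 273.15:.2f} C")
print({k: round(v - 273.15, 2) for k, v in res.events["crossings"].items()})
```

Output (temperatures in °C):

```
A: first ice at -25.94 C      F: first ice at -29.95 C
B: first ice at -29.34 C      G: first ice at -34.18 C
C: first ice at -31.47 C      H: first ice at -36.93 C
D: first ice at -32.90 C      I: first ice at -45.70 C
E: first ice at -31.86 C
{'C_over_F': -34.71, 'D_over_E': -36.19}
```

Reading: ice starts at the trigger node A, reaches its membrane
neighbours B and F, then races through the nucleus (C → D → G) before the
far cytoplasm (H), with the far membrane node I last.  Although the
membrane nodes ice *earlier*, the nucleus nodes grow *faster* (higher
free-water porosity and diffusion factor), so node C's ice volume
overtakes node F's at −34.7 °C and node D overtakes node E at −36.2 °C —
the nucleus fills with ice before the cytoplasm does.

Other built-in protocols (`cryonet experiment <name>` on the command
line, or `cryonet.driver.experiment_suite`):

* `gradient_vs_T` — dehydration-only run showing the centre-high water
  fraction and its growth/saturation with falling temperature;
* `nucleus_vs_ideal` — nucleated cell vs the homogeneous "ideal solution"
  cell (the nucleated cell holds the higher water distribution);
* `node_C_vs_CS` — equal nucleation area to all nodes; node C against a
  duplicate CS with the cytoplasm diffusion factor (C grows ice far
  faster — regional diffusivity, not water content, dominates);
* `equal_fD` — the triggered run with the nucleus diffusion factor forced
  to the cytoplasm value (the nucleus-first pattern disappears).

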