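# Methods

`cryonet` simulates a single oocyte cooled at a constant rate in a
glycerol/NaCl solution that is in equilibrium with external ice, and asks
where and in what order intracellular ice forms.  Two coupled models run
together: an axisymmetric porous-media transport model of water, glycerol
and salt inside the shrinking cell, and a nine-node network model of
intracellular ice formation (IIF) in which heterogeneous nucleation area
enters at one membrane point (the exogenous-trigger hypothesis) and spreads
node-to-node as ice grows.

## Cell model and transport

The cell is an ellipsoid of revolution (semi-axes 41.2 x 39 um) containing
an off-centre ellipsoidal nucleus (15.15 x 12.99 um, displaced 8 um along
the symmetry axis) bounded by a 0.1 um nuclear envelope.  Because the
displacement is smaller than the nuclear semi-axis, the nucleus contains
the cell centre; every ray from the centre crosses nucleus first and
cytoplasm second, and the mesh is built as radial layers along such rays.
Cytoplasm layers are geometrically graded (ratio 1.4) toward the membrane:
osmotic efflux keeps a very thin boundary film near the external liquidus
while the interior lags, and that film — a steep front in the nonlinear,
concentration-dependent diffusivity — must stay resolved for the
dehydration rate to be mesh-independent.  With grading, node activation
temperatures at 16x16 and 24x24 agree to about 0.1 K.

Each region is a porous medium: the pore (free-water) fraction is the
porosity (0.45 cytoplasm, 0.85 nucleus) and bulk diffusivity is reduced by
a gross diffusion modification factor (0.3 cytoplasm, 0.78 nucleus, 0.078
envelope region).  Each mesh cell carries conserved amounts — moles of
water, glycerol, salt, plus inactive and ice volumes — so every
concentration is derived and the water ledger (remaining + ice-bound +
effluxed = initial) closes to machine precision; the test suite asserts
1e-6 relative over full runs.

Diffusion is a finite-volume two-point scheme driven by liquid-phase
concentrations, with face transmissibilities from the harmonic mean of
(liquid fraction x effective diffusivity); the nuclear envelope enters as a
series film conductance gamma_env * f_D_env * D * K / d (K, the
molecule/membrane compatibility, is not tabulated; 1.0 is used).  Time
stepping is backward Euler; with the step slaved to a 0.004 K temperature
cap the temporal error is negligible against the 1-D analytic (erf)
benchmark, which the suite holds to < 1 % L2.

Membrane water efflux follows the Arrhenius-permeability osmotic law:
J_w = L_p(T) (RT/nu_w)(ln a_w^in - ln a_w^ext), with the external activity
pinned to the ideal-dilute liquidus built from the same dHf/T_mw constants,
so the flux vanishes exactly at equilibrium.  The effective membrane area
exceeds the geometric ellipsoid area by the factor A_ef = 4 (microvillar
folding of the oolemma; the factor is not tabulated and 2–6 is the
plausible physiological range).  The flux is applied as a linearised Robin
boundary term inside the implicit diffusion solve — solving flux and film
concentration together is what removes the mesh sensitivity that an
explicit drain-then-refill splitting exhibits.  The membrane is permeable
to water only; glycerol is pre-loaded and salt does not cross.  Boundary
motion is Lagrangian: the realised efflux sets the normal recession speed,
cytoplasm layers rescale between the (fixed) nucleus surface and the
membrane, and cell contents are remapped conservatively in
cumulative-volume coordinates (solute totals preserved to < 1e-8 per
criterion, machine precision in practice).

## Bulk diffusivity from free-volume theory

The glycerol-water mutual diffusivity uses free-volume theory, the
appropriate model for a solution approaching its glass transition:

    D_W  = D0 exp(-dE/RT) exp(-(w_w V*_w + w_g xi V*_g)/V_FH)
    V_FH = w_w k_w (T - T_gw + K21) + w_g k_g (T - T_ga + K22)
    D    = D_W [W x_vw + (1 - x_vw)] (1 - 2 chi phi_w phi_g)

The registry constants (params.py documents the full symbol table) were
validated against bulk measurements: pure-water self-diffusion at 293 K
(2.05e-9 vs ~2.0e-9 m²/s), water tracer diffusion in pure glycerol
(1.3e-11 vs ~1.4e-11), dilute glycerol-in-water (8.8e-10 vs ~0.9e-9), and
the 50/50 mixture (3.2e-10 vs ~4e-10).  V_FH vanishing toward the mixture
glass transition is what arrests diffusion — and therefore ice growth — at
deep supercooling.

## Ice nucleation and growth

Per node, classical nucleation with the tabulated kinetic/thermodynamic
coefficients:

    J = Omega * (c_w nu_w) * exp(-kappa' / (T^3 (T_m - T)^2)),

homogeneous per volume and heterogeneous per catalysing area Ae; kappa' in
K^5 makes the exponent dimensionless, and T_m is the local solution
melting point from the node's own water mole fraction.  The crystal count
rate is throttled by the remaining free volume (1 - X_vice - X_vb).
Crystals nucleated in a step form a cohort; growth is diffusion-limited,
dr/dt = alpha D_eff S / r with S = gamma_t/(1+gamma_t) and supersaturation
gamma_t = C_inf/C_liq(T) - 1.  alpha is a dimensionless growth constant of
order unity for Zener-type diffusion-limited growth and is set to 1.  The
radius ODE is integrated in u = r², whose rate 2 alpha D_eff S is regular
at the seed radius; the 1/r form is stiff there and overshoots by orders
of magnitude under any explicit scheme.  Cohorts advance by classical RK4
with the step slaved to the 0.004 K cap (suite: RK4 vs tiny-step Euler
< 0.5 %).  Soft impingement is an Avrami-type saturating transform with
saturation gamma_t/(1+gamma_t); the driver applies its differential form
and additionally caps each increment by the water actually present, which
produces the plateau when a node's free water is exhausted or diffusion
arrests.

## The IIF network

Nine nodes (A, F, I membrane-adjacent; B, E, H cytoplasm near the nuclear
envelope; C, D, G in the nucleus) sample the transport field by local
weighted least-squares interpolation (cubic by default, with adaptive
order reduction and local-range clipping near fronts; on the axisymmetric
mesh the stencil is mirrored across the symmetry axis).  Node A receives
the exogenous heterogeneous nucleation area 64416.476 at t = 0; spreading
between adjacent nodes follows

    Ae(i->j) = Ae_sal (X_i^M + C) exp(-r_ij/d),

with the tabulated Ae_sal, C = 0, M = 1.  The decay parameter is printed
as 0.02 without units; any metre- or millimetre-scale reading makes the
exponential inert across an 80 um cell and any micrometre reading kills
spreading outright, so d is set to 6 um — the only scale at which the law
acts as a genuine distance gate — which yields the sequential
node-by-node activation the exogenous-trigger hypothesis describes.
Spreading across the nuclear envelope is attenuated by the envelope
equivalent porosity (0.2), since catalysing surface reaches the nucleus
through envelope pores.  Membrane-adjacent nodes are placed ~4 um inside
the membrane (F and I at comparable fractional depths of their rays),
i.e. in the cytoplasm proper rather than inside the equilibrated boundary
film, whose undercooling is structurally near zero.  Node ice increments
return to the mesh over a nearest-node (Voronoi-style) partition,
weighted by local available water and volume-preserving.

## Simulation protocol and experiments

T(t) = T0 - B t with T0 = 273.15 K (the starting temperature is not part
of the reference protocol; nothing happens above the bath liquidus, where
the driver strides coarsely).  Operator splitting per step: implicit
diffusion with the membrane Robin term, boundary motion, network kinetics
(RK4), ice feedback.  The driver is deterministic — identical
configurations give bit-identical traces.

Built-in experiments: the exogenously triggered network run (4.8 mol/L,
0.02 K/s, 0.004 K cap), the equal-diffusion-factor control (nucleus factor
forced to 0.3), the equal-area node comparison (every node handed the
constant area; CS duplicates C's position with the cytoplasm factor), and
dehydration-only runs at 6 mol/L for the water-gradient structure
(dehydration-only runs use a 0.05 K step; no kinetics are active).  Test
runs use 16–20 cells per axis and the acceptance script 32; activation
temperatures change by ~0.1 K between 16 and 24.

## What the model does and does not show

The simulated cell reproduces the structure of the reference experiment
set: centre-high water fraction during dehydration with a gradient that
grows and then saturates; a higher water distribution with the
nucleus/envelope present than in the homogeneous cell; the activation
order A -> B, F -> nucleus cascade C -> D -> G before H, with I last and
E and G plateauing together; faster ice growth at the nucleus node than
at the same node computed with the cytoplasm diffusion factor (growth
rates ordered A < B < CS << C); loss of the nucleus-first pattern when
the diffusion factors are equalised; and nucleus-over-cytoplasm
ice-volume crossings at about -34.8 °C (C over F) and -36.3 °C (D over
E) on the 32x32 mesh.  Absolute event temperatures are anchored by the
dehydration lag, which depends on quantities the tables do not fix — the
effective membrane area factor, the growth constant alpha, the units of
the spreading decay — all chosen here on physical priors or on the
qualitative activation order rather than fitted to the crossing
temperatures themselves.

Of note: with the tabulated envelope parameters the nuclear envelope adds
only a few percent of diffusive resistance, so the nucleated cell's
normalised retention fraction is essentially identical to the homogeneous
cell's; the higher water distribution comes from the nucleus's larger
free-water porosity.

Other limitations: ideal-dilute liquidus (activity coefficients of
concentrated glycerol/NaCl neglected); ice density equal to water density
in the volume ledger; salt shares the water/glycerol mutual diffusivity
(configurable); heat transfer ignored (uniform temperature); axisymmetric
geometry only; nucleation is rate-based and deterministic, with no
stochastic single-event sampling.
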