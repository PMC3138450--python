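# Methods

## Model overview

`isletsim` couples cellular-level Hill-type reaction kinetics to
convection–diffusion mass transport in a perifusion chamber.  The β-cells are
treated as sensors of the local glucose concentration and of its rate of
change: the sustained (second-phase) secretion follows a sigmoid of `c_gluc`,
the transient (first-phase) secretion a sigmoid of ∂c_gluc/∂t active only
while glucose rises.  Oxygen enters twice — consumption (with a
glucose-dependent metabolic demand) and an abrupt hypoxic limitation of
secretion — because oxygen diffusion is the binding constraint in avascular
islet tissue.  No subcellular granule-pool dynamics, time-dependent
potentiation/inhibition, or incretin amplification are modelled.

### Rate laws and parameters

All rates are `R = R_max · cⁿ/(cⁿ + C_Hfⁿ)` of local concentrations
(SI units; mol m⁻³ ≡ mM):

| process | variable | C_Hf | n | R_max |
|---|---|---|---|---|
| oxygen consumption | c_oxy | 1 μM | 1 | −0.034 mol m⁻³ s⁻¹ |
| — metabolic modulation φ_o,g | c_gluc | 7 mM | 2.5 | (dimensionless) |
| glucose consumption | c_gluc | 10 μM | 1 | −0.028 mol m⁻³ s⁻¹ |
| secretion, second phase | c_gluc | 7 mM | 2.5 | 3.0×10⁻⁵ mol m⁻³ s⁻¹ |
| secretion, first phase | ∂c_gluc/∂t | 0.03 mM s⁻¹ | 2 | 21×10⁻⁵ mol m⁻³ s⁻¹ |
| secretion oxygen limit φ_i,o | c_oxy | 3 μM | 3 | (dimensionless) |

Auxiliary constants: metabolic split φ_base = φ_metab = 0.5 with scale
Φ_sc = 1.8 (chosen so φ_o,g(3 mM) ≈ 1, preserving the resting consumption
rate; consumption then rises ≈ 69% from 3 to 15 mM); necrosis cut-off at
C_cr,oxy = 0.1 μM with smoothing half-width 0.05 μM; local-compartment
release k_insL = 0.003 s⁻¹ (t½ ≈ 3.85 min); pO₂ ↔ concentration conversion
700 mmHg per mol m⁻³ (0.200 mM ↔ 140 mmHg); insulin monomer mass
5808 g mol⁻¹ (R_max,ins2 for one islet equivalent ≈ 18.5 pg/IEQ/min).

Diffusivities (m² s⁻¹, water / tissue / capsule): oxygen 3.0 / 2.0 / 2.5
×10⁻⁹; glucose 0.9 / 0.3 / 0.6 ×10⁻⁹; insulin 0.15 / 0.05 / 0.1 ×10⁻⁹.  The
local insulin compartment is carried as a field with diffusivity 10⁻¹⁶ m² s⁻¹
(effectively immobile), which lets all four species share one transport
discretization.

### Design choices where the functional forms were open

* **First-phase glucose modulation σ_i1,g.**  The gradient response is scaled
  by a bump that peaks where islets are most sensitive (C_m = 5 mM) and
  decays at both low glucose (no fuel) and high glucose (second phase already
  elevated).  We use the normalized derivative of the model's own sigmoid
  family with respect to log-concentration: σ = 4 f (1−f) with
  f = c²/(c² + C_m²).  This gives σ(0) = 0, σ(1 mM) ≈ 0.15, σ(10 mM) ≈ 0.64,
  σ(30 mM) ≈ 0.11.  The slope (default 2) is a config knob.  Steeper choices
  suppress the first-phase spike entirely for steps between high glucose
  levels, contradicting the defining biphasic phenotype, which is why the
  shallow log-symmetric form is the default.
* **Necrosis cut δ.**  Applied to oxygen consumption and, for physical
  consistency, to glucose consumption and insulin secretion (dead tissue
  neither consumes nor secretes).  δ is an instantaneous function of the
  current local oxygen — tissue "revives" if oxygen returns; no death memory
  is kept.
* **Smoothed steps.**  All step functions (necrosis cut, inflow staircase)
  are the quintic smoothstep on [−s, +s]: continuous first derivative, no
  overshoot, value ½ at the threshold.
* **Total secretion** is (phase 1 + phase 2) · φ_i,o · δ — the oxygen
  limitation multiplies both phases.
* **∂c_gluc/∂t** for the first phase is the nodal backward difference over
  the last accepted time step, floored at zero.
* **Islet placement.**  The two representative islets (d = 100, 150 μm) sit
  1 mm apart along the flow and are staggered ±0.4 mm across the channel.
  Coaxial placement would put the downstream islet in the upstream islet's
  oxygen-depletion wake, making the oxygen response depend on an arbitrary
  alignment accident; the staggered default keeps the two islets independent
  size-class representatives.  Positions are fully configurable.

## Numerics

* **Mesh.**  Unstructured triangulations from a graded point cloud:
  concentric rings inside and around each islet (spacing ≈ radius/7, with
  exact rings on the tissue and capsule interfaces so no element straddles a
  material boundary), a jittered hexagonal lattice in the lumen (target edge
  `resolution`, default 150 μm → ≈6,400 elements for the default chamber),
  Delaunay triangulation, element subdomain tags by centroid.  Deterministic
  given (geometry, resolution, seed).
* **Flow.**  Steady Stokes (the operating Reynolds number is ≈ 0.57) with
  P1–P1 elements and Brezzi–Pitkäranta pressure stabilization (β = 0.01);
  parabolic inlet 4 v_in s(1−s), no slip on walls and all liquid–solid
  interfaces, zero-pressure/no-viscous-stress outlet.  Full Navier–Stokes via
  Picard iteration is available behind a flag and differs from Stokes by
  < 1% at this Reynolds number.  Solved once per geometry and reused.
* **Transport.**  P1 FEM with the conservative convection form
  (−Cᵀ plus an outflow boundary matrix) and SUPG streamline stabilization for
  the advection-dominated lumen transport.  Inlet concentrations are imposed
  as Dirichlet values (equivalent to the inward-flux condition at the inlet's
  high Péclet number); outflow is the zero-diffusive-flux condition; walls
  insulated; interface continuity is the natural FEM condition (no partition
  coefficients).  The conservative form makes global mass balance and the
  secretion → outflow bookkeeping machine-exact; the price is that spatially
  uniform fields are preserved only up to the discrete divergence of the
  stabilized velocity, an O(h²) consistency error (0.7% max at 300 μm
  resolution, 0.13% at 150 μm).
* **Time stepping.**  Implicit (backward Euler) with Patankar-style
  linearization of the consumption sinks (q = −R(c_old)/c_old enters the
  matrix, preserving positivity) and explicit secretion sources; step size
  adapts up to dt_max = 0.5 s, small enough that the smoothed inflow steps
  (τ = 30 s) cannot be overstepped.  The insulin and local-insulin systems
  have constant matrices at fixed dt and reuse cached LU factorizations.
  Sub-noise negative values (< 10⁻¹⁰ of the field scale) are clipped; larger
  stabilization undershoots are counted and bounded (abort above 20% of the
  field scale) but not removed, keeping the mass balance exact.
* **Steady states** (initialization, dose–response and oxygen-sweep points):
  pseudo-time continuation to near the attractor, then damped Newton on the
  oxygen equation (the necrosis ramp makes plain large-step Picard iteration
  cycle) alternated with linear glucose solves; the insulin pair then follows
  by one linear solve plus the algebraic relation c_insL = c_ins + R_ins/k.
* **Radial model.**  Finite-volume discretization on a graded 1D spherical
  grid (exact shell volumes, interface-aware face diffusivities, exact
  tissue-volume reaction weights), same kinetics and the same steady-state
  algorithm.  Against the closed-form zeroth-order oxygen solution
  c(r) = c_s − (R₀/6D)(a² − r²) it is accurate to < 1%.

### Planar section vs spherical islets

The chamber model is a planar 2D section, so each islet is effectively an
infinite cylinder: its interior oxygen deficit is R₀a²/4D instead of the
sphere's R₀a²/6D, and its exterior supply is more restricted.  Absolute
outflow amplitudes are therefore reported per unit depth and all quantitative
comparisons are made on normalized traces.  For oxygen-dependence summaries
the package provides a spherical-interior estimator
(`oxygen_sweep(..., spherical_islets=True)`): the chamber solve supplies each
islet's surface oxygen concentration and the radial model supplies the
spherical interior.  With it, whole-preparation secretion at 15 mM glucose
stays essentially unchanged down to ~50–60 mmHg incoming pO₂ and is
half-maximal near 29 mmHg; the pure planar chamber yields ~35 mmHg (planar
interiors starve sooner).  For the encapsulated comparison the planar chamber
is used throughout.

## What the built-in scenarios do and do not show

The preset fixtures reproduce standard perifusion protocols: the G1→G30
staircase (30-min plateaus), the single G1→G15→G1 step, the incoming-pO₂
sweep at high glucose, and the free-vs-encapsulated comparison at 140 vs
45 mmHg.  Inflow steps use smoothing half-width τ = 30 s, giving inflow
gradients of 0.03–0.16 mM s⁻¹, the range typical of experimental perifusion
steps.  These synthetic scenarios exercise the full coupled physics, but they
idealize real experiments: islet preparations are polydisperse (here: two
representative sizes), tubing dispersion and sampling dead-volume are absent,
and the secretion amplitude scales with the (arbitrary) per-depth islet mass,
so only normalized amplitudes are meaningful.  Species-level differences
(human vs rodent glucose sensitivity), glucose priming, and incretin effects
are outside the model.

## Known limitations

* Whole-trace quantitative agreement with any specific experimental dataset
  requires amplitude rescaling (planar 2D) and possibly retuning of the
  first-phase constants, which are exploratory.
* The first-phase peak amplitude is sensitive to the inflow smoothing τ and
  to the σ slope; both are exposed in the configuration.
* The necrosis cut is instantaneous in local oxygen; chronic-hypoxia death is
  not persistent.
* Equal-order flow stabilization leaves an O(h²) velocity-divergence defect;
  see Numerics for its consequences and magnitudes.
* The steady-state Newton solver assumes the necrosis ramp's smoothness;
  pathological parameter choices (step_scale → 0) would need continuation.
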