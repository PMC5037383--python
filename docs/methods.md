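# Methods

## The model

`progpot` builds coarse-grained N-body potentials from two ingredients:
ordinary distance-only pair potentials, and coarse-level *interaction
rules* stated as Boolean combinations of proximity predicates.  The
potential is the switched sum

    U(x) = Σ_entities Σ_bonds φ_harm(r)  +  Σ_{p∈𝒫} Σ_{j=1}^{m(p)} S_{p,j}(x) · φ_{p,j}(r_p)

over an interaction pair set 𝒫 with multiplicity m (a pair carries more
than one switched potential when, e.g., a breakable bond needs a
separate transition-state repulsion term).  Each coefficient S_{p,j},
the *encoding function*, takes values in [0, 1] and smoothly turns its
potential on and off according to the configuration of the rest of the
system.  By construction S_{p,j} may depend on any inter-particle
distance except r_p itself — a switch that listened to its own pair
would destroy the factorization into switch times distance-only bond.

Encoding functions are compiled, not hand-written.  A rule is first a
*logic function*: AND/OR/NOT applied to elementary predicates
"particles i and j are within R" (the indicator of the half-open
interval [0, R); ties r = R evaluate to 0).  The connectives use the
algebraic forms

    a ∧ b = a·b,    a ∨ b = a + b − a·b,    ¬a = 1 − a,

which coincide with the usual truth tables on {0, 1} and — unlike
min/max — remain smooth when the leaves become real-valued.  The
*replacement procedure* then substitutes each indicator with

    h_{α,n}(r) = 1 / (1 + (r/α)^{2n}),       h_{0,n} ≡ 0,  h_{∞,n} ≡ 1,

computed via (r²/α²)ⁿ so the function is smooth in the Cartesian
coordinates (no cusp at coincidence; h′(0) = 0 exactly).  Properties
used throughout: h(0) = 1, strict monotone decrease, h(α) = 1/2 for
every n ≥ 1, limit 0 at infinity, and a transition that sharpens as n
grows.  To mimic the indicator of [0, R) one sets α = R, so the
regularized predicate evaluates to 1/2 exactly at threshold.
Convolution with a summability kernel would smooth the logic too, but
is analytically and computationally impractical; per-leaf replacement
keeps everything closed-form and differentiable.

Because every term depends on relative distances only, the switched sum
defines a translation- and rotation-invariant Hamiltonian system.
Forces come in two modes:

* **full** — the exact negative gradient, including ∂S/∂x through the
  chain rule.  These encoding-function gradients are physical: they are
  what makes an approaching particle pay the energy stored in a bond it
  is about to switch off.
* **frozen_switch** — treats ∂S/∂x as zero almost everywhere (exact for
  the discrete logic, which is piecewise constant) and keeps only the
  −S·φ′ terms.  A qualitative approximation appropriate when switching
  energetics are not the object of study; it is the default for the
  inhibitor and transcription systems.

## Numerics

* **Evaluation.** Each system is compiled once into a table of unique
  particle pairs (term pairs, rule leaves, constraint bonds); distances
  are computed in one vectorized pass, leaf values h and h′ in another,
  and per-term values/gradients by walking small expression trees.
  Forces scatter through a signed incidence matrix.  Gradients agree
  with central finite differences to better than 1e−6 relative error
  (audited in the tests and by `progpot check`).
* **Integrators.**  Velocity Verlet for deterministic (NVE) runs —
  requiring full force mode, since frozen-switch forces are not
  conservative — and BAOAB-split underdamped Langevin dynamics for
  constant-temperature runs (best configurational accuracy at large
  time steps among the standard splittings).  The run seed is split via
  `numpy.random.SeedSequence` into independent initialization and
  thermostat streams; identical parameters reproduce trajectories
  bitwise.
* **Constraint bonds.**  Entities are held together by stiff harmonic
  springs, always on, rather than holonomic constraints: this keeps the
  system Hamiltonian and avoids constraint solvers at the scale of
  these systems (≤ 20 particles).  Spring constants are set per fixture
  so the bond-length fluctuation at the fixture's working temperature
  is 2% of the rest length (k = k_BT/(0.02·r₀)²).
* **Degenerate geometry.**  Coincident particles in a leaf are safe
  (h′(0) = 0); a coincident pair in a force term contributes zero force.
* **Confinement.**  An optional flat-bottom harmonic well (zero inside a
  radius, ½k(d − radius)² outside) keeps dissociated entities from
  escaping to infinity so that they can recollide; it is off by default
  and enabled in the simulation fixtures.

## Bond-event analysis

Thermal jitter makes single-threshold event detection chatter, so bond
states are read with two-threshold hysteresis: formed below
r_on = 1.2·r_eq, broken above r_off = 2.0·r_eq, with optional
debouncing of sub-window flickers.  Occupancy is the fraction of frames
in the hysteresis-bound state.  For binding *order* in crowded systems
the package also supports a switch-gated reading: a bond forms at first
passage below a threshold while its encoding function exceeds 1/2,
which distinguishes an engaged potential from coincidental proximity.

The quasi-static dissociation probe translates the approaching entity
rigidly along a straight line and integrates the projected force with
adaptive quadrature (`scipy.integrate.quad`).  Because the potential is
conservative this equals the energy difference between the endpoints;
the probe exists to measure that transfer the way an experiment would.
With a switched bond held at its equilibrium distance, driving the
attacker from 3× the switch radius to the bond's r_eq returns the
dissociation energy D to within ~1.5% at n = 6 (the residual is the
finite sharpness of the switch at the endpoints).

## Example systems

All fixtures use the reduced unit preset (k_B = 1, masses 1); a real
preset (Å / fs / kcal·mol⁻¹) is available in the run-config for users
with calibrated parameters.  Values printed in the source material are
kept verbatim as defaults: Morse depth D = 100 (energy units), width
a = 1 (inverse length), equilibrium length r_eq = 2 for the rod
mechanisms, proximity thresholds R = 3 = 1.5 × r_eq.  Default switch
sharpness is n = 6: sharp enough that distances beyond 2α leave a leaf
below 0.002, soft enough for stable integration at dt = 0.002.
Remaining run conditions are package choices, fixed once so that each
system operates in its intended regime, and all overridable:

* **signaling / inhibitor** (frozen-switch): three 2-site rods,
  kT = 20 = 0.2·D, friction γ = 1, confinement radius 7.  At this
  temperature bonds are stable on the run timescale yet the inhibitor's
  contacts exchange within a 10⁵-step window.
* **reaction** (full mode): AB + C ⇌ AC + B with multiplicity 2 on both
  reactive pairs — the stable Morse bond gated by ¬near(attacker), plus
  the repulsive Morse branch (φ_Morse + D below r_eq, identically 0
  above, C¹ at the splice) gated by exactly the complementary predicate.
  The switch radius 1.5 × partner r_eq means a bond is off before the
  attacker reaches its own bonding distance.  kT = 40 = 0.4·D_AB gives
  tens of activated exchange events per 10⁵-step run, the regime in
  which occupancy statistics converge; the well-depth ratio
  D_AC/D_AB is the `bias` parameter (1 = symmetric, 2 = product-biased).
  B and C carry a passive second site so the full configuration space
  is 12-dimensional while the switched sum depends on 8 coordinates.
* **dna** (frozen-switch): 20 particles — promoter (1,2), polymerase
  (3,4), template strand A=5, C=6, T=7, G=8, and free nucleotides
  U=(9,10,11), G=(12,13,14), A=(15,16,17), C=(18,19,20), each a
  base–sugar–phosphate chain.  Base pairs bind via a hydrogen-bond-like
  Morse (D = 100), backbone links via a stronger covalent-like Morse
  (D = 150); here a = 1, r_eq = 1.  The rules (listed in
  `build_dna`'s docstring) gate each bond on the polymerase–promoter
  contact and on all upstream bonds, producing a strictly sequential
  cascade followed by release of the finished strand and the
  polymerase.

  Two radii matter and must be separated: a bond's thermal fluctuation
  band around r_eq, and the proximity-predicate radius R_bond that
  defines "formed" inside the rules.  R_bond = 2.2 sits several
  standard deviations (σ = √(kT/2Da²) ≈ 0.16 at kT = 5) above the
  bound band, so formed predicates do not chatter, yet below typical
  inter-particle distances in the crowded confinement well (radius 10),
  so unbonded neighbors do not satisfy predicates by accident.
* **"remains on once the backbone has formed"** is encoded per backbone
  bond as a conjunction of the *other* backbone contacts
  (self-reference being forbidden).  For the last link this alone would
  subsume its turn-on rule and complete the backbone prematurely, so
  its hold-open clause additionally requires either the strand to be
  detached (no base-pair contact) or the polymerase to be off the
  promoter.  A residual race survives any purely distance-based
  encoding: if the polymerase rebinds while the released strand is
  still nearby, part of the strand can be recaptured; this occurs in
  roughly one run in ten and is treated statistically by the tests.

## What the synthetic systems do and do not show

The fixtures realize the *designed logic* of each mechanism in a bath:
they demonstrate that compiled encoding functions switch potentials in
the intended order, that switching costs the right energy, and that
biasing well depths biases the steady state.  They are not calibrated
molecular models: 2-D geometry, point sites without excluded volume, no
angular terms, a single friction constant, and supplementary-level
force-field parameters replaced by documented package defaults.
Passing tests therefore validate the formalism and its implementation,
not quantitative predictions for any real molecule.

## Problem sizes

The statistical tests use 10 fixed seeds per experiment with 10⁵ steps
(reaction, dt = 0.002, ~200 time units) or 2×10⁵ steps (transcription),
sizes at which the pilot behavior (tens of exchange events; 10/10
completed transcriptions) is stable.  The deterministic checks run a
single trajectory (energy conservation, 10⁴ Verlet steps) or no
trajectory at all (truth tables, dimension counts, quadrature).

## Known limitations

* Frozen-switch dynamics are not conservative; energy checks apply to
  full mode only.
* Event detection, occupancy and binding order are threshold-based
  readings of distance traces; the thresholds are configurable and the
  defaults documented above.
* The logic formalism is memoryless: rules see only current distances.
  Behaviors that need state ("cannot rebind, ever") can only be
  approximated, as in the transcription release race above.
* No excluded volume is imposed beyond the declared terms; dense
  systems can transiently overlap.
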