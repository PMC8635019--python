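# Methods

## Model

`pumpleak` implements the classical pump-leak description of monovalent-ion
and water homeostasis in an animal cell, in the charge-difference /
flux-balance formulation: a single well-stirred intracellular compartment
exchanging Na⁺, K⁺ and Cl⁻ with an infinite bath through five pathway
classes — Goldman-type electroconductive channels (one rate coefficient per
ion, `pNa`, `pK`, `pCl`, min⁻¹), a Na/K pump first order in intracellular Na
(`β`, min⁻¹) with fixed Na:K flux stoichiometry `γ`, and the electroneutral
cotransporters NC (1Na:1Cl), KC (1K:1Cl) and NKCC (1Na:1K:2Cl) obeying
mass-action product laws (`inc`, `ikc` in ml·µmol⁻¹·min⁻¹; `inkcc` in
ml³·µmol⁻³·min⁻¹).  A fixed pool `A` of impermeant intracellular osmolytes
with mean valence `z` closes the system through two algebraic constraints
that hold at every instant: cytoplasmic electroneutrality and osmotic
balance with the bath (which may contain an impermeant non-electrolyte `B`).

Assumptions inherited from this model class:

- membrane capacitance is neglected, so the membrane potential `u` is an
  algebraic variable re-solved at every step from zero net charge flux;
- water moves much faster than ions: the water volume re-equilibrates
  instantaneously, `V = (Na + K + Cl contents + A)/Osm_o`;
- `A` and `z` are constant (no organic-osmolyte transport);
- single temperature, 37 °C: RT/F is hard-coded as 26.7 mV so that every
  potential and electrochemical gradient is on the same scale as the
  reference values (never recomputed from physical constants);
- the pump is first order in [Na]ᵢ (no saturation kinetics), optionally with
  a linear run-down `β(t) = max(0, β − kb·t)`;
- no divalent ions, pH/bicarbonate chemistry, or spatial gradients.

`γ = 1.5` (3Na:2K) is the package default: it closes the K⁺ flux balance of
every bundled reference parameter column exactly (e.g. pump K influx 0.91
µmol·min⁻¹·ml⁻¹ against channel −0.476, KC −0.307 and NKCC −0.127 for
reference cell A).

### Sign conventions

Fluxes are per ml of cell water per minute; influx is positive.  The anion
channel kernel is `net = pCl·u·([Cl]ᵢ − [Cl]ₒe^u)/g`, `g = 1 − e^u` — the
valence −1 constant-field form.  It is the unique sign choice under which
(a) net chloride flux runs down its electrochemical gradient, and (b) the
chloride balance of all eight bundled parameter columns closes with the
published `pCl` values; both properties are asserted in the test suite.
`u/g` is evaluated with `expm1` and its analytic limit at `u = 0`, so the
kernels are smooth through zero potential (Fick limit `p·(cₒ − cᵢ)`).

### OSOR

The ratio of ouabain-sensitive to ouabain-resistant K⁺(Rb⁺) influx is
computed as pump K influx over the sum of all other unidirectional K
influxes (channel + KC + NKCC).  With NC as the only cotransporter this
yields the closed form `e^u = [K]ₒ(OSOR+1)/[K]ᵢ` for the potential; with K
carried by KC/NKCC the potential is found by a bracketed 1-D root search on
the assembled OSOR(U).  For multi-cotransporter variants the computed OSOR
deviates from the single measured value by construction (model versus
measurement); the measured OSOR reproduces the NC-only column exactly.

## Inverse problem

At a balanced state each ion's channel flux must cancel the summed net flux
of its other pathways, and the channel flux is linear in its rate
coefficient, so the three balances decouple into three scalar equations.
The system is underdetermined by one degree of freedom — the membrane
potential — which the caller closes either with a given `U` (reproducing
the published parameter tables) or with a measured OSOR.  A non-positive
fitted permeability raises an error rather than returning an unphysical
parameter set.

The reference potentials for the multi-cotransporter variants are treated
as given inputs; nothing in the balanced state alone pins them, and their
experimental provenance (inhibitor flux data) is outside this package's
scope.

## Numerics

- **Potential solve**: the net charge flux is strictly monotone decreasing
  in `u` for any conductive membrane (asserted numerically for all bundled
  parameter sets), so the root on `u ∈ [−10, 10]` (±267 mV) is unique.
  `solve_membrane_potential` uses Brent's method at `xtol = 1e-14`; inside
  the integrator the root is tracked by a warm-started safeguarded Newton
  iteration (converges in 1–2 steps per time step) with a Brent fallback.
- **Integrator**: explicit Euler at `dt = 0.01` min, the reference scheme
  for this mildly stiff system (fastest time constants tens of minutes).
  Correctness is defined by the step-halving contract — halving `dt`
  changes every output by < 10⁻⁴ relative in all bundled scenarios — not by
  the scheme.  Each step: solve `u`; advance contents by `dt·V·(net flux)`;
  re-equilibrate water.  Electroneutrality is conserved exactly by the
  charge-free step (residual < 10⁻⁶ relative at every output point) and
  osmotic balance holds by construction.
- **Events**: protocols are ordered timed events (pump block, medium
  replacement, osmolarity scaling, parameter steps) applied on the step
  grid.  The `t = 0` output row records the pre-event state (an event "at
  t = 0" acts for `t > 0`), matching the layout of the reference flux
  tables.  At coincident times parameter changes apply before medium
  changes — a documented, arbitrary tie-break.
- **Balanced-state detection**: a run is flagged balanced when every
  per-ion total net flux falls below 10⁻⁶ µmol·min⁻¹·ml⁻¹ at an output
  point.  `equilibrium.balanced_state` additionally solves the fixed point
  algebraically (damped Newton on log-contents plus `u`), serving as an
  independent oracle for the integrator's long-time limit; a solution
  diverging to very large volume is reported as "no finite balanced state"
  (the Donnan unbounded-swelling regime).
- **Extremum detection** for the simulation targets uses the 1-min output
  grid and reports the grid argmax/argmin.

## Reference data and presets

The bundled presets describe two resting U937 cell states: cell A
([K]ᵢ 156, [Na]ᵢ 35, [Cl]ᵢ 70 mM; used for pump-block runs) and cell B
([K]ᵢ 147, [Na]ᵢ 38, [Cl]ᵢ 45 mM; used for RVD runs), each under four
cotransporter sets, with `β = 0.039 min⁻¹` and the standard 310 mOsm bath
(Na 140, K 5.8, Cl 116, B 48.2 mM).  Presets store the published channel
parameters verbatim and verify on load that each column closes its flux
balance to < 1% of the largest unidirectional flux, which catches
transcription errors while tolerating table rounding.  `refit=True`
replaces the rounded permeabilities by the exact inverse-solver values so
that simulations start from an exact fixed point.  The derived impermeant
pools are A/V = 49 mM, z = −2.47 (cell A) and A/V = 80 mM, z = −1.75
(cell B).

The protocol builders reproduce the computational experiments: pump block
(with and without external impermeant osmolyte, where the B = 0 bath is the
charge-balanced Na 149.2 / K 5.8 / Cl 155 mM composition), the iso→hypo
transition to 160 mOsm by 75 mM NaCl removal, the sucrose-substitution
media separating the NaCl signal from the osmotic signal, the iso→hypo→iso
round trip, NC rate steps, single-parameter steps, and the 24-run 10×/0.1×
parameter scan.  In the sucrose experiment, the "sucrose removal only"
variant starts from the cell pre-equilibrated to flux balance in the
310 mOsm sucrose bath — the only initial condition under which no NaCl
change occurs at the transition.

Sucrose (and `B` generally) is modelled purely as impermeant osmolyte: it
enters the osmotic balance only, since external electroneutrality is not
part of the model and no equation assigns `B` a charge.

## What the bundled scenarios do and do not show

All inputs are printed reference values, not raw data; the package contains
no stochastic generator.  Passing tests show that the deterministic model
reproduces the published balanced states, parameter fits and simulation
endpoints — they say nothing about biological variability, cell-population
heterogeneity (e.g. the adapted/non-adapted subpopulations seen in density
gradients), receptor-mediated volume regulation, or organic-osmolyte
fluxes, all of which are outside the model class.  The buoyant-density
conversion `v = (1 − ρ/1.38)/(0.72(ρ − 1))` is implemented for completeness
of the measurement chain; its constants (dry-mass density 1.38 g/ml,
protein share 0.72) affect absolute but not relative water contents.

## Known limitations

- Explicit Euler needs small `dt`; an adaptive integrator is deliberately
  not the reference path (determinism and auditability are preferred).
- Approach to flux balance is exponential with time constants of hundreds
  of minutes; runs to the 10⁻⁶ flux tolerance take a few thousand simulated
  minutes (a second or two of wall time each).
- The inverse problem is solved per ion at a *given* state; fitting
  cotransporter rate coefficients themselves (from inhibitor data) is not
  implemented.
- Media with zero conductive pathways, or OSOR targets requiring a
  depolarized `e^u > 1` regime, are reported as errors, not extrapolated.
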