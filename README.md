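# pumpleak

Pump-leak modelling of monovalent ion and water homeostasis in animal cells:
a flux engine for channels, the Na/K pump and the cation–chloride
cotransporters NC, KC and NKCC; an inverse solver that recovers membrane
parameters from measured intracellular ion concentrations; and a dynamic
simulator for pump-block and anisoosmotic (RVD/RVI) protocols with full
per-pathway unidirectional flux accounting.

The package is aimed at cell physiologists who have flame-photometry /
radiotracer measurements of intracellular Na⁺, K⁺ and Cl⁻, a cell-water
estimate (e.g. from buoyant density in a Percoll gradient), and a pump rate
coefficient, and who want to ask quantitative questions such as: *which
channel permeabilities are consistent with this resting state?  What happens
to cell volume when the pump is blocked by ouabain?  How much of the
"regulatory" volume decrease in a hypoosmolar medium is pure electrochemistry
rather than signalling?*  The reference parameter sets bundled with the
package describe resting human U937 histiocytic-lymphoma cells.

## The model

The cell is treated as a well-stirred electrochemical compartment.  Two
algebraic constraints hold at every instant — cytoplasmic electroneutrality
and osmotic (water) balance:

    [Na]ᵢ + [K]ᵢ − [Cl]ᵢ + z·A/V = 0
    [Na]ᵢ + [K]ᵢ + [Cl]ᵢ + A/V = [Na]ₒ + [K]ₒ + [Cl]ₒ + [B]ₒ

where `A` is the (constant) amount of membrane-impermeant intracellular
osmolytes with mean valence `z < 0`, `V` the cell water volume and `B` the
external impermeant osmolyte.  The ion contents evolve by

    dNaᵢ/dt = V·{ pNa·u·([Na]ᵢe^u − [Na]ₒ)/g − β[Na]ᵢ + J_NC + J_NKCC }
    dKᵢ/dt  = V·{ pK ·u·([K]ᵢe^u − [K]ₒ)/g + β[Na]ᵢ/γ + J_KC + J_NKCC }
    dClᵢ/dt = V·{ pCl·u·([Cl]ᵢ − [Cl]ₒe^u)/g + J_NC + J_KC + 2·J_NKCC }

with `u` the dimensionless membrane potential (`U = 26.7·u` mV at 37 °C),
`g = 1 − e^u` (Goldman constant-field channel kernels), a pump first order in
[Na]ᵢ with Na:K stoichiometry γ = 3:2, and electroneutral cotransporters
following mass-action product laws, e.g. `J_NC = inc·([Na]ₒ[Cl]ₒ −
[Na]ᵢ[Cl]ᵢ)`.  The membrane potential is an algebraic variable solved at
every step from zero net charge flux; water equilibrates instantaneously.

Given a measured balanced state, the three per-ion flux balances are linear
in `pNa, pK, pCl`, so the inverse problem is solved in closed form once the
potential is pinned — either directly (a given `U`) or through a measured
OSOR, the ratio of ouabain-sensitive to ouabain-resistant Rb⁺(K⁺) influx.

## Worked example

```python
import pumpleak as pl

# inverse problem: membrane parameters from a measured resting state
medium = pl.standard_rpmi_medium()            # Na 140, K 5.8, Cl 116, B 48.2 mM
conc = (35.0, 156.0, 70.0)                    # measured [Na]i, [K]i, [Cl]i, mM
a_over_v, z = pl.impermeant_from_state(conc, medium)
p_na, p_k, p_cl = pl.fit_permeabilities(conc, medium, beta=0.039, gamma=1.5,
                                        inc=7e-5, ikc=3e-5, inkcc=8e-9, U=-45.2)
print(f"A/V = {a_over_v:.0f} mM, z = {z:.2f}")
print(f"pNa = {p_na:.4f}, pK = {p_k:.4f}, pCl = {p_cl:.4f} min^-1")

# forward problem: block the pump and follow the cell to its new balance
state, params, med = pl.preset("A", "NC+KC+NKCC", refit=True)
protocol = pl.Protocol(events=(pl.Event(0.0, "set_beta", 0.0),),
                       duration=8000.0, out_dt=5.0)
traj = pl.simulate(state, params, med, protocol, stop_when_balanced=True)
print(f"balanced at t = {traj.balanced_time:.0f} min, "
      f"V_final/V_initial = {traj.v[-1]/traj.v[0]:.3f}, "
      f"U: {traj.U[0]:.1f} -> {traj.U[-1]:.1f} mV")
```

prints

```
A/V = 49 mM, z = -2.47
pNa = 0.0019, pK = 0.0100, pCl = 0.0040 min^-1
balanced at t = 2745 min, V_final/V_initial = 1.380, U: -45.2 -> -5.8 mV
```

The impermeant intracellular osmolytes amount to 49 mM with mean charge
−2.47; channel permeabilities of 0.0019 / 0.0100 / 0.0040 min⁻¹ balance every
ion flux at −45.2 mV.  With the pump blocked, the 48.2 mM of external
impermeant osmolyte caps the Donnan swelling: the cell settles at 1.38× its
initial water volume in a nearly depolarized state, instead of swelling
without bound (set `b_o = 0` in the medium to see the unbounded case).

A command-line interface mirrors the library:

```
pumpleak balance examples/cellA_pump_block.toml
pumpleak simulate --preset fig1 --cell A -o trajectory.tsv --flux-out fluxes.tsv
pumpleak rvd-limit --cl-iso 45
pumpleak density2water 1.045
```

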