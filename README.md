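# shgkin

Cross-membrane transport kinetics and monolayer mechanics from
second-harmonic-generation (SHG) scattering of dye-loaded lipid vesicles.

## The problem

How fast does a small charged molecule cross a lipid bilayer, and how high is
the energy barrier?  SHG scattering answers this label-free and in real time:
a cationic SHG-active dye added to a vesicle suspension adsorbs on the outer
leaflet and forms a net-oriented layer that scatters coherently at the second
harmonic.  As the dye flips within the outer leaflet and then translocates to
the inner leaflet — where its orientation is anti-phased and cancels the
outer signal — the SHG field decays.  The decay time constants are therefore
direct kinetic read-outs of membrane permeation, and their temperature
dependence gives the activation energy.  `shgkin` is for membrane
biophysicists and formulation scientists who want that analysis chain as
tested, scriptable code.

## The model

The SHG field `E = sqrt(I)` (square root of the corrected, background-
subtracted scattering intensity) is fitted past its post-addition maximum
with a double exponential,

    E(t) = A0 + B1·exp(−(t−t0)/τ1) + B2·exp(−(t−t0)/τ2),   τ1 < τ2,

where τ1 is the fast flip-embedding constant and τ2 the slow cross-membrane
transport constant.  The transport rate k = 1/τ2 across several temperatures
yields the activation energy through the Arrhenius equation,

    ln k = ln A − Ea/(R·T),

by linear regression of ln k on 1/T.  A mechanistic four-state rate-equation
chain (solution → adsorbed upright → flipped → inner leaflet, with optional
back-rate) is provided as the generative counterpart, solved in closed form.
Monolayer packing is quantified from pressure–area isotherms via the
compressional modulus Cs⁻¹ = −A·dπ/dA.

Raw counts are corrected before anything else: multiply by the extinction
factor, subtract the hyper-Rayleigh background of dissolved dye, then take
the square root.

Because no public SHG trace data exist for this assay, the package ships a
synthetic-experiment generator (`shgkin.synthetic_data`) that emulates the
full measurement — adsorption rise, bi-exponential decay with a planted
Arrhenius law, Poisson photon counting, extinction attenuation,
hyper-Rayleigh floor, an overnight anchor bin, and anchored liquid-expanded
isotherms — so every stage is testable end to end.  See `docs/methods.md`
for the model details and defaults.

## Worked example

Simulate a DOPG giant-vesicle experiment (five temperatures, planted barrier
68 kJ/mol), then run the full pipeline on the written trace tables:

```sh
$ shgkin simulate --preset dopg_guv --seed 7 --out demo
wrote 5 traces for dopg_guv (planted Ea = 68.0 kJ/mol) to demo

$ shgkin fit-transport --in demo --seed 7 --out demo_fit
Ea = 67.93 ± 0.19 kJ/mol (n=5, R² = 1.0000)
```

The recovered barrier is within 0.1 kJ/mol of the planted 68 kJ/mol: the
uncertainty is the standard error of the Arrhenius slope over the five
per-temperature fits, and R² confirms the (1/T, ln k) points are collinear.
`demo_fit/fits.csv` holds the per-temperature decay fits (τ1, τ2, rate,
convergence flags) and `demo_fit/arrhenius.csv` the barrier; both embed the
seed and a config hash for provenance.

The same works in Python:

```python
from shgkin.cli_io import RunConfig, run_transport_pipeline

result = run_transport_pipeline(RunConfig(preset="dopg_suv", out_dir="out", seed=1))
print(result["arrhenius"].Ea)   # ~114 kJ/mol: high-curvature SUVs resist transport
```

Isotherm analysis:

```sh
$ shgkin isotherm --preset cardiolipin --seed 0 --out demo_iso
cardiolipin: area at 25 mN/m = 130.22 Å²
```

i.e. the mean molecular area of cardiolipin at 25 mN/m surface pressure
(130 Å² planted; the 0.2 Å² offset is the trough sensor noise), with the
compressional-modulus curve and the pressure-window ranking written to
`demo_iso/`.

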