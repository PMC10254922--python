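# Methods

`shgkin` estimates how fast a cationic, SHG-active dye crosses lipid bilayer
membranes, from second-harmonic-generation (SHG) scattering time traces of
dye-loaded vesicle suspensions, and how rigidly the corresponding lipid
monolayers pack, from Langmuir pressure–area isotherms.  This note records
the models, the defaults and their rationale, the numerical choices, and what
the synthetic experiments do and do not establish.

## Measurement model

SHG is coherent and interface-specific: dye free in solution is isotropically
oriented and contributes only an incoherent hyper-Rayleigh floor, while dye
adsorbed on the vesicle surface forms a net-oriented layer that scatters at
the second harmonic.  Dye that has crossed to the inner leaflet is oriented
oppositely, so its field contribution is anti-phased and cancels part of the
outer-leaflet signal.  The observable therefore rises within seconds of dye
addition (adsorption), then decays in two phases: a fast phase attributed to
flip-embedding of adsorbed dye within the outer leaflet, and a slow phase
attributed to translocation across the bilayer.

The detected counts per bin are modelled as Poisson with mean

    lambda(t) = (E(t)^2 + hrs_level) / extinction_factor

where `E(t)` is the coherent SHG field, `hrs_level` the hyper-Rayleigh floor,
and `extinction_factor >= 1` the attenuation by sample absorbance at the
fundamental and second harmonic.  The analysis inverts this chain in fixed
order — multiply by the extinction factor, subtract the floor, clamp at zero,
take the square root — because the background is incoherent *intensity* that
sits on the attenuated signal.  The zero clamp before the square root keeps
Poisson undershoot from producing complex fields.

## Phenomenological decay model

Post-peak fields are fitted with

    E(t) = A0 + B1 exp(-(t - t0)/tau1) + B2 exp(-(t - t0)/tau2),  tau1 < tau2

with `t0` fixed at the detected field maximum (fitting `t0` is degenerate
with `B1`; the peak is a measured feature of the trace).  The transport rate
is `k = 1/tau2`, with the delta-method error `se(k) = se(tau2)/tau2^2`, and
the activation energy follows from the Arrhenius law `ln k = lnA − Ea/(R T)`
by linear regression of `ln k` on `1/T` (`Ea = −slope·R`, reported in kJ/mol,
R = 8.314 J mol⁻¹ K⁻¹, joule→kilojoule conversion applied exactly once at the
reporting boundary).  The regression is unweighted by default; weighting by
`(k/se_k)^2` — the inverse delta-method variance of `ln k` — is available.

### Fitting details

* **Ordering.** `tau1 < tau2` is structural: the optimizer works in
  `(tau2, ratio)` with `tau1 = ratio·tau2`, `ratio ∈ (0, 1)`.  Label
  switching is impossible, and a swapped user initial guess is canonicalized
  before use.
* **Weights.** Residuals are weighted `1/max(E, 1)`.  For a square-rooted
  Poisson signal the field variance is nearly constant (≈1/4 count), so this
  heuristic over-weights the tail slightly; empirically it leaves the slow
  constant unbiased at the default photon budget while keeping the plateau
  well determined.
* **Initialization.** A two-stage log-linear bootstrap on a moving-average
  smoothed trace: the plateau is the smoothed minimum (the *raw* minimum sits
  several noise sigmas low and would leave a spurious offset in the log
  fit); the slow constant comes from the last two thirds of the contiguous
  stretch still resolved above 3% of the decaying amplitude (adapting the
  tail window to the decay scale rather than the trace length); the fast
  constant from the positive head residual.
* **Multi-start.** The double-exponential surface has a degenerate basin in
  which one amplitude collapses and the freed time constant drifts to its
  bound.  Four deterministic starts (bootstrap plus three log-normally
  perturbed copies) are always run and the lowest chi-square kept; further
  restarts occur only while no start has converged.  Bounds: amplitudes
  ≥ 0, `tau2` ≤ 10× the fitted window length.
* **Overnight anchor.** One long-time bin (12 h by default) is included in
  the fit; it pins `A0` when `tau2` exceeds the acquisition window (the
  anchor halves the plateau's standard error in the regime tested).

## Mechanistic chain

The generative mechanism is a linear four-state chain

    solution --k_ads--> upright --k_flip--> flipped <--k_back-- inner
                                  flipped --k_trans--> inner

solved in closed form by eigendecomposition of the rate matrix; when two
eigenvalues coincide within a relative gap of 1e-12 the solver evaluates the
matrix exponential per grid point instead (exact in the degenerate limit).
The observable is `E = scale · max(0, w_up·n_up + w_flip·n_flip + w_in·n_in)`
with `w_up = +1` by convention and `w_in < 0` (anti-phased inner leaflet);
the clamp at zero encodes the convention that cancellation can null the
field but not drive it negative.

Because `w_in = −1`, any template with a negative flip weight has a negative
equilibrium coherent sum once the upright state drains, i.e. a clamped field.
The preset templates therefore use a *positive, reduced* flip weight
(`w_flip = +0.4`: flipping attenuates the molecule's contribution without
anti-phasing it) and a back-rate `k_back = k_trans/w_flip`, which makes the
equilibrium field exactly zero.  The slow eigenmode `k_trans + k_back` then
reproduces the late mono-exponential decay, and the post-peak mechanistic
field is captured by the bi-exponential model to ≲0.2% relative residual.
The bare `KineticParams` type retains `w_flip = −0.6` as its default for
exploring stronger cancellation; such configurations clip at zero in finite
time and are not used as generator presets.

Phenomenological (direct bi-exponential) sampling is the default generator
because measured traces are fitted phenomenologically; mechanistic mode would
add model error by design and is used for consistency tests.

## Synthetic experiment defaults

| parameter | default | rationale |
|---|---|---|
| temperatures | 294.15–318.15 K, 6 K steps (5 points) | lab temperature (21 °C) up through mild heating |
| bin width / duration | 1 s / 3600 s | resolves the seconds-scale rise and the hours-scale tail |
| overnight anchor | one bin at 43 200 s | pins the plateau for slow decays |
| counts at peak | 1e4 per bin | bright-but-realistic photon-counting budget |
| hyper-Rayleigh floor | 2% of peak counts | background present but small |
| extinction factor | 1.25 | moderate sample absorbance |
| rise | saturating exponential, maximum at t0 = 30 s, tau_rise = t0/6 | "rapid adsorption over seconds" |
| amplitude split A0 : B1 : B2 | 0.15 : 0.35 : 0.50 of the peak field | partial fast cancellation, dominant slow phase, nonzero plateau |
| reference rate | k(306.15 K) = 1/600 s⁻¹ for every preset | slow decays of minutes at mid-grid; `lnA` then follows from each preset's Ea |

Preset activation energies: the DOPG pair (GUV 68, SUV 114 kJ/mol) is the
quantitatively established curvature contrast and the package's recovery
benchmark.  POPG (GUV 45, SUV 47) and cardiolipin (GUV 72, SUV 65) and the
50%-cholesterol variants (90/70/95) are placeholders ordered by the
qualitative findings — POPG well below DOPG and nearly curvature-independent,
cardiolipin GUV slightly above DOPG GUV with its SUV slightly below, and
cholesterol raising every barrier — and are trivially editable in
`synthetic_data.PRESETS`.  All lie inside the 28–128 kJ/mol span reported
for small organics crossing vesicle membranes.

Per-temperature seeds are spawned from the experiment seed through a
`SeedSequence`, so a whole experiment reproduces from one integer and no
global random state exists.

## Isotherms and compressional modulus

The generator produces liquid-expanded-phase isotherms
`pi(A) = pi_max · exp(−(A − A_min)/lambda)` with `A_min` chosen so that
`pi = 25 mN/m` exactly at the prescribed mean molecular area (130 Å² for
cardiolipin, 66 Å² POPG, 69 Å² DOPG), plus additive Gaussian sensor noise
(sd 0.2 mN/m — trough pressure sensors have additive, not counting, noise).
The analytic modulus `Cs⁻¹ = (A/lambda)·pi(A)` is stored as truth.  The decay
lengths (cardiolipin 25, POPG 28, DOPG 15 Å²) make POPG the softest monolayer
in the 20–30 mN/m window, matching the rigidity ranking the modulus analysis
must reproduce.

`Cs⁻¹ = −A·dpi/dA` is estimated by a local quadratic fit in a sliding
11-point window (a Savitzky–Golay-style derivative that tolerates the
slightly non-uniform area grid); half-window edge points are excluded rather
than padded, because one-sided stencils bias the derivative exactly where the
curve is steepest.  Doubling the window moves interior moduli by <2% on
noiseless data.

`area_at_pressure` first enforces a monotone non-increasing envelope
(running minimum along increasing area), then interpolates the area linearly
in `(A, ln pi)`.  Log-linear interpolation is exact for the exponential
generator — no pre-smoothing is applied, since a local-polynomial smooth
would bias the noiseless anchor — and under the default noise the lookup at
25 mN/m stays within ±0.3 Å² of truth in ~95% of seeds.

## Numerical choices and degenerate inputs

* Eigenvalue-degeneracy fallback threshold: 1e-12 relative (matrix
  exponential per time point beyond it).
* Peak detection: argmax of a 5-bin moving-average smoothed field, ties to
  the earliest bin; a maximum on the final point means no decay phase and is
  an error.  Monte-Carlo calibration at the default photon budget puts the
  detection within ±6 bins of the true maximum in >95% of seeds; the rise
  side is flat near the top, so errors skew slightly early, where the field
  is within ~0.5% of the peak and the fitted constants are insensitive to
  the offset.
* Zero clamps: background subtraction and the coherent field sum clamp at
  zero; both conventions are stated at the operation.
* Temperatures are stored in °C on disk and kelvin in memory, converted
  exactly once at the I/O boundary.
* Table round trips write floats with `%.17g` and read with pandas'
  round-trip parser; round trips are bit-identical.

## What the synthetic data do not emulate

The generator is model-matched to the analysis: traces are (mostly) drawn
from the same bi-exponential family the fits assume, with exactly known
instrument constants.  Passing recovery tests therefore validates the
inference machinery — correction order, fit parameterization, error
propagation, regression — under realistic counting noise, not the adequacy
of the bi-exponential model for real vesicle suspensions.  Not emulated:
photobleaching and laser power drift, vesicle size polydispersity and
sample-to-sample concentration variation, temperature-control error,
correlated detector noise and dead time, scattering-geometry effects, and
any uncertainty in the extinction correction itself (the pipeline inverts
the true planted constants).  Problem sizes used by the validation runs —
50 seeds × 5 temperatures per preset for barrier recovery, 100 random
parameter draws for the solver oracle, 50 seeds for detection and lookup
calibrations — were chosen to make Monte-Carlo means stable to well below
the asserted tolerances.

## Known limitations

* The fast constant `tau1` is weakly identified when `tau2/tau1 ≲ 4`
  (hottest presets); its median error is a few percent but individual fits
  can trade amplitude between components.  The slow constant, which carries
  the physics, stays within ~1%.
* The weighted decay fit uses a heuristic variance model (see above), not a
  full Poisson likelihood.
* Spectrum-mode extinction correction is a plain Beer–Lambert product at the
  fundamental and second harmonic with a user-supplied effective path length;
  scalar-factor mode is the default.
* Only compression-branch isotherms are handled; no hysteresis analysis.
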