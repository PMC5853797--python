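# Methods

## Scope and data model

The package analyses two synchronised signals from whole-plant imaging:

* a **reflectance trace** `R(t)` with dark baseline `R₀`, carrying the
  chloroplast-movement signal as relative reflectance `x = (R − R₀)/R₀`;
* a **pulse-fluorescence series** — dark-adapted `(F₀, F_M)` plus per
  time point `(F_S, F_M′)` and optionally `(F_M″, t″)` — carrying the
  photosynthesis signal.

All times are minutes from photoperiod start; intensities are
µmol photons m⁻² s⁻¹ throughout. `R₀` is fixed once per experiment (the
last dark sample), not re-baselined per dark period.

## Light regimes

Three templates are built programmatically:

* **Photorelocation ladder** — alternating 60-min dark/light steps with
  intensities 10, 50, 100, 250, 500; the accumulation read-out falls at
  120 min (end of the 10 µmol step) and the avoidance read-out at 600 min
  (end of the 500 µmol step). Ladder and step length are configurable.
* **Five-day protocol** — 16-h photoperiods: Days 1 and 4 constant
  100 µmol; Day 2 an hourly-discretised half-sine peaking at 500; Days 3
  and 5 repeat each Day-2 ambient hour as 40 min ambient + 20 min at
  exactly twice the ambient intensity ("fluctuating" steps). The
  discretised sinusoid is renormalised so its two mid-photoperiod steps
  equal the peak exactly.
* **Single fluctuating day** — the Day-3 schedule alone, the template for
  dual-imaging experiments.

Regime invariants are enforced at construction: contiguous non-overlapping
steps, dark ⇔ zero intensity, and every fluctuating step exactly double
its preceding ambient step.

## Movement forward model

Relative reflectance relaxes first-order toward a light-dependent target:

```
dx/dt = (x*(I) − x)/τ(I)
x*(I) = −A_acc·I/(I + K_move)                         0 < I ≤ I_switch
x*(I) = +A_avoid·(I − I_switch)/((I − I_switch) + K_move)   I > I_switch
x*(0) = 0,  τ = τ_acc / τ_avoid / τ_dark by branch
```

This is the simplest kinetic model producing the saturating, reversible
accumulation/avoidance traces the assay measures; no mechanistic claim is
attached to it. Because the light is piecewise constant on the 1-min
sampling grid and the ODE is linear, each step is advanced with the exact
exponential update `x ← x* + (x − x*)·exp(−Δt/τ)`; there is no integration
error, and closed-form checks hold to rounding. Measurement noise is
additive Gaussian on `x` per sample.

## Quenching forward model

qE responds instantaneously to intensity; qI integrates damage above a
threshold against first-order repair:

```
qE(t)  = qE_max·I/(I + K_qE)
dqI/dt = k_dmg·max(0, I − I_crit) − k_rep·qI,   qI(0) = 0
Φ_II   = φ_max·K_φ/(K_φ + I) / (1 + β_qI·qI)
NPQ    = qE + qI
```

advanced with the same exact per-step update. No xanthophyll-cycle (qZ)
state is modelled; the slow component is lumped into qI.

## Observation model

Intrinsic yields follow Stern–Volmer quenching of the dark-adapted
maximum: `F_M′ = F_M/(1 + qE + qI)`, `F_M″ = F_M/(1 + qI)` (the F_M″ flash
is placed 10 min into the following dark relaxation, by which qE has fully
relaxed and qI persists; the interval is configurable),
`F_S = F_M′·(1 − Φ_II)`, `F₀ = F_M·(1 − φ_max)`. Each in-the-light yield
is multiplied by the light-reception factor `(1 + m·x)` with `x` at that
yield's own measurement time; the dark pair is emitted unmodulated. This
forward model is the exact algebraic inverse of the correction equations,
which is what makes the exact-inversion test meaningful: on noiseless data
the corrected quantities must reproduce the intrinsic ones to rounding.
The sign/mechanism of the yield–reflectance relationship is not modelled —
only the linearised algebraic relationship with slope `m` is assumed, and
`m` is treated as an empirical calibration constant (default 1.0,
estimable by origin-constrained OLS; both variables are changes from the
same baseline, so a free intercept would only absorb baseline error).
Fluorescence noise is multiplicative Gaussian with coefficient of
variation `cv_noise`; every stochastic output takes an explicit seed and
uses its own generator stream, so runs are bit-reproducible.

## Image path

Bursts of 30 frames per time point (matching rapid-burst acquisition
practice) are rendered as a disk-shaped plant of level `R(t)` on a darker
background with i.i.d. Gaussian pixel noise. Analysis averages each burst
pixelwise, segments the plant by global Otsu threshold — refined by one
intermeans step, because with well-separated classes the Otsu criterion is
flat across the empty histogram gap and the raw threshold can hug the
background cluster — keeps the largest connected component, and takes the
masked mean. Burst averaging shrinks the per-pixel noise by √30; the
masked mean of N pixels has standard error `σ/√(30N)`, the yardstick used
when validating trace recovery. No registration or leaf tracking is
attempted: whole-rosette masks only.

## Genotype presets

Presets are data, not logic. The wild type is tuned to produce an
accumulation read-out near −0.07 at 120 min and an avoidance response
saturating near +0.4 under 500–1000 µmol light. The `large` class scales
the avoidance amplitude to 30% of wild type (accumulation to 60%), slows
avoidance onset, and raises the damage rate; `intermediate` uses 65%/80%
scaling; `small` shares every parameter with the wild type. These mirror
the qualitative class structure of chloroplast-division mutants — severe
avoidance loss in large-chloroplast genotypes, partial attenuation in
intermediate ones, wild-type behaviour in the small class — and are not a
fit to any particular measured genotype.

## Analysis conventions

* Read-outs (movement summaries, per-pulse reflectance look-ups) use the
  nearest sample, ties to the earlier sample; a pulse time past the end of
  the reflectance trace carries the last value forward with a warning.
* Reported percentages are rounded half-away-from-zero to one decimal; the
  unrounded value is kept alongside for downstream arithmetic.
* Replicate dispersion is the sample SD (n−1); the significance test is
  the two-sided pooled-variance Student's t-test (Welch available as an
  option), per time point without multiple-testing correction — a
  Benjamini–Hochberg option exists but is off by default, matching the
  per-time-point testing convention of the assay. Zero-variance groups
  are resolved explicitly (equal means → p = 1, unequal → p = 0).
* Heat-map cells are log₂ fold changes of replicate means (base 2 is a
  display choice; significance is base-free); cells whose wild-type or
  mutant mean falls below a configurable floor (10⁻⁶) are emitted as
  missing rather than clipped. Negative computed quenching values under
  noise are reported as-is; clipping would bias replicate means.
* The pigment module consumes concentration tables (µg g⁻¹ FW and
  pigment ratios); it does not compute concentrations from absorbances.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
instances chosen as the smallest sizes that exercise every code path with
stable statistics: single-day simulations on a 1-min grid (1441 samples),
10⁴ random inputs for the algebraic identities, 100 seeds × 200 points for
slope recovery, 1000 random small samples for the t-test oracle, and
11-point image stacks of 30 frames at 64×64 pixels.

## Known limitations

* Movement and damage kinetics are phenomenological first-order models;
  real traces show multi-phase kinetics the single time constant cannot
  reproduce.
* The multi-day template simulates days independently (movement and qI
  reset overnight); slow acclimation and incomplete overnight repair are
  outside the model.
* The reception correction is linear in `x`; strong movement with |m·x|
  approaching 1 leaves its domain and is rejected rather than
  extrapolated.
* Replicate variability in simulations arises from measurement noise
  only; biological between-plant variance is not modelled, so simulated
  p-values are optimistic relative to real experiments.
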