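# chloroquench

Analysis pipeline for **dual imaging of chloroplast photorelocation and
chlorophyll-fluorescence quenching** in whole plants, with a synthetic-data
generator that makes every stage verifiable end to end.

## The problem

Plants reposition their chloroplasts with light: under weak light the
chloroplasts spread along the periclinal cell walls to harvest more photons
(*accumulation*), under strong light they stack along the anticlinal walls
to shade each other (*avoidance*). Movement is read out non-invasively as
whole-plant red-light reflectance — accumulation decreases reflectance,
avoidance increases it — quantified as the relative reflectance
`x = (R − R₀)/R₀` against the dark baseline `R₀`.

The same movement is a systematic error source for pulse-amplitude
fluorescence phenotyping. The standard saturation-pulse parameters are

```
Φ_II   = (F_M′ − F_S)/F_M′          PSII operating efficiency
NPQ    = F_M/F_M′ − 1               non-photochemical quenching
qE_SV  = F_M/F_M′ − F_M/F_M″        fast, energy-dependent component
qI     = F_M/F_M″ − 1               slow, photoinhibitory component
```

with `F_M` from the dark-adapted plant, `F_M′` flashed in the light and
`F_M″` flashed after a short post-illumination dark relaxation.
`NPQ = qE_SV + qI` identically. Φ_II is a ratio of two yields taken in the
same optical state, so movement cancels out of it; NPQ and its components
compare yields across optical states and are **biased whenever the
chloroplasts have moved**. The fix is a per-pulse correction from
simultaneously imaged reflectance:

```
c′ = 1 + m·x′      x′ at the F_M′ time        NPQ_corr  = c′·F_M/F_M′ − 1
c″ = 1 + m·x″      x″ at the F_M″ time        qI_corr   = c″·F_M/F_M″ − 1
                                              qE_SVcorr = c′·F_M/F_M′ − c″·F_M/F_M″
```

where `m` (≈ 1 for Arabidopsis) is the slope of relative fluorescence-yield
change on relative reflectance change, estimable from calibration data with
`estimate_m` (origin-constrained OLS).

The package is written for phenotyping of chloroplast *division* mutants —
genotype classes with large / intermediate / small chloroplasts whose
avoidance responses range from ~25% of wild type to indistinguishable — and
ships a forward simulator of those classes, the reflectance image pipeline
(burst averaging, Otsu segmentation, masked means), the quenching formulas,
the movement correction, and replicate-level genotype-vs-WT statistics
(pooled t-tests, log₂ fold-change heat maps, percent-of-WT pigment tables).

## Worked example

```python
import chloroquench as cq

day = cq.build_single_fluctuating_day()        # 16 h, hourly ambient + 2× spikes
mut = cq.get_profile("large")                  # large-chloroplast preset

trace, truth = cq.simulate_experiment(day, mut, noise_sd=0.005, seed=1)
pulses = cq.render_observed_pulses(
    truth, cq.ReflectanceTrace.from_relative(truth.frame["time_min"],
                                             truth.frame["x"]),
    m=1.0, cv_noise=0.02, seed=2)

apparent  = cq.process_series(pulses)                 # movement-biased
corrected = cq.correct_series(pulses, trace, m=1.0)   # movement-corrected

mid = apparent.frame["time_min"].between(420, 540)
print(apparent.frame.loc[mid, "npq"].round(3).tolist())
print(corrected.frame.loc[mid, "npq"].round(3).tolist())
```

prints, for the four mid-day pulses,

```
[2.567, 3.295, 2.936, 3.296]     # apparent NPQ
[2.989, 3.768, 3.36, 3.811]      # corrected NPQ
```

against simulator truth `[3.084, 3.652, 3.301, 3.848]`: the apparent values
are biased low by ~0.4–0.5 because avoidance movement (x ≈ +0.1 in this
mutant) inflates `F_M′`, and the correction removes most of that bias. A
movement summary over the standard dark/light ladder (read-outs at 120 min
for accumulation, 600 min for avoidance),

```python
ladder = cq.build_photorelocation_regime()     # dark/10/50/100/250/500 ladder
traces = {g: [cq.simulate_movement(ladder, cq.get_profile(g), 0.005,
                                   seed=10 * i + r)[0] for r in range(6)]
          for i, g in enumerate(("WT", "large"))}
print(cq.movement_table(traces, "WT"))
```

gives accumulation −0.071 (WT) vs −0.043 (large) and avoidance 0.246 vs
0.058 — the mutant retains 23.6% of the wild-type avoidance response
(p < 1e-10, pooled t-test). Pigment bookkeeping works from the shipped
summary table: `cq.pigment_summary()` reports, e.g., the *arc6-5*
pre-treatment chlorophyll content as 84.2% of its wild type.

A `chloroquench` CLI exposes the stages (`simulate`, `movement`,
`fluorescence`, `correct`, `compare`, `full-run`) over CSV/TIFF files and a
YAML config; `chloroquench full-run --config cfg.yaml` writes the complete
output tree deterministically for a given seed.

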