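# microedtk

A toolkit for electron-counting MicroED (microcrystal electron diffraction)
data. In counting mode a direct electron detector registers at most one
electron per pixel per raw frame, so rotation diffraction movies must be
collected at ultra-low exposure rates, summed into still images, converted
to crystallographic formats and audited for coincidence loss. `microedtk`
covers that pipeline end to end on synthetic data:

- **detector model** — per-frame binarized counting, periodic reset frames,
  a seeded Monte-Carlo simulation of the coincidence-loss DQE with its
  closed-form occupancy oracle, and per-pixel lifetime damage accounting;
- **movie synthesis** — continuous-rotation counting movies (parametric
  Bragg spots with Gaussian rocking curves and footprints, plus Poisson
  background) and flat-field exposures for flux calibration;
- **geometry & dose** — relativistic electron wavelength, rotation wedges,
  per-image oscillation, inverse-square beam-diameter dose scaling,
  selected-area geometry, resolution at a detector radius, and flux
  estimation from flat-field counts;
- **conversion** — bit-exact counting-stack → SMV stills (×32 gain scaling,
  half-away-from-zero rounding, 16-bit saturation, last-image discard),
  plus TIFF export and a minimal MRC2014 stack reader/writer;
- **quality statistics** — merging statistics (R_merge, R_meas, R_pim,
  CC½, CC*, multiplicity, completeness, ⟨I/σ⟩) on multi-observation
  reflection sets, occupancy histograms annotated with expected DQE, and
  spot line profiles with peak-over-background summaries.

## The model in brief

For a pixel receiving `n` electrons spread uniformly over `F` raw frames,
the counted output is the number of occupied frames, so the detective
quantum efficiency of counting is the occupancy ratio

```
DQE(n) = E[N_out]/n = (F/n) · (1 − (1 − 1/F)^n),
```

which is 1 at `n = 1` and decreases monotonically as electrons start to
share frames. The Monte-Carlo simulator draws frame assignments directly
and must agree with this closed form; every other module (movie generator,
flux calibration, occupancy histogram) rides on the same counting rule.
Merging quality uses the standard unmerged-intensity statistics, e.g.

```
R_merge = Σ_h Σ_i |I_hi − ⟨I_h⟩| / Σ_h Σ_i I_hi,   CC* = √(2·CC½/(1+CC½)).
```

## Worked example

```python
from microedtk import (AcquisitionPlan, DetectorSpec, rotation_coverage,
    generate_reflection_schedule, simulate_movie, simulate_flat_field,
    estimate_flux, total_dose, stack_to_smv, pixel_histogram_dqe,
    simulate_dqe_curve)

# a scaled-down 8 s acquisition on a 128-px detector
plan = AcquisitionPlan(rotation_rate=0.2, exposure_time=8.0,
                       summation_window=1.0, pixel_size_mm=0.028)
spec = DetectorSpec(width=128, height=128)

print(round(plan.wavelength, 6))              # 0.019687   (Å at 300 kV)
print(rotation_coverage(0.2, 8.0).degrees)    # 1.6        (deg)
print(plan.osc_per_image)                     # 0.2        (deg per image)

ff = simulate_flat_field(plan, spec, flux=0.4, illuminated_area=2e4, seed=1)
flux = estimate_flux(ff, 2e4)
print(round(flux, 5))                         # 0.40045    (e-/Å²/s recovered)
print(round(total_dose(plan.with_flux(flux)), 4))  # 3.2036 (e-/Å² budget)

schedule = generate_reflection_schedule(40, plan.total_rotation,
    intensity_scale=150.0, seed=1, start_angle=plan.wedge_start, spec=spec)
stack = simulate_movie(plan, spec, schedule, background_rate=0.5, seed=2)
print(stack.n_images, stack.total_counts)     # 8 69369    (images, electrons)

print(len(stack_to_smv(stack, plan)))         # 7          (last image discarded)
print(round(pixel_histogram_dqe(stack).min_dqe, 4))  # 0.9478 (worst pixel DQE)
```

The flux estimate lands within Poisson error of the generator's input, the
last still is discarded on conversion as acquired stacks require, and the
occupancy histogram shows the exposure stayed in the near-linear counting
regime (worst-case expected DQE ≈ 0.95). The DQE curve itself:

```python
curve = simulate_dqe_curve([1, 10, 100, 500], n_reps=1000, seed=3)
# n_in=  1  DQE=1.0000 +/- 0.0000
# n_in= 10  DQE=0.9797 +/- 0.0427
# n_in=100  DQE=0.8253 +/- 0.0329
# n_in=500  DQE=0.4323 +/- 0.0090
```

A `microedtk` console script exposes the same operations as subcommands
(`dqe`, `simulate`, `plan`, `convert`, `stats`, `profile`); see
`microedtk --help`.

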