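# Methods notes

## Counting model

The detector operates at `frame_rate` raw frames per second (default 250)
and records at most one electron per pixel per raw frame; every
`reset_period`-th frame (default 32) resets the sensor and carries no image
data. `count_frame` implements the binarization (`min(arrivals, 1)`), and
`sum_frames` partitions counted frames into consecutive summation windows,
dropping reset slots, so total electrons over non-reset frames are
conserved. Reset frames are identified by the 0-based convention
`(i + 1) % reset_period == 0`, i.e. frames 32, 64, … in 1-based counting.

### Coincidence-loss DQE

With `n` electrons assigned independently and uniformly to `F` frames, the
counted output is the number of occupied frames and

    E[DQE] = (F/n)·(1 − (1 − 1/F)^n).

`simulate_pixel_dqe` samples this process directly (sorted integer draws,
chunked to bound memory) and reports the mean and sd over repetitions; the
closed form (`expected_dqe`) is its analytic oracle and is forced to
exactly 1 at `n = 1`, where floating rounding of the power expression
otherwise lands at 1 + 1e-16. The simulation deliberately keeps all 250
frames as candidate arrival slots — resets are not excluded — because the
one-second DQE interval describes the per-pixel counting bottleneck, not
the readout bookkeeping; resets are modeled separately in `sum_frames`.
The default repetition count is 1000; 256 (a common averaging choice for
plotted sd bands) or any other value is a parameter. All stochastic
operations take an explicit seed and use numpy's PCG64 generator;
`simulate_dqe_curve` spawns independent child seeds per occupancy so
per-point results do not depend on evaluation order.

### Damage accounting

The sensor's DQE is specified to deteriorate 10% after a lifetime exposure
of 1.5e9 electrons per pixel. `DamageLedger` tracks raw accumulated
electrons with a single threshold flag and a warning on first crossing.
No degradation law is fed back into the counting simulation — only the
threshold is specified physics; inventing a decay curve would imply
precision the model does not have.

## Synthetic movies

Bragg spots are parametric events, not products of an Ewald-sphere model:
each has a center angle, a Gaussian rocking profile (FWHM `rocking_width`,
default 0.2°, truncated at ±3σ), an isotropic Gaussian detector footprint
(σ default 2 px, truncated at ±4σ and renormalized) and an expected
electron budget drawn from an exponential distribution (the acentric
Wilson intensity distribution) with configurable mean. Per-frame arrival
means are the background rate plus each active spot's budget × (rocking
mass swept this frame) × (footprint weight); arrivals are Poisson and
independent across pixels and frames (no charge sharing, no sub-pixel
event localization, no MTF). Spot positions avoid a central beam-stop disc
whose default radius is 2% of the shorter detector side (≈40 px on a
2048-pixel camera) so the default scales to the small detectors used in
fast simulations; a disc that covers the usable face raises rather than
looping forever.

What the generator does *not* emulate: diffraction physics (unit cells,
mosaicity, absorption, inelastic scattering), detector gain maps, or the
vendor's multi-frame transmission bundling. Passing tests therefore
demonstrate that the counting, conversion, planning and statistics paths
are self-consistent and recover known ground truth — not that the spot
model reproduces real crystal data.

### Problem sizes

Simulations in the test suite and examples run on 32–128 px detectors with
exposures of 2–8 s (500–2000 raw frames). These sizes keep every movie's
ground truth exactly checkable while exercising the identical code path a
full 2048² × 420 s acquisition would take; the frame loop is streamed, so
memory is bounded by one frame block regardless of duration.

## Geometry, dose and flux

Wavelength uses the relativistic de Broglie form with scipy's CODATA
constants. The beam is treated as a uniform (top-hat) disc for dose
purposes, so fluence scales with 1/diameter²; total dose is flux ×
exposure time and is invariant under re-partitioning of the exposure into
summation windows. The selected-area demagnification defaults to 50
(100 µm aperture ↔ 2 µm at the specimen) and is configurable per
instrument. Detector pixel size has no default: it is instrument metadata
and must be supplied before SMV conversion or resolution calculations.

`estimate_flux` divides recorded electrons by illuminated area and the
*effective counting time*: reset frames expose the specimen but record
nothing, so wall-clock exposure overstates counting time by
1/reset_period (3.1% at the default). Stacks carry exact non-reset frame
counts (`frames_per_image`); when absent, wall-clock exposure is used
as-is. Without this correction, flux recovery on synthetic flat fields
would be biased low by exactly the dead-time fraction.

## Conversion conventions

- Gain scaling: stored = round(32 × counts), electrons = round(stored/32),
  both rounding half away from zero (`floor(x + 0.5)` on nonnegative
  input). The two maps are exact mutual inverses on integer counts in
  [0, 2047]; 2048 × 32 = 65536 exceeds 16 bits and saturates at 65535.
  Saturation is the only lossy path and is logged with a clipped-pixel
  count; half-integer quotients (e.g. 48/32) are decided by the same rule
  so downstream parity checks are reproducible.
- SMV dialect: 512-byte ASCII header (`{ KEY=value; … }`, space-padded),
  little-endian unsigned-short payload, ADSC key set (SIZE1/SIZE2,
  PIXEL_SIZE, DISTANCE = nominal camera length × post-column
  magnification, WAVELENGTH, OSC_START/OSC_RANGE/PHI, BEAM_CENTER_X/Y,
  TIME). Beam center defaults to the geometric image center. No pedestal
  is added by default; `pedestal` is available for integration programs
  that expect one.
- The final image of an acquired stack covers a partial window and is
  discarded on conversion (`keep_last` disables this); a one-image stack
  converts to nothing, with a warning.
- TIFF export writes the full stack without discard or rescaling, so the
  stack's total electron content is preserved.
- MRC I/O is a minimal MRC2014 subset (mode-2 float32, little-endian,
  single volume, no extended header) sufficient for unit-gain counting
  stacks, with a plain-text `key = value` sidecar for rotation metadata.

## Merging statistics

R-statistic sums run over reflections observed at least twice (singletons
carry no internal-consistency information and are excluded from both
numerator and denominator, the convention of standard scaling programs);
multiplicity and completeness count every group. Negative intensities are
kept in all sums — flooring would bias the R-statistics. CC½ splits each
multiply-observed group into random halves (seeded permutation; odd groups
drop one observation via the shuffle) and correlates the half means over
groups; at least three usable groups are required, below which the default
is an `InsufficientDataError` and `on_insufficient_cc="nan"` keeps the
R-statistics. CC* = √(2·CC½/(1+CC½)) is NaN (with a warning) for negative
CC½, where the closed form leaves the real line. No resolution-shell
binning is built into the core statistics; shelling is a thin wrapper
concern, applied by passing per-shell observation subsets.

The occupancy histogram aggregates per-pixel counts over one-second
intervals of raw frames (the DQE simulation window), requires uniform
per-image exposure, and annotates each occupancy bin n ≥ 1 with
`expected_dqe(n, 250)`; its `min_dqe` summarizes the worst coincidence
loss plausibly present in the data.

Line profiles average across the short axis of a box; background is the
median of the profile with the central third excluded (configurable in
principle — the exclusion protects the peak), and the reported I/σ treats
short-axis sums as Poisson counts: (peak − background)·m / √(peak·m) for
short-axis width m. Profiles of means are reported for plotting; the σ
estimate deliberately returns to raw counts, since Poisson error applies
to counts, not means.

## Known limitations

- Spot events are independent; overlapping footprints add their arrival
  means, which is correct for Poisson arrivals but ignores that real
  neighboring reflections are correlated through the lattice.
- Damage accounting does not feed back into counting efficiency.
- The occupancy histogram assumes the stack's images align with interval
  boundaries (exposures that divide one second evenly).
- The SMV reader accepts only the dialect this package writes plus minor
  header variations; it is not a general ADSC archaeology tool.
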