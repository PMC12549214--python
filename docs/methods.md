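# Methods

This document records the model, conventions, default parameters, and
numerical choices behind `fibermesi`, plus the known limitations of the
simulator and segmentation.

## Speckle contrast

Spatial speckle contrast is `K = sigma / <I>` computed over a small
neighborhood of a single frame.

- **Sliding window** (`sliding_window_contrast`): a square window (default
  7×7) centered on each pixel; the standard deviation uses the sample
  estimator (`ddof = 1`, N − 1 in the denominator). Pixels whose window
  extends past the image border, and windows with non-positive mean, are
  marked invalid (`NaN`).
- **Nearest fiber** (`nearest_fiber_contrast`): each segmented core
  contributes one sample — its mean intensity over the core's pixels. The
  contrast at a fiber is std/mean (again `ddof = 1`) over the fiber and its
  `k` nearest neighboring cores (default `k = 36`, the population of the
  three surrounding rings of a hexagonal lattice: 6 + 12 + 18). Fibers with
  fewer than `k` neighbors within `max_neighbor_distance` (edge fibers) or
  with a non-positive sample mean are invalid.

The small-sample standard deviation is biased low; with 49 (sliding
window) or 37 (nearest fiber) samples the bias is a few percent of `K`,
which enters `K²` and is largely absorbed by the fitted `beta`. It produces
a common multiplicative offset on absolute contrast, not on relative ICT
between regions or time points, which is what the pipeline reports.

## MESI model and fitting

With `x = T / tau_c`:

```
K²(T) = beta rho² (e^{-2x} − 1 + 2x) / (2x²)
      + 4 beta rho (1 − rho) (e^{-x} − 1 + x) / x²
      + nu
```

- `tau_c` — speckle correlation time; the reported flow index is
  ICT = 1/`tau_c`.
- `rho` ∈ [0, 1] — fraction of detected light scattered by moving
  particles.
- `beta` — instrumentation constant (coherence, pixel/speckle size
  ratio, polarization); through a fiber bundle it also absorbs the fixed
  per-fiber transmission pattern.
- `nu` ≥ 0 — exposure-independent noise floor.

Limits: as `T → 0`, `K² → beta rho² + 2 beta rho (1 − rho) + nu`; as
`T → ∞`, `K² → nu`.

Numerical choices in `fit_mesi`:

- The helper `g(y) = (e^{-y} − 1 + y) / y²` switches to its Taylor series
  below `y = 2e-4`, where direct evaluation loses precision to
  cancellation; the two branches agree to ~1e-10 relative at the switch.
- The solver is SciPy's bounded trust-region reflective least squares
  (`scipy.optimize.least_squares`, TRF), not Levenberg–Marquardt, because
  `rho`, `beta`, and `nu` have hard physical bounds.
- `tau_c` is fitted in log space so the optimizer moves multiplicatively
  across its many-decade range.
- Initialization is deterministic (from the curve's plateau and knee).
  If the first fit converges poorly (large residual or a bound-pinned
  parameter), a small fixed grid of multi-start initializations is tried;
  the best residual wins. No randomness is involved, so fits are
  reproducible.
- A curve needs at least five finite points spanning a non-trivial
  exposure range; otherwise `InputError`.

### Degeneracy and the two-stage / fixed-beta protocols

The free four-parameter fit is ill-conditioned when the data are noisy or
the exposure ladder does not bracket `tau_c` well: `beta`, `rho`, and
`tau_c` can trade off against each other with nearly identical residuals
(in experiments on simulated bundle data, a free fit with residual ~5e-7
still misestimated ICT by tens of percent). Two standard remedies are
implemented:

- **Two-stage shared beta** (`fit_mesi_two_stage`): fit all ROI curves
  freely, average the converged `beta` estimates into `beta_bar`, then
  refit every curve with `beta` fixed to `beta_bar`. If no first-stage fit
  converges, a `RuntimeWarning` is issued and `InputError` raised.
- **Static-reference calibration**: a static scene (no motion,
  `rho = 1`, long `tau_c`) imaged through identical optics has
  `K² ≈ beta` at any exposure, giving an effective `beta` directly;
  `fit_mesi(curve, fixed_beta=...)` then fits only `tau_c`, `rho`, `nu`.
  This is the protocol used in the bundle closure test, where it reduced
  ICT errors from tens of percent (free fit) to 1–3%.

## Fiber bundle handling

### Segmentation

`segment_fibers` detects cores on a flat-field image: Canny edges →
circular Hough transform over the configured radius range → the
accumulator is masked to bright (above-Otsu) pixels before peak finding,
which suppresses "interstitial ghosts" — spurious circle responses
centered on the dark dead space between cores — without discarding true
peaks. Peaks are then deduplicated greedily by accumulator value with an
exclusion radius of `max(r_min, 2 r_min − 1)`: two true cores cannot sit
closer than two minimal radii. A saturated flat-field (many pixels at the
dtype maximum) triggers a `RuntimeWarning`, since clipping flattens the
core profiles the Hough transform relies on.

Each image pixel is assigned to the nearest detected center within the
detected radius (`FiberMap`), so per-fiber intensity is the mean over that
core's pixels.

Known limitation: with very tight packing (dead gaps of ~2 px) combined
with bundle rotation, Canny edges of adjacent cores merge and recall drops
below 100% (e.g. ~90–97% on a 721-core lattice with 5 px cores at 12 px
pitch). At 3 px or more of dead space, or with an appropriately narrowed
radius range, detection is complete (verified up to 5677/5677 cores).

### Flat-field normalization

Segmented cores inevitably include a few dark dead-space pixels, giving
each fiber a fixed transmission-like intensity pattern (~2% RMS in the
simulator). Because the pattern is exposure-independent, it adds a floor
to `K²` that distorts the MESI curve shape. Dividing each fiber's mean
intensity by its flat-field mean intensity before computing contrast
removes the pattern; this mirrors the standard flat-field correction for
real bundles, where core-to-core transmission varies.

## Simulator

`fibermesi.simulate` is a statistical simulator, not a physical-optics
one. Each frame pixel is drawn independently from a Gamma distribution
whose mean is the scene intensity and whose variance matches the MESI
model `K²(T)` for the pixel's region parameters. This reproduces the
first and second moments that the entire analysis chain consumes, with
exact ground truth, at negligible cost. It does **not** emulate spatially
correlated speckle grains, diffraction, partial coherence, detector shot
noise as a separate mechanism (it is folded into `nu`), or temporal
correlation between frames beyond the per-exposure statistics.

Bundle rendering places circular cores on a hexagonal lattice (optionally
rotated), integrates the scene over each core's aperture with area-weighted
supersampling, sets dead space to zero, and renders onto the detector grid
at a chosen magnification.

Flow phantoms: a straight channel of configurable width across a static
background; ICT in the channel is proportional to flow rate with a default
calibration of 200 (1/s) per (µL/min), i.e. `tau_c = 1 / (200 q)`.
`flow_to_mean_speed` converts a volumetric rate and square channel side to
mean speed for reporting.

## Occlusion and clearance rules

`detect_occlusion` operates on an ICT time course (default sampling period
0.3 s per MESI sequence):

- **Occlusion start**: the first time ICT drops below the threshold
  (default 1500 1/s).
- **Clearance**: the first time `t` after the start such that ICT stays at
  or above the threshold for the entire persistence window `[t, t +
  persistence]` (default 60 s), and the record actually extends through
  `t + persistence`. Shorter excursions above threshold are rejected;
  a recovery too close to the end of the record is not declared.

## Default parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| Exposure ladder | 15 exposures, 50 µs – 80 ms, log-spaced | >3 decades brackets `tau_c` from fast flow (~0.1 ms) to near-static (~10 ms) with both plateaus sampled |
| Contrast window | 7×7 | 49 samples: acceptable estimator variance without oversmoothing |
| Nearest fibers `k` | 36 | three full hexagonal rings (6 + 12 + 18) around a core |
| Occlusion threshold | 1500 1/s | midway between the phantom's open-flow and occluded ICT regimes |
| Clearance persistence | 60 s | rejects transient reflow spikes |
| Sequence period | 0.3 s | one full ladder per cycle at realistic frame rates |
| Flow calibration | 200 (1/s)/(µL/min) | places the phantom range 1–10 µL/min at ICT 200–2000 1/s, inside the ladder's sensitive band |

Problem sizes used by the studies and the acceptance script (lattice
rings, frame counts, sequence counts, noise levels) are the package's own
choices, sized so each study finishes in seconds while keeping Monte Carlo
error well below the effect being measured.

## Limitations

- The Gamma moments model omits spatial speckle correlation, so
  window-size effects on estimator correlation are not reproduced.
- Absolute `K` carries the small-sample std bias (~few percent); relative
  and fitted quantities are unaffected in practice.
- Segmentation recall degrades for sub-3-px dead gaps under rotation (see
  above).
- The free four-parameter MESI fit should not be trusted for absolute ICT
  on noisy single-ROI data; use the two-stage or static-reference
  protocols.
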