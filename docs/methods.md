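# Methods

## The measurement and the statistic

A block-design stimulation paradigm — `cycles` repetitions of
`rest_duration` s rest followed by `stim_duration` s stimulation, imaged at
`frame_rate` frames/s — concentrates the evoked hemodynamic signal at the
stimulation fundamental `f_stim = 1/(rest + stim)` and its harmonics.
Spontaneous vasomotion, the dominant physiological background on the exposed
cortex, occupies the very-low-frequency (VLF) band below about 0.04 Hz. The
activity map exploits that separation: for every pixel,

```
ratio(r, c) = P_s(r, c) / P_VLF(r, c)
```

where `P_s` is the one-sided spectral power at the `f_stim` bin and `P_VLF`
is the summed one-sided power over bins with `0 < f < 0.04 Hz`, excluding DC
(mean brightness, not physiology) and, by default, the stimulation bin with a
±1-bin guard. Excluding the stimulation bin from the denominator matters:
the ratio is meant to express evoked power *relative to* the vasomotor
background, and a denominator containing the evoked signal would suppress
exactly the pixels the map is supposed to highlight. The flag
(`exclude_stim_bin_from_vlf`) and guard width are exposed.

The ratio is invariant to global gain (camera digitization, illumination
level), which is why raw 8-bit or 12-bit intensities are analyzed as-is,
converted to float64 but never rescaled.

### Spectral conventions

- Power at bin k is `s_k |X_k|^2 / N` with `s_k = 2` for interior one-sided
  bins and 1 for DC/Nyquist. Consequences used as test oracles: summed
  non-DC one-sided power equals `N · var(x)` (population variance;
  Parseval), and a bin-aligned sinusoid of amplitude `a` carries
  `a^2 N / 2`. An `amplitude` mode (`|X_k|`-based) exists for exploration;
  the ratio map semantics are defined on power.
- No window function by default: the record holds an integer number of
  cycles, so the stimulation component is bin-aligned and a window would
  only smear it into the guard bins.
- `f_stim` must land on an exact DFT bin; otherwise the map computation
  refuses and suggests the nearest record lengths, rather than silently
  mis-assigning leakage.
- The VLF band is half-open, `(0, vlf_max)`: a bin exactly at 0.04 Hz is
  out.

### Detrending and the discrete ramp

Per-pixel linear detrending (least squares, mean + slope) runs before the
FFT by default to keep slow drift from leaking broadband power into the VLF
denominator. One subtlety: a *sampled* sinusoid at an exact bin is not
exactly orthogonal to a discrete linear ramp (`Σ n·sin(2πkn/N) =
−(N/2)·cot(πk/N)`), so detrending perturbs the stimulation-bin power
slightly — under 2 % at the default paradigm (bin 9 of 1080 frames), and
exactly zero for components even-symmetric about the record center. The
tests pin both facts. Detrending is switchable off (`detrend: false`).

## Segmentation chain

1. `z_thresh = mean + k_sd · SD` of the ratio map over trepanation pixels
   only; population SD; strict `>` so a constant map segments to nothing.
   `k_sd` defaults to 1 but is exposed — awake acquisitions are noisier and
   can need a higher multiplier.
2. Area opening: connected components with fewer than `min_size = 10`
   pixels are removed (strictly smaller; a 10-pixel component survives).
   8-connectivity by default, 4 available.
3. The `k = 3` largest remaining components form the activation area; ties
   in size are broken by ascending first raster index, making the selection
   platform-independent.
4. The convex hull is rasterized over true-pixel *centers* (a grid pixel is
   in the hull iff its center is inside or on the hull polygon), so the
   hull is a superset of the mask and hull(hull) = hull. Degenerate inputs
   (empty, single pixel, collinear) reduce to the obvious limits.

The whole chain is equivariant under positive affine rescaling of the map,
so segmentation results are comparable across gains and offsets.

## Comparison

- DICE `2|A∩B|/(|A|+|B|)`; the undefined empty-vs-empty case returns 0 with
  a warning (a silent 1 would fabricate agreement). The reference mask is
  clipped to the trepanation before every comparison.
- The DICE triplet scores the reference against (a) the segmented
  activation, (b) its convex hull, (c) the complete thresholded map.
- Region statistics report median/Q1/Q3 (linear-interpolation quantiles,
  the numpy default; configurable convention documented here as the chosen
  one) and pixel counts over the disjoint partition {reference activation,
  PSC − reference, trepanation − PSC}. Empty regions report NaN with
  n = 0 instead of raising.
- Topographic composition paints per-site activations into one label map in
  listing order; overlapping pixels keep the earliest label, the conflict
  counts are recorded, the raw per-site masks are preserved, and a pairwise
  DICE matrix quantifies inter-site overlap. For single-site topography the
  natural choice is `k = 1` (the largest component per site), which is what
  the somatotopy validation uses.

## The synthetic generator

Per frame `t` and pixel `(r, c)`:

```
I(t, r, c) = B · (1 + A(r, c) · h(t) + v(t) + d(t)) + ε(t, r, c)
```

- `B` — baseline reflectance, arbitrary units, default 128 (comfortably
  inside 8-bit range for the RGB path).
- `A(r, c)` — injected fractional amplitude: `activation_amplitude` inside
  the truth ellipse, 0 outside. Default −0.02 (a 2 % decrease; blood-volume
  increase absorbs more light at the hemoglobin-sensitive band).
- `h(t)` — hemodynamic response in [0, 1]: the stimulus boxcar delayed by
  `response_delay` (2 s) driving a first-order exponential follower with
  `response_tau` (5 s). With a 30 s stimulation epoch the plateau saturates
  (>99 % of the asymptote), so the injected plateau amplitude is
  recoverable to within 1 %.
- `v(t)` — shared vasomotion: sinusoids at 0.008/0.015/0.030 Hz, fractional
  amplitude 0.005 each, fixed phases. Global across pixels, as vasomotion
  is a vascular rhythm, and deliberately *not* bin-aligned — real
  vasomotion is not phase-locked to the record.
- `d(t)` — linear drift, `drift_slope` = 0.002 fractional change per minute
  (~1.8 % over the 9-min default record): large enough to matter if
  detrending were skipped, small against the evoked response.
- `ε` — i.i.d. Gaussian noise, fractional SD `noise_sd` = 0.005.
- Optional motion: per-frame global integer translations up to
  `motion_max_shift` px (default 0), exposed borders filled with baseline.

Truth geometry: trepanation = centered disc (radius 0.42 · min grid side),
PSC = oblique band through it (width 16 px, angle 0.5 rad), activation =
ellipse (semi-axes 12 × 6 px) on the band axis; all parameterizable, and
nesting activation ⊆ PSC ⊆ trepanation is enforced. `somatotopic_configs`
places several activation ellipses at distinct positions along the band to
emulate stimulating different body parts in somatotopic order.

Randomness: one integer seed; the single-channel stack uses stream 0 of
`SeedSequence([seed, stream])`, the RGB red/blue noise stream 1, so the RGB
green channel is bit-identical to the single-channel output (exactly equal
with quantization off, within half a gray level in 8-bit mode). Fixed seed
⇒ byte-identical stacks.

The defaults (128 × 128 grid, 9 cycles of 30 s + 30 s at 2 fps → 1080
frames, 2 % response, 0.5 % noise, three 0.5 % vasomotion components) are
the scenario the validation suite runs: recovery across seeds 0–9, a null
scenario with the response amplitude zeroed, somatotopic ordering across
seeds 0–4. The frame rate is a declared convention — camera exposure times
do not determine it — and any rate that divides the cycle into whole frames
is accepted.

### What the generator does not emulate

No vasculature texture, heartbeat or respiration aliasing, specular
reflections, spatially varying illumination, non-rigid tissue deformation,
or partial-volume blur at activation borders. Passing recovery tests
therefore demonstrates the correctness of the analysis chain under the
stated signal model, not clinical performance on intraoperative video; on
real data the threshold multiplier, registration quality and artifact
handling dominate.

## Design choices that were genuinely open

- **Registration**: deformable registration of a pulsating cortex is
  unspecified and unfalsifiable at this scope; the package ships
  integer-pixel rigid translation via FFT cross-correlation (mean-removed;
  constant frames tie-break to zero shift; borders filled with the frame
  median) as a documented stand-in and extension point.
- **Power vs amplitude**: the map is defined on power, matching the symbol
  semantics (`P_s`, `P_VLF`); amplitude mode is a switch.
- **SD flavor**: population SD; at thousands of trepanation pixels the
  sample/population difference is far below the threshold's sensitivity to
  `k_sd`.
- **dice(∅, ∅) = 0 with warning**, not 1: conservative.
- **Quantile rule**: linear interpolation between order statistics.
- **Coordinate convention**: (row, col), origin top-left, time axis first;
  every writer follows it.

## Numerical notes

- Stacks are float64 in memory; ratio maps are written as float32 TIFF plus
  a float64 NPZ bundle.
- Thresholding uses a strict inequality, so zero-variance maps yield empty
  segmentations rather than full ones.
- Pixels with zero VLF power get ratio 0 and are counted in a diagnostic
  field instead of producing infinities.
- Manifests store SHA-256 checksums with paths relative to the output
  directory; identical config + seed reproduces byte-identical artifacts.

## Problem sizes used in validation

Unit tests run on 16–64 px grids and records of 32–1080 frames; end-to-end
validation uses the full default scenario (128 × 128 × 1080) across 10
seeds for recovery, 10 for the null, and 5 × 3 simulations for somatotopy.
These sizes are the package's declared reference conditions for the
synthetic benchmark.
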