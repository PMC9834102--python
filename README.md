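# ioimap

Stimulation-locked spectral activity mapping for **intraoperative optical
imaging (IOI)** of the exposed human cortex.

During tumor surgery near the primary sensory cortex (PSC), a camera on the
surgical microscope films the cortical surface through the craniotomy while a
body part is stimulated in a block design (e.g. 9 cycles of 30 s rest +
30 s tactile stimulation). Stimulation-evoked increases in cerebral blood
volume darken the tissue at hemoglobin-sensitive wavelengths (568 nm filter,
or the green channel of an RGB camera) by a few percent. Because the paradigm
is periodic, the evoked signal lives at a known frequency, and functional
cortex can be mapped pixel by pixel from the video's spectrum — without
touching the brain.

`ioimap` implements that analysis as a reusable, tested pipeline, together
with a synthetic cortical-reflectance generator so every stage can be
validated against known ground truth:

1. **simulate** — seeded synthetic acquisitions: baseline reflectance, a
   delayed-exponential hemodynamic response inside a true activation region,
   shared vasomotion oscillations (< 0.04 Hz), drift, white noise, optional
   global motion; plus ground-truth trepanation / PSC / activation masks.
2. **preprocess** — green-channel extraction from RGB stacks, integer-pixel
   rigid motion compensation by cross-correlation, per-pixel linear
   detrending.
3. **spectral** — pixelwise FFT; the activity map is the ratio
   `P_s / P_VLF`, where `P_s` is the one-sided power at the stimulation
   frequency `f_stim = 1/(t_rest + t_stim)` (1/60 Hz by default) and
   `P_VLF` is the summed power over the very-low-frequency vasomotion band
   `0 < f < 0.04 Hz` (DC and the stimulation bin ± 1 guard bin excluded).
4. **segment** — threshold at `z_thresh = Ā + s_A` (mean + SD of the map
   within the trepanation), remove connected components smaller than
   10 pixels, keep the 3 largest components as the activation area, and
   rasterize its convex hull.
5. **compare** — DICE coefficients of a reference mask (e.g. fMRI-derived)
   against the activation, its convex hull, and the complete thresholded
   map; median/Q1/Q3 of raw activity values over the three disjoint regions
   {reference activation, PSC minus reference, surrounding}; composition of
   several stimulation sites into one topographic label map.
6. **cli_io** — YAML-configured end-to-end runner with checksummed
   manifests, plus TIFF/PNG/NPZ/JSON readers and writers.

## Worked example

```python
from ioimap import (SimulationConfig, simulate_sequence, detrend_pixelwise,
                    compute_activity_map, segment_activation, dice_triplet,
                    region_statistics, RegionMaskSet)

config = SimulationConfig(seed=7)            # 128x128, 9 x (30+30) s at 2 fps
seq, truth = simulate_sequence(config)
amap = compute_activity_map(detrend_pixelwise(seq), config.paradigm)
seg = segment_activation(amap, truth.trepanation_mask)
dsc = dice_triplet(seg, truth.activation_mask, truth.trepanation_mask)

print(f"frames: {seq.n_frames}, f_stim = {amap.f_stim:.4f} Hz (bin {amap.stim_bin})")
print(f"z_thresh = {seg.z_thresh:.3f}")
print(f"DSC = {dsc[0]:.2f}/{dsc[1]:.2f}/{dsc[2]:.2f} (activation/hull/full map)")
```

prints

```
frames: 1080, f_stim = 0.0167 Hz (bin 9)
z_thresh = 0.397
DSC = 1.00/1.00/1.00 (activation/hull/full map)
```

The 1080-frame record puts the stimulation fundamental exactly on DFT bin 9.
The threshold 0.397 is the mean + SD of the ratio map inside the synthetic
trepanation; with a 2 % evoked response over 0.5 % noise the segmented
activation recovers the injected truth mask perfectly, so all three DICE
variants are 1. Region statistics on the same run separate cleanly — the
activity ratio has median ≈ 2.1 inside the true activation versus ≈ 0.01 in
the rest of the PSC and the surrounding trepanation:

```
reference_activation: median 2.107 (Q1 2.023, Q3 2.200, n=230)
psc_minus_reference:  median 0.011 (Q1 0.007, Q3 0.016, n=1484)
surrounding:          median 0.011 (Q1 0.008, Q3 0.016, n=7366)
```

On real intraoperative data the same chain is driven from files
(multi-page TIFF stack + mask images) through the CLI:

```bash
ioimap run --config pipeline.yaml --out results/
ioimap map --in stack.tif --out mapdir/          # single stages also exposed
ioimap segment --map mapdir --trepanation trep.png --out segdir/
```

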