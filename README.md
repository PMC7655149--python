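# srmtools

A scriptable Python toolkit for super-resolution fluorescence microscopy
post-processing and quality control. It is aimed at microscopists and image
analysts who need the standard corrections and checks around a
super-resolution experiment without an ImageJ session: estimating and
removing lateral stage drift, calibrating and undoing chromatic
misalignment between colour channels, reconstructing super-resolved images
from short fluctuation movies, quantifying how trustworthy a
super-resolution image is against a widefield reference, mapping local
image resolution, and averaging many copies of a structure into a
high-SNR model.

Every algorithm ships with a synthetic-data generator
(`srmtools.synthetic_data`) that produces bead fields, filament scenes and
blinking movies with known ground truth — drift curves, displacement
fields, emitter positions — so every stage of the toolkit is verifiable by
parameter recovery without any microscope data.

## What is inside

| Module | Method |
| --- | --- |
| `drift_correction` | Drift between frames is the peak of the cross-correlation matrix (CCM): the Pearson correlation ρ(u, v) of the two frames at every trial offset, computed exactly over the overlap region via FFT. The integer peak is refined by two-pass bicubic-spline upsampling to 1/f² px, and frames are corrected by analytic bicubic translation. Optional temporal binning raises the inter-frame correlation at very low SNR; a template-refinement pass re-measures each frame's residual against the mean corrected stack. |
| `channel_registration` | The field of view is tiled into blocks; each block's inter-channel shift comes from the same CCM + subpixel peak; the scattered shifts are interpolated into dense shift maps by Shepard inverse-distance weighting, `f(p) = Σ wᵢ dᵢ / Σ wᵢ` with `wᵢ = 1/dist(p, pᵢ)^q`. Accuracy is scored as target registration error (TRE), the RMS residual at held-out beads. |
| `srrf` | Super-resolution radial fluctuations: per frame, *radiality* is computed on a magnification-times-finer grid — ring samples of the intensity-gradient field vote by how close their gradient line passes to the grid point, positive when pointing inward — and the radiality time series is projected by mean (TRA), max (TRM) or lag-1 auto-cumulant (TRAC2). Drift tables are consumed as per-frame grid offsets, never by resampling frames. |
| `squirrel` | Error mapping: fit the resolution scaling function `WF ≈ G_σ ∗ (α·SR + β)` (golden-section on σ, closed-form α, β), then report the per-pixel error map, RSP (Pearson of blurred estimate vs reference; 1 = perfect structural match) and RSE (RMS mismatch; 0 = perfect intensity match). Resolution: Fourier ring correlation with 1/7 threshold, globally and block-wise with neighbour interpolation for blocks without resolvable correlation. |
| `particle_averaging` | Template-driven single-particle averaging: detect bright spots, crop, exhaustively align over rotations and subpixel translations (score = correlation peak), reject poor matches, average accepted particles per channel; poses found on one channel apply to all channels. |
| `image_io` | Multi-page float32 TIFF stacks with pixel-size metadata, `frame,dx_px,dy_px` drift CSVs, 2-page TIFF displacement fields. |

A note the toolkit's docs repeat deliberately: a *good* FRC resolution does
not certify that structures are depicted correctly — it only measures
reproducibility between two realisations. Use the error map and the
resolution map together.

## Worked example

```python
import numpy as np
from scipy.ndimage import gaussian_filter
from srmtools import synthetic_data as syn
from srmtools import drift_correction as dc
from srmtools import squirrel as sq

# simulate a drifting bead movie at peak-SNR 8 (pixel 100 nm)
scene = syn.generate_bead_scene(20, (128, 128), seed=0)
noise = syn.NoiseModel(background_offset=10, gaussian_sigma=3, seed=0)
scene = syn.scale_scene_to_peak_snr(scene, noise, snr=8.0)
truth = syn.random_walk_drift(50, seed=0, max_excursion_px=4.0)
movie = syn.simulate_drift_movie(scene, truth, noise, n_frames=50)

# estimate and correct the drift
table = dc.estimate_drift(movie)
err_nm = np.hypot(table.dx_px - truth.dx_px, table.dy_px - truth.dy_px) * 100
print(f"RMS drift error: {np.sqrt((err_nm**2).mean()):.1f} nm")
corrected = dc.correct_drift(movie, table)

# SQUIRREL quality check of a synthetic SR/widefield pair
sr = syn.render_scene(
    syn.generate_filament_scene(4, (256, 256), 400, seed=1)).frames[0]
wf = gaussian_filter(3.0 * sr + 10.0, sigma=2.0, mode="nearest")
res = sq.error_map(sr, wf)
print(f"RSP = {res.rsp:.6f}, RSE = {res.rse:.2e}, "
      f"fitted blur sigma = {res.fit.sigma_px:.3f} px")
```

Output:

```
RMS drift error: 8.8 nm
RSP = 1.000000, RSE = 7.19e-07, fitted blur sigma = 2.000 px
```

The drift table recovered from the noisy movie deviates from the known
ground-truth drift by under 9 nm RMS at a 100 nm pixel pitch — a tenth of
a pixel-tenth. The second block constructs a widefield image as an exactly
blurred, intensity-scaled copy of the SR image; the fitted blurring
function recovers σ = 2 px and the quality scores sit at their
perfect-match limits (RSP = 1, RSE ≈ 0).

The same pipelines are scriptable from a shell:

```bash
srmtools simulate --kind drift --seed 1 --out movie.tif --truth truth.csv
srmtools drift-estimate --in movie.tif --out drift.csv
srmtools drift-correct --in movie.tif --drift drift.csv --out corrected.tif
srmtools squirrel-error --sr sr.tif --wf wf.tif --out-json metrics.json
```

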