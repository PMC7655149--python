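# Methods

This note documents the models implemented in srmtools, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the conditions under which the package's accuracy figures are
computed.

## Coordinate and sign conventions

One convention is used everywhere: 0-based (row, col) indexing, x = col,
y = row, pixel centres at integer coordinates. A stored shift (dx, dy) —
in a drift table or a displacement field — means *this frame/channel is
displaced by (+dx, +dy) relative to its reference*; correction therefore
resamples at +shift (equivalently, translates content by −shift).
`translate_frame(frame, s)` translates content by +s. All continuous
resampling is cubic B-spline (`scipy.ndimage.map_coordinates`, order 3)
with out-of-domain samples set to 0. Drift tables are always stored
relative to frame 0, whatever the estimation mode.

## Synthetic data: what is emulated

The generator produces the data the estimators are designed for, with
exact ground truth:

* **PSF**: pixel-integrated isotropic 2D Gaussian (error-function
  integrals per pixel), not a sampled Gaussian — correct at small sigma
  and the standard surrogate for an Airy spot. Default sigma 1.5 px.
* **Camera noise**: constant background offset, optional Poisson shot
  noise on signal + offset, then Gaussian read noise. *Peak SNR* is
  defined as the brightest noiseless signal pixel divided by the
  background noise standard deviation `sqrt(offset + read_sigma²)`;
  `scale_scene_to_peak_snr` calibrates emitter intensities against a
  rendered frame so the definition is exact rather than nominal.
* **Drift**: a 2D Brownian path smoothed over ~3 frames and rescaled to a
  requested maximum excursion. Thermal stage drift is strongly
  autocorrelated between consecutive exposures; an unsmoothed per-frame
  random walk with ~0.5 px jumps is not a physical drift trace (and would
  also defeat temporal binning, which presumes intra-bin motion is small).
* **Chromatic warp**: sinusoidal displacement fields with default
  wavelength 4× the field extent — chromatic misalignment varies slowly
  and near-monotonically across a field of view. Amplitude is the caller's
  choice (2 px in the accuracy runs).
* **Blinking**: i.i.d. Bernoulli on/off per emitter per frame — the
  simplest model exhibiting the intensity fluctuations SRRF exploits. No
  dark-state memory, bleaching, or EMCCD gain statistics.

Passing tests on this generator demonstrate correctness of the estimators
under Gaussian-PSF, Poisson–Gaussian, rigid-drift assumptions. They do not
demonstrate robustness to structured background, anisotropic or spatially
varying PSFs, axial drift, or fluorophore photophysics with memory — none
of which the generator produces.

All stochastic operations take an explicit integer seed and are exactly
reproducible.

## Drift correction

The cross-correlation matrix (CCM) holds, for every integer offset within
±`max_shift_px`, the Pearson correlation of the two frames computed
*exactly over their overlap region* at that offset (masked normalised
cross-correlation with zero-padded FFTs). This makes the [−1, 1] bound and
the centre-entry-equals-plain-Pearson property exact, with no wrap-around
or padding bias; an FFT implementation and a brute-force per-offset
oracle agree to 1e−6 in the tests.

Subpixel refinement fits a bicubic spline to the 5×5 neighbourhood of the
integer peak and evaluates it on two successively finer grids (spacing
1/f then 1/f², default f = 10, i.e. 0.01 px resolution). Ties at equal
maxima resolve to the smallest (|dy|, |dx|), then smallest dy, then dx. A
peak on the CCM border cannot be refined and is returned clamped, with a
warning. If the integer peak correlation is already 1.0 the integer shift
is returned as-is: around the cusp-like unit peak of identical images the
spline overshoots and would bias the refinement sideways.

`estimate_drift` adds three accuracy devices around the per-pair core,
all optional:

* **Gaussian prefilter** (default sigma 1.0 px) on the frames before
  correlation — an approximate matched filter for PSF-limited data. The
  best peak-localisation accuracy is obtained slightly below the PSF
  sigma; the filter never touches the corrected output.
* **Temporal binning** (`time_bin`): consecutive frames are averaged
  before estimation and per-frame drift is linearly interpolated between
  bin centres (constant extrapolation at the ends, curve re-referenced so
  frame 0 is exactly zero). Recommended below peak-SNR ≈ 5; at higher SNR
  the interpolation floor costs more than the noise reduction buys.
* **Template refinement** (default 1 pass): correct the stack with the
  current table, build for each frame the leave-one-out mean of the
  corrected frames, and measure each corrected frame's *residual* shift
  against its template, cropping the border band swept by the zero fill.
  Measuring residuals near zero shift cancels the S-curve ("pixel
  locking") bias inherent to interpolation-based subpixel estimators
  (~0.01 px here), and the averaged template removes the reference
  frame's own noise from every pair. Leaving the frame's own data out of
  its template is essential — otherwise its noise locks the estimate onto
  the previous pass's error.

Measured under the standard conditions (20 beads, 128×128 field at
100 nm/px, 50 frames, drift ≤ 4 px, 10 seeds): RMS per-frame error
≈ 17–26 nm at peak-SNR 2 (with bin 3), ≈ 9.5 nm at SNR 6, ≈ 7–8 nm at
SNR 8, ≈ 6 nm at SNR 10 (per-frame estimation). The acceptance script
recomputes the SNR-2 and SNR-8 figures.

## Channel registration

Calibration tiles the bead image into `blocks_per_axis²` equal blocks
(remainders absorbed by the last row/column), estimates each block's shift
with the same CCM + subpixel machinery (channels prefiltered at sigma
1 px), rejects blocks with zero variance or peak correlation below 0.2,
and interpolates the valid samples with plain Shepard inverse-distance
weighting (default power 2, exact at sample centres). Defaults: 5 blocks
per axis, power 2.

Global Shepard weighting is deliberately simple and has a known bias: far
samples never stop contributing, so the field regresses toward the sample
mean between block centres. For a 2 px sinusoidal warp with wavelength 4×
the field this costs ~0.17 px RMS field error — small against the
sub-50 nm TRE target at 100 nm pixels, but the dominant error term.
Anyone needing tighter fields should raise the IDW power or fit a smooth
parametric model; both are outside the present scope.

The displacement field follows the image-resampling convention: it is
indexed by *reference* coordinates, `target = p + field(p)`. Registering
an image samples the target at p + field(p); registering a *point*
therefore inverts that map, done by fixed-point iteration
`p ← target − field(p)` (8 iterations; the contraction factor is the
field gradient, ≲ 0.05 for calibration-grade fields). TRE is the RMS
distance between registered target positions and their reference mates
over beads *held out* of the calibration, in nanometres; RMS (not mean)
is used, consistent with the other error statistics. Fields estimated on
a diffraction-limited grid can be applied to M-times-finer images by
bicubic upsampling of the rasters with values multiplied by M.

Measured: hold-out TRE ≈ 22–25 nm (200 beads, 256×256, amplitude 2 px,
50/50 split, 10 seeds), every seed below 34 nm.

## SRRF

Radiality at a magnified-grid point p: take `n_ring_samples` points on a
circle of `ring_radius_px` (source-pixel units) around p; at each sample
the interpolated intensity gradient defines a line; the sample votes
`±max(0, 1 − d/R)` where d is the perpendicular distance from p to that
line, positive when the gradient points toward p; radiality is the mean
vote clipped at 0. Gradients are centred differences (edge-replicated)
evaluated continuously via bicubic splines; samples whose gradient
magnitude is below 1e−9 of the frame's peak gradient abstain, since their
direction is floating-point noise. Defaults: magnification 5, ring radius
0.5 px, 12 ring samples — a sub-PSF ring with enough angular samples for
isotropy.

This concrete operator is this package's own; it satisfies the defining
properties of radiality-based reconstruction (sharp maxima at PSF
centres, zero on constant images, invariance to affine intensity
rescaling when intensity weighting is off) without claiming numerical
equivalence to any other implementation.

Temporal projections: TRA (mean), TRM (max), TRAC2 — the lag-1 temporal
auto-cumulant `mean[(R_t − R̄)(R_{t+1} − R̄)]` clipped at 0. Under the
i.i.d. blinking model the *expected* lag-1 autocovariance is zero for
signal and noise alike; what separates them after clipping is the
estimator's positive bias, which grows with per-pixel variance and is
therefore much larger on fluctuating-signal pixels. The corresponding
test compares pixel-population means per trial.

Drift is consumed during analysis: the magnified sampling grid of frame t
is offset by the frame's drift so all radiality maps live on a common
grid; raw frames are never resampled, avoiding a second interpolation. An
all-zero drift table is bit-identical to no table.

## SQUIRREL

The resolution scaling function is modelled as an isotropic Gaussian with
an affine intensity map: `WF ≈ G_σ ∗ (α·SR + β)`. Because the kernel is
normalised, α and β have a closed-form least-squares solution for fixed
σ, and σ is found by golden-section search on [0.5, 20] SR px. The search
tolerance is 1e−6 px: the 1D objective costs one Gaussian filter per
evaluation, so the ~40 extra iterations over a coarser tolerance are
cheap, and RSE is *linear* in the σ error near the optimum — a 1e−3
tolerance would leave a residual orders of magnitude above the
perfect-match floor. A pair with no blur between them pins σ at the lower
bound and is flagged (`at_bound`).

Error map = |WF − estimate| per pixel on the SR grid (widefield upsampled
bicubically when grids differ, values preserved so a constant image stays
constant — intensity per unit physical area is conserved). RSP = Pearson
correlation of estimate vs reference; RSE = RMS of the error map ("mean
intensity mismatch" realised as RMS, consistent with the L2 fit).

FRC: rings of width 1 FFT sample up to Nyquist, DC excluded;
`FRC(q) = Re Σ F₁F₂* / sqrt(Σ|F₁|² Σ|F₂|²)` per ring; resolution =
pixel_size / q* at the first crossing below the threshold (default 1/7,
the field's fixed-threshold convention) *from above* — a curve already
below threshold at the lowest ring carries no resolvable correlation.
Non-square images are zero-padded to square. The block-wise map runs the
FRC per tile (default 8 per axis); a tile is valid only if it yields a
crossing *and* the low-frequency quarter of its curve averages at or
above the threshold (noise-only tiles fluctuate above 1/7 at single
rings); invalid tiles are filled by inverse-distance interpolation from
valid tile centres and flagged. `split_halves` provides the standard
odd/even-frame split for building the two realisations from a movie.

Low FRC values (fine resolution) do not imply the structures are
*correct* — only reproducible. Error mapping and resolution mapping are
reported together for that reason.

## Particle averaging

Detection: local maxima of the 1 px Gaussian-smoothed image above
mean + k·std (default k = 4), pruned to `min_separation_px` with the
brightest winning, centres refined by 5×5 intensity centroid. Extraction:
bicubic crops centred on the subpixel positions; positions within half a
box of the border are dropped. Alignment: exhaustive search over
rotations (default step 5°, crop rotated about its centre) with the best
translation per angle from the CCM peak within `max_shift_px`; the pose
with the highest peak correlation wins, is scored by it, and applies to
all channels of the particle. Classification: accept score ≥ threshold
(default 0.5); rejecting everything raises an error carrying the score
histogram. Model building iterates align → classify → average a fixed
number of times (default 3) from a user-supplied (or brightest-detection)
seed template; a fixed iteration count keeps runtime deterministic and
in practice the template stabilises after the second pass.

Averaging N aligned particles reduces background noise ≈ √N; the pose
space is rotation + translation only (no mirror flips); orientation
classes are handled by running the builder once per seed template.

## Accuracy-figure conditions (scripts/acceptance.py)

All figures are computed at desk scale, chosen to finish in seconds to
minutes on one CPU while leaving the statistics meaningful:

* Drift: 20 beads (sigma 1.5 px) in 128×128 at 100 nm/px, 50 frames,
  smoothed random-walk drift with 4 px maximum excursion, offset 10,
  read noise 3, Poisson on; peak-SNR 2 (with temporal bin 3, the
  estimator's low-SNR regime) and peak-SNR 8 (per-frame); pooled RMS
  per-frame error over 10 seeds, reported in nm.
* Registration: 200 beads in 256×256, sinusoidal warp amplitude 2 px
  (wavelength 4× field), 5×5 blocks, IDW power 2, random 50/50
  calibration/hold-out split, pooled RMS TRE over 10 seeds, in nm.
* Error-map limits: 4 synthetic filaments in 256×256; reference
  constructed exactly as `G_2.0 ∗ (3·SR + 10)`; RSP and RSE reported.

All seeds derive from the single `--seed` argument via
`numpy.random.SeedSequence`.

## Known limitations

* Lateral drift and 2D warps only: no axial drift, no rotation, no
  affine/polynomial global registration models.
* Plain global Shepard interpolation limits displacement-field accuracy
  to ~0.1–0.2 px for pixel-scale warps (see above).
* The SRRF operator documents its own functional form; outputs are not
  numerically comparable to other radiality implementations.
* The RSF is a single isotropic Gaussian; measured or anisotropic PSFs
  are not fitted.
* FRC inputs are images; localisation-table (point-list) workflows are
  not supported.
* Particle averaging is 2D, rotation-only, single-template per run.
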