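# Methods

## Stimuli

**Base images.** Natural photographs are emulated by Gaussian noise with a
radially averaged amplitude spectrum `∝ f^(−β)` (default β = 1, the
classic natural-scene statistic), rescaled to [0, 1].  Rasters are square,
default 128 px at 0.025 °/px, so an image spans 3.2° and comfortably
covers a ~1°-radius classical receptive field (CRF).  Synthetic images
share the spectral statistics of photographs but none of their structure
(edges, objects, phase alignment); conclusions about *which* features
drive real neurons do not transfer, only the recoverability of the
analysis itself.

**Bubble masks.** Each mask holds `n = 20` transparent unit-peak Gaussian
windows (σ = 7 px) at i.i.d. uniform centers.  Overlapping windows combine
by the independent-occlusion rule `T = 1 − Π_i (1 − g_i)`, which keeps
transparency in [0, 1] and makes the per-pixel expectation analytic.
Window profiles are evaluated on *circular* pixel distance (they wrap at
the raster edge).  This choice makes expected coverage exactly uniform
across the raster and equal to the closed form

`E[mean T] = 1 − (1 − 2πσ²/N²)^n ≈ 31.6%  (N = 128)`,

matching the ~32% coverage the protocol is calibrated to.  Without
wrapping, edge truncation loses ~7% of window mass and coverage drops to
≈29%, no longer matching the closed form.  The masks' own spatial
correlation (scale ≈ σ√2) is the resolution limit of the method: masks
are upper bounds on the true driving pixels and are never smoothed.

**Gratings.** Sinusoidal gratings (orientation = bar angle, 0° =
horizontal bars, period 180°; 8 orientations × 6 spatial frequencies
0.5–4 c/° × 4 phases by default) are alpha-blended into the mid-gray
background with a trapezoidal radial envelope (full contrast inside 70% of
the raster half-extent, zero at the edge) to avoid boundary transients.

## Synthetic neurons

The generator implements the three mechanism classes the analysis is
designed to dissociate:

`rate = max(0, baseline + gain · (max(0, w_L·L + F − θ) − S))`

* `L` — spectral channel: dot product of the stimulus amplitude spectrum
  with an (orientation × frequency) gain surface, normalized to 1 for the
  neuron's optimal full-contrast grating.  Phase-invariant by
  construction.
* `F`, `S` — localized excitatory / suppressive patch channels.  Two
  forms: a *template* channel (rectified normalized correlation with a
  stored image fragment — a fragment matcher) and an *energy* channel
  (RMS contrast revealed at the patch, normalized to ~1 at full
  visibility of the home fragment).  Suppression subtracts **after** the
  excitatory threshold, so a suppressive feature shown alone pulls the
  rate below baseline (floored at 0) while a blank screen yields exactly
  the baseline — the signature the mask analysis must recover.
  Subtractive rather than divisive suppression is a modeling choice; the
  mask analysis constrains only the sign and location of suppression, not
  its algebra.
* Position coding: the patch sampling location shifts by
  `(1 − v) · gaze offset`, so `v = 0` is retinotopic (driving region
  follows gaze across the image, slope 1) and `v = 1` head-centered
  (slope 0).  The energy form is used for position-coding studies: a
  rigid fragment matcher falls silent once gaze moves its fragment off
  the template, so it cannot express translation *sensitivity* over a
  fixed image.

Spiking is Poisson per frame (expected count = rate × 100 ms) with
lognormal latency jitter (median 100 ms, ~10 ms spread), so the fixed
50–150 ms analysis window captures the bulk of each response.  Eye traces
are truncated-normal per-frame vertical offsets on [−1°, 1°] (horizontal
spread one third of vertical, matching the vertical dominance of the
fixational movements this emulates), with 500 Hz samples around each
frame's modal offset.

Defaults chosen once for adequate recovery signal-to-noise at
desk-scale session lengths (2000–3000 frames/image): feature neurons
baseline 20 sp/s, gain 60, template weights +1.0 / −0.8; quasi-linear
neurons baseline 5 sp/s, gain 250 (masked 1/f images pass only ~9% of the
optimal-grating drive through a narrowband filter, so the gain is set to
give masked-image responses a realistic tens-of-sp/s dynamic range).

## Analyses

**Response window.** `w_n` = spike count in `[onset+50, onset+150) ms` /
100 ms, half-open.  Consecutive windows may not overlap (validated).

**STM significance.** The raw weighted mask average is compared per pixel
with a null ensemble built by permuting responses across frames
(≥ 200 shuffles; default 500–1000).  Pixels inside the central
`1 − α` interval (α = 0.01) are zeroed; survivors are labeled by sign.
Reported weights are null-mean-subtracted, making sign meaningful (the
expectation of the null is the unweighted mean mask).  The wording
"99.5% confidence interval" and "two-tailed α = 0.01" describe the same
rule here; α is configurable.  Because the ~200 independent mask-scale
blocks of a 128² raster make a single session's false-positive rate
noisy, the calibration check averages the significant-pixel rate over
independent replicate sessions.

**Spatial RF.** Probe-map half-max contour (map upsampled ×4, bicubic) fit
with an algebraic (Kåsa) least-squares circle.  **SRF.** Per-(θ, f, φ)
mean rates, phase-collapsed by averaging; cells sampled fewer than
`min_count = 5` times are flagged NaN and excluded downstream.  **OSI** =
`(R_pref − R_orth)/R_orth` on the across-frequency mean tuning curve,
with `R_orth` linearly interpolated 90° from the peak (period-180 wrap);
0 for flat curves, capped (default 100) when `R_orth ≤ 0`.  This ratio
form is adopted because it reproduces the ≫1 values the protocol reports;
the exact formula in the original OSI reference is not restated there.

**Linear model.** SRF normalized to [0, 1] by its maximum; FFT bins mapped
to (θ, f) by bilinear interpolation with 180° wrap; DC and
out-of-grid frequencies get zero gain.  The filter is scaled so the
squared response to the optimal full-contrast grating peaks at exactly 1,
and the `1 − SRF` suppressive filter shares that scale so "the same
threshold" is meaningful.  Area matching is exact up to ties (ties broken
by value, then row-major index).  Orientation power inside a mask uses
the mean-subtracted image, cosine-tapered over 3 px at the set boundary
(distance transform), power summed per orientation bin of the SRF grid.
Image+mask OSI windows the image by the excitatory STM weights and probes
it with the grating set (absolute dot products; max over phase, mean over
frequency).

**Invariance.** Equal-count (rank-based) gaze bins — fixed-width bins
starve the tails of the offset distribution; vertical axis by default.
`min_frames = 100` per (bin × image) before a conditional STM is
attempted.  Slopes are unweighted OLS on ≤ 4 points and carry no
individual significance; inference is at the population level (one-tailed
one-sample t against 1 and against 0, per-mask and per-neuron-averaged,
plus the Pearson correlation of mean slope with CRF radius).  Centroids
use the excitatory component only, |weight|-weighted.

## Numerical and design notes

* Spectral leakage of the windowed gratings (blob width ≈ 0.3 c/° set by
  the envelope) biases the estimated SRF frequency peak upward by up to
  one grid step for low-frequency-preferring neurons; orientation peaks
  are unbiased.  Recovery checks therefore accept a one-grid-step
  frequency error.
* Mask stacks are float32 (a 3000 × 128² stack is ~200 MB); shuffle nulls
  are computed as a single matrix product.  Permutation order changes the
  last bits of float32 sums; tests compare with atol 1e-6.
* All randomness flows through explicitly passed `numpy` Generators;
  identical seeds reproduce sessions, masks and spike trains bit-exactly.
* Problem sizes in the test suite (2000–3000 bubble frames, 3000–5000
  grating frames, 300–1000 shuffles, 3–5 replicates per condition) are
  the package's chosen desk-scale study conditions; they give each
  recovery check a comfortable margin over its tolerance.

## Known limitations

* Synthetic base images lack object structure; template "features" are
  self-referential image fragments, not shape primitives.
* The generator has no adaptation, spike history, contrast gain control
  or divisive normalization; Poisson variability only.
* The energy patch channel confounds revealed contrast with local image
  contrast, which can slightly attenuate invariance slopes toward the
  image's contrast hotspots.
* Suppression is subtractive and output-stage; the analysis cannot
  distinguish this from divisive forms, and neither could the protocol it
  implements.
* Color, surround mapping, temporal kernels beyond the fixed
  latency/window, and second-order (covariance) kernels are out of scope.
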