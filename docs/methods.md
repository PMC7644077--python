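# Methods

This note documents the models, estimators and numerical choices behind
`cellmag`, what the synthetic fixtures do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Video model and conventions

All processing happens on floating intensities in [0, 1] (integer inputs
are divided by their dtype maximum), so thresholds such as the edge
gradient threshold `GTH` and the motion threshold `MTH` are independent of
acquisition bit depth. Coordinates are 0-based `(row=y, col=x)`; ROIs are
half-open rectangles. Angles of motion are measured from the image
vertical (Y) axis: 0° points along +y, 90° along +x. A frame rate is
mandatory — every spectral quantity is expressed in Hz through it — and a
missing rate is an error rather than a default.

## Edge selection

Spectral analysis is restricted to edge pixels of the temporal-mean image,
on the premise that a cell moves mostly at its boundary. For the gradient
operators (Sobel — the default —, Prewitt, Roberts) the mask is the literal
condition `|∇ mean| > GTH`, intersected across channels, and is therefore
monotone in `GTH`. Canny, Laplacian-of-Gaussian and zero-cross are not
magnitude thresholds; they return their native binary maps with `GTH`
passed through as the operator threshold (for Canny the hysteresis pair is
`(0.4·GTH, GTH)`, a convention, not a claim of equivalence). The averaging
window defaults to the whole clip.

## Spectrum estimation

Each edge-pixel trace is mean-removed and its biased sample
autocorrelation `r[τ] = (1/N) Σ x̃[t] x̃[t+τ]`, τ = 0..L−1, is transformed
by a length-L DFT; the real parts are averaged over the M edge pixels and
clipped at zero (rectangular lag truncation can produce slightly negative
estimates). This is a Blackman–Tukey estimator with a rectangular lag
window; a Bartlett taper is available (`taper="bartlett"`) but off by
default. Implementation detail: because averaging commutes with the DFT,
the per-pixel periodogram average is computed in the FFT domain with a
single inverse transform — algebraically identical to the per-pixel path
(the unit tests pin this to 1e-9) and O(M·N log N).

Two DC-suppression mechanisms are applied deliberately: per-pixel mean
removal before the autocorrelation (reduces DC leakage into the lowest
bins at small L) *and* exclusion of the DC bin from the dominant-peak
argmax. The frequency grid is `f_k = k·fs/L`, k = 0..⌊L/2⌋, so the
resolution is one bin, `fs/L`; `L` defaults to `N` and can be shortened
when the motion frequency drifts within a clip. Peak prominence is
`100·(P_dom − P̄)/P̄` over the non-DC bins. Motion above the Nyquist
frequency folds back to `|f₀ − fs·round(f₀/fs)|`; `aliased_frequency`
computes the folded value and warns, and the fixture generator refuses
super-Nyquist drives unless aliasing is explicitly requested.

## Phase-based magnification

The pyramid is a frequency-domain complex steerable pyramid without
spatial downsampling: radial octave rings with one-octave raised-cosine
transitions in log₂ frequency, angular windows `β·cos^(B−1)(θ−θ_b)`, and a
half-plane doubling mask per orientation (the analytic-signal step that
gives coefficients a meaningful local phase). The normalization constant β
is chosen so the squared analysis masks tile the frequency plane exactly;
reconstruction of an unmodified decomposition is exact to floating point,
comfortably inside the 1e-3 RMS contract. Defaults: 4 levels × 4
orientations. Not downsampling trades memory for exactness and simplicity,
which is appropriate for the small fields of view this tool targets.

Per band, the phase is unwrapped along time (frame-to-frame differences
wrapped to (−π, π], then cumulatively summed), band-pass filtered,
optionally smoothed spatially with amplitude-squared weights (Gaussian
σ = 2 px, on by default — phase is unreliable where amplitude is low),
scaled by α and added back. The temporal filter is a zero-phase FFT
band-pass, flat over `center ± half_band` with raised-cosine edges half a
band wide; a recursive band-pass narrow enough to be selective rings
startup transients into clips a few hundred frames long, while the FFT
filter rejects out-of-band frequencies exactly — this is the standard
choice for offline whole-clip processing, and the band-selectivity
property (≤ 20% out-of-band gain at 3·f₀) is tested against it. The
default half band is `max(0.1·f₀, one bin)`. The method is first-order in
phase: the gain law `(1+α)·a` holds while `α·ω_x·a` stays small in the
highest band, which is why the gain-law test drives 0.05 px (so even α=20
stays in the linear regime); larger amplified excursions saturate the
finest scales first.

## Motion directors and phase annotation

The grid follows the literal lattice definition: one-pixel-wide segments
with strictly interior coordinates, so each segment carries l−1 pixels and
the lattice corner pixels belong to no segment; the geometric center is
the mid-length pixel. The motion statistic is the plain sum of absolute
consecutive-frame differences over the segment (time-reversal invariant by
construction); `MTH` is empirical, and `auto_mth` offers a reproducible
default (95th percentile of the statistic over a static control region).

Direction assignment centers four probe lines (l pixels; diagonals are
8-connected chains) on the segment center and takes the rms excursion of
the intensity center of mass in probe-index units, exactly as the
center-of-mass definition enumerates pixels. The index convention matters:
for a boundary feature moving along its normal, the apparent motion along
an oblique probe is geometrically larger by 1/cos ψ, which cancels the √2
physical length of diagonal index steps — measuring in physical pixels
instead would systematically favor diagonal probes on edges. The
assignment is reliable when the probe is centered on the moving feature
(its intended use: segments triggered on a cell edge); for features offset
within the segment the four scores can come close, which is the price of
not computing a flow field. Ties break toward the lowest angle
(deterministic); segments whose scores all fall below 1e-6 are suppressed,
and probes that would leave the frame are skipped with a warning. The
center of mass of a line with total intensity below 1e-12 is defined as 0.

Phase annotation fits a degree-5 polynomial by least squares over the
2·n_fit+1 frames around each time point (n_fit ≥ 3 so the fit is
determined) and takes the analytic derivative's sign; the first and last
n_fit frames reuse the nearest full window rather than shrinking the fit.
The default rendering colors positive derivative red and negative blue;
the color↔expansion mapping is a configuration option because conventions
for it differ, and only the sign-flip timing is contractual.

## Degree of motion and the noise floor

Dense Lucas–Kanade flow: per pixel pair, derivatives from central
differences on the frame average, structure tensor summed over a 5×5
window, 2×2 solve, and flow zeroed where the tensor's smaller eigenvalue
falls below the noise-reduction threshold (default 1e-4 on normalized
intensities). The degree of motion is the flow magnitude summed over all
pixels and frame pairs; flow below threshold is zeroed, which for the sum
is equivalent to excluding it. The noise-floor curve magnifies the sample
and a static control at each α and classifies the sample's motion as real
exactly where it exceeds the control — the control curve itself is the
boundary between the regimes.

## Preprocessing

Both steps are opt-in. Deconvolution is Richardson–Lucy (frames
reflect-padded by the kernel size to suppress FFT edge ringing, output
clipped to [0, 1], never negative); blind mode alternates image and kernel
RL updates from a flat 7×7 initial guess on the first frame, then applies
the estimated PSF everywhere — initial guess and iteration count (10) are
configuration, not claims. Stabilization estimates a per-frame similarity
transform from ORB keypoint matches with RANSAC, refines the translation
sub-pixel by phase correlation, and scores a pure-translation candidate
against the full similarity by registration error, keeping the better:
keypoint quantization can fake ~1° rotations that would otherwise corrupt
the translation by several tenths of a pixel. The transform sequence is
smoothed by a local-linear (Savitzky–Golay, window 5) filter — the
least-squares version of a moving average that is unbiased on linear
drifts including at the clip ends, where a plain moving average biases a
0.5 px/frame ramp by ~0.3 px. Frames whose matching fails inherit the
previous transform with a logged warning. Warping is bilinear with
out-of-frame pixels set to the frame median, so stabilization does not
manufacture border edges for the edge detector.

## Synthetic fixtures

The generator emulates three study conditions: a ring whose radius
oscillates harmonically (Gaussian radial profile, anti-aliased by
construction), a band-limited texture translating sinusoidally with
sub-pixel amplitude — the analog of a fluorescent gel cyclically stretched
by 1 µm seen at 2.77 µm/pixel, i.e. 0.36 px — and a static textured field
with per-frame iid Gaussian intensity noise as the noise control, plus a
constant-velocity drifting field for stabilization tests. Sub-pixel
translation uses Fourier-shift interpolation, exact for band-limited
images, so the injected displacement is unambiguous ground truth; every
fixture returns its ground truth and is bit-identical for identical
spec+seed. Gaussian intensity noise is the default noise model; Poisson
shot noise is available behind a flag.

What the fixtures do **not** emulate: photobleaching, focus drift,
non-rigid deformation, intensity fluctuations from fluorophore expression
(which the magnifier cannot distinguish from motion), structured detector
noise, or any actual cell mechanics. Passing tests therefore demonstrate
the correctness of the estimators and transforms under controlled motion
and noise, not robustness to every artifact of live-cell imaging.

## Problem sizes used in the test and acceptance runs

The frequency-recovery experiment runs at the full stated conditions
(128×128, 480 frames at 24 fps, 20 seeds). The magnification, direction
and noise-floor properties run on 48×48–96×96 clips of 48–96 frames —
sizes chosen so each property is measured well clear of its tolerance
while the whole suite stays quick to iterate on; the measured quantities
(gain ratios, selectivity, recovery rates, curve separations) are
scale-free.

## Known limitations

- First-order phase magnification only; strongly accelerated motions and
  large amplified excursions blur or saturate at fine scales.
- Four-direction assignment is intentionally coarse, degrades for features
  offset from segment centers, and does not track directors over time.
- The spectrum estimator reports one dominant frequency per run; motion
  whose frequency changes requires manual sub-windowing via `L`/`window`.
- Gray-level change is the observable: intensity fluctuations without
  motion are indistinguishable from motion at every stage.
- AVI/MP4 support depends on an ffmpeg-capable imageio plugin; TIFF is the
  reliable interchange format.
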