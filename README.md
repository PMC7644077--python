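# cellmag

Detection, spectral characterization, magnification and annotation of
imperceptible periodic motions of biological cells in time-lapse microscopy
video.

Many non-muscle cells — fibroblasts on glass, cells embedded in soft
hydrogels, cells pulling on micropillar arrays — perform rhythmic sub-micron
movements that are invisible to the eye in raw microscope footage (a 1 µm
oscillation imaged at 2.77 µm/pixel moves the image by 0.36 px). `cellmag`
is a toolkit for microscopists and mechanobiologists who want to find those
motions, measure their frequency, make them visible, and tell them apart
from pixel noise.

## What it computes

The pipeline operates on a `VideoSequence` (T×H×W×C intensities in [0, 1]
with a frame rate) and chains:

1. **Edge selection** — edge pixels of the temporal-mean image, where a
   cell's protrusive/retractive motion concentrates:
   `|∇ mean_t I(x, y, t)| > GTH` in every analyzed channel.
2. **Motion power spectrum** — each edge pixel's intensity trace `x_j[t]`
   is a realization of a random process; the biased sample autocorrelation
   `r_j[τ] = (1/N) Σ_t x̃_j[t] x̃_j[t+τ]` is Fourier-transformed at lag
   length `L` and averaged over the `M` edge pixels (a Blackman–Tukey
   estimator whose variance shrinks with `M`). The dominant oscillation
   frequency is the spectral argmax excluding DC; its prominence (% above
   the mean non-DC power) separates genuinely moving samples from fixed
   ones.
3. **Phase-based Eulerian video magnification** — frames are decomposed on
   a complex steerable pyramid, the local phase of every band is band-pass
   filtered around the chosen frequency, multiplied by α and added back, so
   a sub-pixel displacement `a` re-emerges with amplitude `(1+α)·a` while
   amplitude noise is largely untouched.
4. **Motion directors** — one-pixel-wide grid segments of odd length `l`
   are flagged as moving when `Σ_t Σ_pixels |I[t] − I[t+1]| > MTH`; four
   probe lines 45° apart are centered on each flagged segment and the
   direction with the largest rms excursion of the gray-level center of
   mass `P_θ^CM(t) = Σ_h h·I / Σ_h I` is assigned as the direction of
   movement.
5. **Phase annotation** — on a kymograph of the chosen probe line, each
   frame is labeled expansion/contraction by the sign of the derivative of
   a local 5th-degree polynomial fit to the center-of-mass track.
6. **Noise-floor validation** — dense Lucas–Kanade optic flow sums the
   "degree of motion" of an amplified sample and an amplified static
   control as a function of α; amplified motion is trusted only where the
   sample curve exceeds the control curve.

A seeded synthetic-fixture generator (pulsating ring, sub-pixel oscillating
texture, drifting field, static noise control) ships as first-class code so
every stage is testable without microscope data, with exact ground truth
(sub-pixel shifts use Fourier interpolation).

## Worked example

Generate the sub-pixel validation fixture — a textured field oscillating at
1 Hz with 0.36 px amplitude under σ = 0.01 intensity noise, invisible frame
to frame — and recover its frequency:

```bash
cellmag synth --kind oscillating_texture --size 128,128 --frames 480 \
        --fps 24 --freq 1.0 --amp 0.36 --noise 0.01 --seed 42 --out gel.tif
cellmag spectrum gel.tif --gth 0.05 --out-prefix gel_spectrum
```

which prints

```json
{
  "dominant_freq_hz": 1.0,
  "dominant_period_s": 1.0,
  "prominence_pct": 8202.880690468219,
  "M": 10997,
  "L": 480,
  "frame_rate_hz": 24.0
}
```

The dominant non-DC peak of the averaged edge-pixel spectrum sits exactly
on the 1 Hz drive (frequency resolution 24/480 = 0.05 Hz); 10 997 edge
pixels were averaged; the peak towers ~82× over the mean non-DC power —
a static control of the same texture shows no such peak. The same stages
are scriptable from Python (`cellmag.synthio`, `cellmag.detect_edges`,
`cellmag.estimate_spectrum`, `cellmag.magnify`, …) or chained from a YAML
config with `cellmag run --config run.yaml`, which writes every
intermediate artifact plus a checksummed manifest for reproducibility.

To make the motion visible and classify it against noise:

```bash
cellmag magnify gel.tif --alpha 20 --freq 1.0 --band 0.3 --out gel_x21.tif
cellmag validate --sample gel.tif --control static.tif --alphas 2,5,10,20 \
        --freq 1.0 --out-prefix floor
```

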