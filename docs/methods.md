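# Methods

This note records the model implemented by each module, the default
parameters (with units), the scope of the synthetic generators, and the
numerical design choices, so results can be interpreted and reproduced
without reading the source.

## 1. Hearing-impairment simulation (`hearing_sim`)

### Model

The simulator reproduces two components of a moderate sloping sensorineural
loss for presentation to normal-hearing listeners:

1. **Reduced frequency selectivity.** The signal is decomposed by a
   normal-hearing (NH) gammatone filterbank — 33 channels spaced 1 ERB
   apart from 80 Hz up to 10 kHz, with the Glasberg–Moore bandwidth
   ERB(f) = 24.7 (4.37 f/1000 + 1) Hz — and by an impaired bank whose
   bandwidths are scaled ×2 (`bandwidth_scale=2`). Each channel's Hilbert
   envelope from the impaired (2-ERB) analysis of the **original** signal is
   taken as the fixed target. The processed signal is built iteratively
   (default `n_iter=10`): analyze the current signal through the NH bank,
   keep each band's fine structure (cosine of the analytic phase), multiply
   by the target envelope, and sum across bands. Convergence is measured as
   the mean band-wise Pearson correlation between NH-analyzed envelopes of
   the output and the 2-ERB targets; bands whose target envelope RMS is
   below −60 dB re full scale are excluded as silent.

2. **Loudness recruitment.** The envelope-processed signal is short-time
   Fourier transformed, split into six octave-spaced bands centered at 250,
   500, 1000, 2000, 4000, 8000 Hz (band edges at the geometric midpoints;
   outer edges at 0 and Nyquist), and each frame's band level is re-mapped
   expansively: with threshold T (dB HL, from the audiogram) and the
   105 dB SPL uncomfortable-level anchor shared by normal and impaired
   listeners, L_out = 105 (L_in − T) / (105 − T). The slope
   105/(105 − T) > 1 is recruitment; levels at or below T map to or below
   the normal absolute threshold (0 categorical units). Gains are clamped
   to ≤ 0 dB (attenuation only). The default audiogram is the standard N3
   moderate loss: 40, 40, 45, 54, 62, 70 dB HL at the six band centers.

3. **RMS equalization.** The final output is scaled to the input's overall
   RMS (matched within 0.01 dB), so presentation level is preserved.

### Parameters

| Parameter | Default | Units |
| --- | --- | --- |
| filterbank start frequency | 80 | Hz |
| channel spacing | 1 | ERB |
| number of channels | 33 (≤ 10 kHz) | — |
| impaired bandwidth scale | 2 | ×ERB |
| imposition iterations | 10 | — |
| silence floor (envelope correlation) | −60 | dB re full scale |
| octave band centers | 250 … 8000 | Hz |
| uncomfortable level | 105 | dB SPL |
| categorical-loudness maximum | 50 | CU |
| N3 audiogram | 40/40/45/54/62/70 | dB HL |
| STFT window | Hann, 50 % overlap, 2^round(log₂(0.023·fs)) samples | — |

`AudioSignal.calibration_spl` (default 100 dB) defines the SPL of a
waveform with RMS 1.0; all dB SPL figures follow from it. Sample rates
must exceed 20 kHz so the 10 kHz top channel is below Nyquist (the CLI
resamples lower-rate input to 22.05 kHz).

### Numerical choices

* **Zero-phase gammatone realization.** Filters are realized in the
  frequency domain with the 4th-order gammatone magnitude
  |H(f)| = (1 + ((f − cf)/b)²)⁻² and zero phase, with b chosen so the
  numerically integrated equivalent rectangular bandwidth equals the
  nominal scaled ERB exactly (the analytic integral of |H|² for this shape
  is 15π/48 · b). A conventional IIR gammatone imposes a
  frequency-dependent group delay (0.5–14 ms across channels here), which
  desynchronizes bands between analysis and resynthesis; with IIR filters
  the imposition iteration *diverged* (envelope correlation 0.58 after 10
  iterations, below the 0.76 single-pass baseline; group-delay
  compensation still decayed 0.90 → 0.82), while the zero-phase
  realization converges monotonically (≈ 0.93 at 10 iterations on
  speech-like noise). Zero-phase filtering is acausal, which is acceptable
  for offline stimulus preparation.
* **STFT loudness frames.** Window length 2^round(log₂(0.023·fs)) (512
  samples at 22.05 kHz, ≈ 23 ms), Hann, 50 % overlap; band power per frame
  is 2 Σ|S|²/(N Σw²), calibrated so a steady tone's band level equals its
  RMS level. Gains vary per frame, so band attenuation follows the signal's
  level trajectory; abrupt rectangular onsets in probe stimuli produce
  broadband splatter that is attenuated per the *frame-average* level, so
  calibrated test tones use 10 ms raised-cosine ramps (`pure_tone`), as in
  audiometric practice.
* **Threshold measurement.** `measure_simulated_threshold` sweeps a
  calibrated tone in 1 dB steps, converts output levels to categorical
  units through the normal loudness function, and extrapolates the linear
  portion of the CU-vs-level curve back to its zero crossing, which
  removes floating-point slivers of loudness at the exact threshold.

## 2. Scotoma simulation (`vision_sim`)

The mask is a soft-edged, irregular, roughly semi-circular alpha map with a
non-zero footprint of exactly 731 × 497 px (≈ 17° × 11.5° at the default
screen). The base boundary is an ellipse filling the box whose right half is
flattened toward a vertical edge (superellipse exponent 6); seeded low-order
sinusoids (3 components, relative amplitude 0.04–0.12) perturb the boundary
radius, with a sin²(2θ) factor pinning the four cardinal points so the
bounding box is invariant to the seed. Alpha is 1 in the core and falls to 0
over a 40 px raised-cosine ring. Four orientations (identity, horizontal,
vertical, and double flip) form the Klein four-group used to vary the mask
across trials.

Inside the mask the video is replaced (alpha-composited) by a Gaussian
low-pass version. The amplitude response of a Gaussian blur is
exp(−2π²σ²f²); setting it to ½ at the cutoff f_c gives
σ = √(ln 2) / (√2 π f_c) degrees — 1.249° (55.8 px) at the default
f_c = 0.15 cycles/degree. The default screen geometry is 1920 × 1080 px
spanning 43° × 24.8° (44.65 px/deg horizontally; 49.64° diagonal).
Compositing uses out = (1 − α)·frame + α·blurred, with the mask anchored by
its bounding-box center to the gaze sample nearest each frame's timestamp
and cropped at screen edges.

## 3. Behavioral schedule and scoring (`behavior_metrics`)

Each participant receives 64 practice trials (8 per condition, two practice
actors, fixed condition order) and 768 main trials: 6 blocks × 8 sub-blocks
× 16 trials. The 96 stimuli (12 emotions × 8 actors) each appear exactly
once per condition; sub-block condition orders follow an order-8 balanced
Latin square (zig-zag first row, participant index rotating row assignment),
so every condition precedes and follows every other equally often.
`two_session_actor_split=True` reproduces a two-session variant where
blocks 1–3 use one half of the actors and blocks 4–6 the other.

Accuracy per cell is the unbiased hit rate Hu = correct² / (occurrences ×
response uses), i.e. recall × precision, which is 0 when the response
category was never used and undefined (an error) when the emotion never
occurred. Hu is arcsine-square-root transformed before modeling. Chance
level is 1/12.

## 4. Gaze pipeline (`gaze_pipeline`)

Events arrive pre-parsed (fixation/saccade/blink with on/off times). Per
trial: (1) events are clipped to the first 1000 ms after stimulus onset;
(2) the trial is discarded if any single in-window blink exceeds 300 ms
(two shorter blinks do not trigger exclusion); (3) saccades with amplitude
strictly greater than the 49.6° display diagonal are removed as artifacts.
Dynamic AOIs are rebuilt per video frame from 17 tracked landmarks: the eye
boxes span eyebrow-outer to eyebrow-inner in x and eyebrow-middle down to
the eye–nose border (midpoint of left-pupil y and nose-tip y); the nose box
spans the nostrils in x between the eye–nose and nose–mouth borders
(the latter the midpoint of right-nostril y and mouth-top y); the mouth box
spans the mouth corners down to mouth-bottom; hands get fixed 80 px squares.
Every AOI is expanded by 10 px per side *except* across the two shared
borders, so face AOIs touch but never overlap. Fixations are resampled at
1 ms; each time point is scored against the nearest frame's rectangles
(first match in the order eyes, nose, mouth, hands), and proportions over
eyes/nose/mouth/hands/elsewhere partition to exactly 1.

## 5. Mixed-model statistics (`stats_models`)

Models are written as lme4-style formulas and fitted with statsmodels
`MixedLM` by maximum likelihood (not REML, so AIC is comparable across
fixed-effect structures), optimizer BFGS with a Powell fallback. The first
random term supplies the grouping factor and optional random slopes (full
covariance); further random terms must be intercept-only and enter as
variance components. Categorical fixed effects are sum-to-zero coded, so
the intercept is the grand mean and Wald chi-square tests per term are
type III. The model ladder accepts a more complex candidate only if it
converged, is not singular, and lowers AIC by at least 2. A fit is singular
when any random-effect standard deviation falls below 10⁻⁴ of the outcome's
standard deviation or any random-effect correlation exceeds 0.999 in
magnitude. Rank-deficient fixed designs are rejected before fitting, naming
the aliased term. Post-hoc pairwise contrasts are estimated-marginal-mean
differences over a balanced reference grid (numeric covariates at their
means), with asymptotic z tests corrected by Bonferroni or
Benjamini–Hochberg FDR.

## 6. Synthetic data (`synthetic_data`)

All generators are pure functions of (config, seed) with `GeneratorConfig`
holding the ground truth:

* **Audio**: Gaussian noise with a −6 dB/octave tilt above 500 Hz, split
  into 6 log-spaced subbands (80 Hz–10 kHz) each modulated by an
  independent lognormal 2–8 Hz envelope (depth 0.7). Independent subband
  modulators matter: with a single coherent broadband modulator the 1-ERB
  and 2-ERB envelopes nearly coincide and the imposition problem becomes
  trivial.
* **Track points**: the 17 landmarks on an anatomically ordered face
  around (960, 450) px with smooth seeded sinusoidal motion (±12 px face,
  ±36 px hands).
* **Gaze**: an alternating renewal process — Gamma fixation durations
  (shape 4; means 500/275 ms young intact/degraded, 374/363 ms older),
  40 ms saccades with Gamma amplitudes (shape 9; means 2.83/6.54° young,
  1.58/2.78° older), landing direction biased toward the face center under
  intact video and away under degraded video, blinks as a 0.15 Hz Poisson
  process with Gamma durations (mean 120 ms).
* **Responses**: correct with a configured group × condition probability
  (young: A 0.45, V 0.55, AV 0.70, dA 0.38, dV 0.42, AdV 0.62, dAV 0.66,
  dAdV 0.52; older 0.12 lower, floored at 0.15), shifted per participant by
  a logit-normal offset (sd 0.3); errors are drawn with weights decaying in
  valence/arousal quadrant distance (decay 1.0) times a response-bias
  vector (joy ×2, sadness ×1.5), so raw hit rates and Hu genuinely differ.

The accuracy defaults encode only the qualitative ordering A < V < AV and
degraded ≤ intact; they are generator ground truth for parameter-recovery
tests, not empirical claims.

## Limitations

* The hearing simulator models frequency selectivity and recruitment only —
  no temporal-processing deficits, no audibility-of-noise floor, and the
  zero-phase filterbank is acausal (offline use only).
* The scotoma is a relative (blurring) scotoma with a fixed size; no
  eccentricity-dependent blur, latency of gaze-contingent update, or
  monitor gamma handling.
* Synthetic generators make no attempt at realistic speech, faces, or
  oculomotor dynamics; they exist to give the pipeline known ground truth.
* Mixed-model inference is asymptotic (Wald chi-square, z post-hocs);
  small-sample degrees-of-freedom corrections (Kenward–Roger,
  Satterthwaite) are not implemented.
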