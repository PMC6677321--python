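# Methods

This note documents the models, parameters and numerical choices behind
`homecage`, and what the synthetic-data validation does and does not
establish about real recordings.

## Motion detection

The background estimate is an exponentially weighted running mean,

    B_t = (1 - alpha) * B_{t-1} + alpha * F_t,        B_0 = F_0,

and each frame is compared to the background *before* it is absorbed:

    delta_t = | B_{t-1} - F_t |.

The delta frame is binarised (pixels strictly above `delta_threshold`
count as changed), 8-connected components are extracted, and components
with at least `min_area_px` changed pixels become motion regions. The
scalar motion signal is the summed qualifying area divided by the frame
pixel count, so it is a dimensionless fraction comparable across
resolutions.

Defaults and why:

- `alpha = 0.05` (per frame). At 15 fps the background time constant is
  ~1.3 s: slow enough that a moving mouse stays distinct from the
  background, fast enough to absorb illumination drift with periods of
  minutes to hours. A mouse that stops moving is absorbed into the
  background within a few seconds; for sleep scoring that is the point -
  "not moving" and "part of the background" coincide.
- `delta_threshold = 25` grey levels (8-bit): far above sensor noise
  (a few grey levels) and far below the animal/background contrast
  (~110 in the synthetic scene, similar for dark mice on light bedding
  under IR).
- `min_area_px = 0.5%` of the frame area: a mouse occupies on the order
  of 1% of a top-down cage view, while cables, bedding shifts and the
  breathing flank motion of a sleeping animal change well under 0.5%.

The streaming motion loop keeps its background accumulator in float32
for speed; the resulting quantisation (~1e-5 grey levels) is negligible
against the 25-grey-level threshold. The standalone background-model
API operates in float64 and matches the closed-form step response
`b - (b - a)(1 - alpha)^k` to 1e-9.

## Tracking

Each frame is blurred with a Gaussian kernel (size 21, sigma 3.5),
thresholded, and the largest 8-connected foreground component is taken
as the animal; its pixel-centroid is the position estimate. The
threshold defaults to Otsu's method on the blurred frame, which removes
a free parameter and makes segmentation invariant to uniform brightness
offsets; a fixed level can be supplied instead. Polarity defaults to
"animal darker than background". Area ties between components break on
the first foreground pixel in row-major order, for reproducibility.
Frames with an empty mask are stored as missing and never interpolated;
downstream consumers decide how to treat gaps.

## Sleep/wake scoring

All scorers emit a hypnogram on a 1-s epoch grid; comparisons resample
both inputs onto a common grid by majority state.

**Video.** The motion signal is (1) low-pass filtered below 0.1 Hz with
a zero-phase Chebyshev filter, (2) locally detrended in 10-s windows
with 5-s overlap to remove baseline variation across the light/dark
cycle, (3) rectified and integrated with a 20-s centred moving average,
(4) thresholded at its 55th percentile (configurable within 50-60), and
(5) subjected to the immobility-duration rule: only sub-threshold runs
of at least 40 s count as sleep, shorter ones are quiet wakefulness.

**EMG.** Band-pass 90-1000 Hz (zero-phase), rectify, 20-s moving-window
integration, 55th-percentile threshold. No minimum-duration rule is
applied to the EMG scorer.

**LFP+EMG.** The LFP is band-passed 0.2-100 Hz and downsampled to
200 Hz; delta (0.5-4 Hz) power and the theta (6-10 Hz)/delta power
ratio are computed in 5-s windows stepped by 1 s, with EMG RMS in the
matching windows. An epoch is sleep iff the EMG RMS is at or below its
55th percentile AND (delta power is strictly above its 25th percentile
OR the theta ratio exceeds 0.35). The conjunction encodes low muscle
tone plus a sleep-like spectrum: delta-dominated NREM, or theta with
atonia (REM). The strict inequality on delta means a featureless
(constant) LFP can never license sleep, however quiet the EMG.

Numerical and design choices:

- Chebyshev flavour: Type I, order 4, 0.5 dB passband ripple, applied
  forward-backward (`sosfiltfilt`). The section gains are rescaled to
  exact unity at DC, because an even-order Chebyshev-I sits at -ripple
  at DC and the forward-backward pass would square that deficit.
- Local detrending fits straight lines by least squares in sliding
  windows stepped by (window - overlap); the per-sample trend is the
  triangularly weighted average of all window fits covering the sample
  (weights floored at 1e-3 so edge samples keep coverage). A global
  linear ramp is removed exactly.
- "Integrated" means a centred moving average of the rectified signal,
  with the window shrinking at the record edges - a bounded envelope
  suitable for percentile thresholding, not a cumulative sum.
- Percentile thresholding flags samples at or below the empirical
  percentile of the whole record, so a constant series is flagged
  entirely and scoring is invariant to positive rescaling of the input.
- The immobility rule is enforced at epoch level after majority
  aggregation, which guarantees the output invariant that no sleep bout
  is shorter than `min_sleep_s`. Missing epochs interrupt candidate
  runs and remain missing.
- The theta "ratio" denominator is delta-band power, which makes a
  0.3-0.4 threshold meaningful for a ratio of band powers.
- LFP downsampling uses polyphase resampling at the rational ratio
  nearest 200 Hz / fs.

**The occupancy-matching assumption.** A within-record percentile
threshold at the p-th percentile flags a fraction p/100 of the record
as candidate sleep, so scorer-vs-truth accuracy is bounded above by
`1 - |sleep occupancy - p/100|` regardless of how separable the two
states are. The method therefore assumes the recording's sleep
occupancy is close to the chosen percentile (true of day-long rodent
recordings, where sleep occupies roughly half the time). Short records,
or records dominated by one state, violate the assumption and degrade
all three scorers together. This is visible in the validation suite:
2-h schedules drawn with 300-s mean bouts realise occupancies between
0.37 and 0.61 across seeds, and measured accuracy tracks the bound
closely (e.g. occupancy 0.613 gives EMG-vs-truth 0.937 against a bound
of 0.937). Tests that probe state separability rather than occupancy
effects therefore use balanced schedules with the percentile matched to
the known 50% occupancy.

## Metrics

Agreement between two hypnograms is matching-epoch time divided by
compared time, with epochs missing in either input excluded from both
numerator and denominator; the complementary disagreement time is also
reported. Bout tables are maximal same-state runs; bout-duration
densities use a Gaussian kernel on log-duration (a plain KDE stands in
for more elaborate averaged-shifted-histogram estimators). Day/night
summaries assign each epoch by its start time to half-open light
phases on the 24-h clock. Figures (hypnogram step plot, double-plotted
actogram) render deterministically - fixed SVG hash salt, no embedded
date - so identical inputs give byte-identical files.

## Synthetic data generator

The generator produces video, EMG and LFP driven by one ground-truth
schedule, with a shared time origin, so every pipeline stage can be
scored exactly.

**Schedule.** Alternating sleep/wake bouts with durations drawn from an
exponential distribution truncated below at `min_bout_s` (implemented
as `min + Exp(mean - min)`, so the configured mean is the true bout
mean). Defaults: 300-s mean bouts, 60-s minimum. Note that a 2-h
realisation of this law has a realised sleep-occupancy SD of about 8
percentage points across seeds, with the consequences described above.

**Video.** A dark ellipse (semi-axes 18 x 11 px, intensity 60) on a
light background (170) in a 240 x 320 frame at 15 fps. During wake the
centroid performs a reflected random walk with per-frame step SD
3 px, modulated by (a) a lognormal Ornstein-Uhlenbeck speed factor
(tau 15 s, sigma 0.5), giving the seconds-scale vigour fluctuations the
0.05-0.15 Hz band of the scoring chain responds to, and (b) brief
quiet-wakefulness pauses (mean 3 s, between moving spells of mean 35 s,
<10% of active time) - the immobile-but-awake behaviour that makes very
short immobility thresholds misclassify wake as sleep. During sleep the
blob is stationary except for breathing, modelled as a sinusoidal
oscillation of the ellipse axes at 3 Hz (typical murine resting
respiratory rate) with 0.5-px amplitude: sub-pixel flank motion whose
changed-pixel footprint stays strictly below both the locomotion
footprint and the mouse-area threshold. Nuisance processes: additive
sinusoidal illumination drift (amplitude 8 grey levels, period 1 h),
two small static distractors with 0.3-px jitter, and i.i.d. Gaussian
pixel noise (SD 2), generated exactly via Box-Muller on float32
uniforms (chosen over the default ziggurat for speed at full-frame
sizes). Frames render lazily and reproducibly: re-iterating a stream
restarts the per-frame noise generator from the same child seed.

**Ephys.** EMG is white noise whose SD switches between wake (10) and
sleep (1) values with a 1-s linear cross-fade at transitions (avoiding
unphysical step discontinuities in the envelope). LFP is a 1/f
spectrally shaped background (unit exponent, SD 10) plus a 2-Hz delta
sinusoid gated by sleep (amplitude 30) and an 8-Hz theta sinusoid gated
by wake (amplitude 20), same cross-fade. Sampling defaults to 4 kHz,
with a 2 kHz floor so the 90-1000 Hz EMG band is representable.

**What the generator does not emulate.** Photorealism, fur texture,
multi-animal scenes, lens distortion, REM/NREM structure within sleep,
electrode artifacts, and - importantly - any correlation between wake
EMG tone and locomotor vigour (wake EMG amplitude is constant by
construction). Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the stated statistical structure,
not performance on real video, where contrast, occlusions and
behavioural variety are richer.

## Validation problem sizes

End-to-end validation simulates five 2-h coupled recordings (108,000
frames of 240 x 320 video each, 4 kHz ephys) - large enough for ~24
bouts per run and stable sweep curves, small enough to run on one CPU
core in minutes. Parameter sweeps (immobility threshold over
{5,...,240} s, smoothing window over {2,...,80} s) re-score the cached
motion signal rather than re-rendering video. Tracking accuracy uses a
noise-free 60-s wake clip; primitive contracts (closed-form background
response, flood-fill equivalence on random masks, filter lag and
attenuation, the 40-s boundary rule) run in seconds.

## Known limitations

- Single animal only; identity is never in question because the
  largest contour is assumed to be the animal.
- The percentile threshold ties accuracy to occupancy (see above);
  records far from ~50% sleep need an adjusted percentile or an
  absolute threshold.
- Binary sleep/wake only; the video signal cannot separate REM from
  NREM.
- The stored trajectory keeps missing frames missing; distance
  travelled skips over gaps by connecting the flanking valid samples.
- MP4 input/output requires an ffmpeg-capable imageio plugin; the
  always-available interchange format is a PNG image-sequence directory
  plus a timestamp CSV.
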