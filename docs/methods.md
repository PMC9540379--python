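# Methods

This note records the models, numerical choices and validation logic
behind `ciliawave`, and what the synthetic tests do and do not establish
about real recordings.

## Problem setting

A primary cilium is a single sub-micron-wide filament, typically 5–10 µm
long, anchored at a basal body that stays essentially stationary while the
axoneme sweeps slowly (wave periods of order 20–30 s in islet cells).
Recordings are single-channel confocal time-lapse stacks, typically
512 × 512 pixels at 0.26–0.44 µm/pixel and at least one frame per 2 s.
The analysis target is the tangent-angle field θ(s, t) — the angle between
the cilium's local tangent and the image x-axis as a function of arc
length s from the base and time t — and scalar metrics derived from it.
The whole pipeline is deterministic: identical inputs produce bit-identical
traces and metrics.

## Drift stabilization

Frame-to-frame specimen translation is estimated by registering
consecutive frames and accumulating the steps relative to frame 0,
then undone by bilinear re-sampling (out-of-field pixels take the frame
median as a background estimate). Consecutive-pair registration is used
rather than all-to-reference because the scene deforms slowly (the cilium
beats) while drift is smooth; over the ≤ 300-frame movies targeted here
the accumulated error stays well below the acceptance bound (measured
RMSE ≈ 0.25–0.35 px on 50-frame random walks with 1 px/frame steps).

Three numerical choices matter, all made because the naive estimator
quantifiably failed on realistic synthetic scenes:

- **Band-pass prefilter** (difference of Gaussians, σ = 4 and 25 px by
  default). Fluorescence scenes are smooth; their correlation peak is
  broad and wanders by several pixels under per-pixel noise. The band-pass
  sharpens the peak. The 4 px low cutoff (≈ 1.4 µm at 0.35 µm/px) also
  suppresses the sub-micron-wide cilium itself, so registration follows
  the static tissue around it rather than the moving filament.
- **Plain cross-correlation** instead of whitened (pure-phase)
  correlation. Whitening equalizes all spectral bands, which hands the
  (white) noise floor the same weight as the signal; on SNR 10 scenes it
  produced per-step errors of several pixels versus ≈ 0.1 px for the
  unnormalized cross-power spectrum.
- **No window by default.** A Hann window apodizes content near the frame
  edge; since the windowed content of the two frames differs when the
  scene translates, each estimated step is biased toward zero by a
  fraction of the true displacement (measured slope ≈ 0.83 at 1 px
  steps), and the bias accumulates across the movie. The zero-mean
  band-passed input already suppresses the periodic-wraparound artifacts
  a window would address. Windowing remains available (`window=True`).

Subpixel precision is 1/upsample (default 10) via upsampled-DFT peak
refinement. Rotation and scaling are deliberately not corrected: only
translation of the ciliary base needs removing for the tracer, and islet
drift is translational to good approximation.

## Seeded tracing

The user-clicked polyline is resampled at equal arc-length steps Δs,
giving N = floor(L/Δs) segments (the tip remainder is dropped; the seed
fixes the cilium length once and N never changes, so length dynamics are
not tracked). The chain is rebuilt from the resampled tangent angles so
every inter-node distance equals Δs to machine precision; node 0 is pinned
to the seed base in every frame.

Each frame is Gaussian-smoothed (σ = 1 px by default) and min–max
normalized before costing. The smoothing is matched-filter-style noise
suppression — it reduced the median per-segment angle error on SNR 10
movies from ≈ 3.0° to ≈ 2.0° at Δs = 2.5 px without biasing the noiseless
case — and the normalization makes the penalty weights transferable across
movies of different brightness.

Segments are chosen in order from the base by exhaustive search over a
candidate fan θ ∈ [θ_prev − Θ, θ_prev + Θ] in steps of δθ (defaults 30°
and 1°), centered on the same segment's angle in the previous frame; the
fan doubles as a hard limit on per-frame rotational velocity. Ties are
broken toward the candidate nearest the fan center, then toward the
numerically smaller angle, making the argmin deterministic. The cost of a
candidate is the penalized sum described in the README: a negative
weighted-mean intensity under a rotating rectangular probe array
(n_along × n_across bilinear samples spanning Δs × w; default 5 × 7 over
w = 3 px, transverse Gaussian weights with σ = w/4 so centered candidates
score best), plus quadratic penalties on within-frame curvature,
end-node translational velocity, rotational velocity, and the temporal
change of curvature, the three velocity-like terms divided by Δt². All
angle differences are wrapped to (−π, π]. For the first segment the
within-frame curvature reference is the seed's initial angle, which
anchors the base direction the way the basal body anchors the real
filament. "Rate of change of curvature" is interpreted temporally (the
change of the local bend between frames), consistent with the other two
velocity penalties.

Default penalty weights (w_I = 1, w_curv = 0.05, w_tvel = 0.005,
w_rvel = 0.05, w_dcurv = 0.02, in units of the normalized-intensity scale
per rad², px²/s² and rad²/s²) were chosen so that the intensity term
dominates on clean data while the penalties measurably reduce tracking
error on poor data: at SNR 2 the default weights cut the median angle
error from ≈ 6.1° (all penalties zero) to ≈ 4.2–4.9°, while the noiseless
median error stays ≈ 1.1°, within the 1°-grid quantization plus the small
temporal-penalty lag.

Probe samples falling outside the image take the frame median
(background); if every candidate's probe lies entirely outside, the trace
is truncated at that segment for the frame (remaining segments keep the
previous frame's angles and the frame is flagged) so N stays constant.

Per-frame cost components are summed over segments, the per-frame total
being exactly the sum of the five components. The diagnostics report the
series mean and mean ± 2 population SDs of the total; frames above the
upper band are flagged as candidate tracking failures for manual review.

## Waveform metrics

All statistics are restricted to segments (or joints) whose arc-length
position lies in the middle 80 % of the cilium, [0.1 L, 0.9 L], excluding
the clamped base and the noisy tip; the same band is used consistently
for amplitude, the period series and curvature.

- **Amplitude** — population SD of θ pooled over the band and all frames
  (the spatiotemporal pool). Angles are first wrapped about their circular
  mean, so a cilium oriented near the ±π branch cut gives the same answer
  as one along the x-axis. For a rigid pivot with θ(t) = θ₀ + A·sin(2πt/T)
  sampled over whole periods this equals A/√2. The pooled (rather than
  per-frame-spatial or per-point-temporal) reading is exposed as the
  single definition; the middle fraction is a parameter.
- **Period / periodicity / frequency** — the band-averaged angle series
  φ(t) is mean-centered and autocorrelated (biased estimator, normalized
  to 1 at lag 0, searched up to half the record). The period is the lag of
  the first local maximum at lag ≥ 2 frames whose height exceeds 0.2,
  refined to sub-frame precision by a parabola through the three
  surrounding correlations; the periodicity score is that (clipped) peak
  height. Autocorrelation was preferred over a spectral argmax because
  real beats are irregular, and it yields a bounded regularity score for
  free. The biased estimator damps the large-lag variance of the sample
  autocorrelation that otherwise produces spurious "periods" in aperiodic
  series, at the cost of shrinking the score by (1 − lag/T) — negligible
  when several cycles are recorded. If no qualifying peak exists the
  period is reported absent with a `period_unreliable` flag. At least 20
  frames are required.
- **Length** — N · Δs · pixel size, constant by construction. The floor
  rule quantizes length downward by up to one segment, so length fidelity
  improves with finer Δs.
- **Maximal curvature** — max over frames and in-band joints of
  |wrap(θ_{i+1} − θ_i)| / (Δs · pixel size), in µm⁻¹. An exactly traced
  circular arc of radius R gives 1/R up to discretization.

## Synthetic scenes and what they establish

The generator renders a single-harmonic traveling wave
θ(s, t) = θ₀ + A·sin(2πt/T − k·s + φ₀) (k = 0: rigid pivot; optional
per-cycle multiplicative period jitter, default off, emulates irregular
beats), integrates the centerline from the base at ≤ 0.5 px arc steps, and
draws it with a Gaussian transverse profile (σ = 0.25 µm — the
diffraction-limited, sub-micron apparent width) by taking the per-pixel
maximum over point contributions, so tube brightness is independent of the
sampling density. Scene intensity is background + (peak − background) ·
profile, with peak meaning the absolute brightness on the filament crest;
SNR is defined as (peak − background)/noise SD. Optional static Gaussian
blobs emulate out-of-focus tissue fluorescence; they move with the
whole-field drift (a cumulative Gaussian random walk, zero at frame 0) and
give the registration the static context that surrounding tissue provides
in a real islet. Noise is additive Gaussian clipped at zero — a
detector-agnostic choice that keeps the SNR definition simple. Defaults
mirror a typical acquisition: 512 × 512 at 0.35 µm/px, 2 s/frame, 8 µm
cilium, A = 0.3 rad, T = 24 s, peak 200 over background 20 with noise
SD 18 (SNR 10).

Ground truth records the exact tangent field, centerline and drift, so
every pipeline stage is validated by parameter recovery. Validation
problem sizes: 100 random single-segment instances for grid-search
optimality; 50 frames with 1 px/frame random-walk drift for stabilization;
60-frame movies at SNR ∞/5/2 for tracing accuracy; one 300-frame movie
(10 min of recording, 25 beat cycles) for end-to-end recovery, traced at
Δs = 2.5 px — fine enough that floor-quantized length stays within a few
percent of truth while per-segment angle noise remains moderate.

What passing these tests does *not* show: robustness to photobleaching,
z-drift and out-of-focus excursions, Poisson-dominated noise, neighboring
cilia crossing the traced one, or non-harmonic beat shapes. The penalty
terms address exactly these failure modes qualitatively, but the synthetic
scenes only probe additive-noise degradation; on real movies the cost
diagnostics (frames above mean + 2 SD) remain the practical guard.

## Known limitations

- Cilium length is frozen at seeding; growth/shrinkage and tip excursions
  beyond the seeded length are not tracked.
- Only translation is stabilized; rotation or non-rigid tissue deformation
  leaks into the angle data.
- The candidate fan bounds per-frame rotation to ±30° by default; faster
  motion (undersampled beats) aliases or truncates.
- Periodicity is a sample-autocorrelation peak height; for short records
  (< ~5 cycles) it is biased low and the period estimate is coarse.
- 2D projection: a cilium pivoting out of the focal plane foreshortens,
  which the planar model reads as amplitude/length change.
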