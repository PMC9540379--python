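# ciliawave

Quantitative waveform analysis of primary cilia in live-cell fluorescence
time-lapse movies.

Primary cilia on pancreatic islet cells are solitary, ~5–10 µm long and
sub-micron wide projections that move slowly and irregularly, with wave
periods on the order of 20–30 s. Quantifying that motion from confocal
time-lapse recordings requires (i) removing whole-specimen translation
(islets drift under treatments and osmotic changes), (ii) tracing the
cilium's centerline in every frame starting from its stationary base, and
(iii) condensing the resulting tangent-angle field θ(s, t) into waveform
metrics. `ciliawave` implements this pipeline for researchers analyzing
single-cilium motility, together with a synthetic movie generator with
exact ground truth so every stage can be validated by parameter recovery.

## Method

**Stabilization.** Whole-field translation is estimated by FFT
cross-correlation of consecutive, band-pass-filtered frames (subpixel peak
localization by upsampled DFT) and accumulated relative to the first
frame; frames are then shifted back by the inverse translation.

**Tracing.** On the first analyzed frame the user marks the cilium base
and a polyline to the tip; this fixes the cilium as a chain of N equal
segments of length Δs and sets the initial tangent angle. In each
subsequent frame, segments are re-oriented one at a time from the base
outward: a fan of candidate angles θ around the previous frame's angle is
scored and the minimizer of

```
E(θ) = −w_I ⟨I⟩_probe(θ)
     + w_curv  · wrap(θ − θ_{i−1,t})²
     + w_tvel  · ‖x_i(θ) − x_{i,t−1}‖² / Δt²
     + w_rvel  · wrap(θ − θ_{i,t−1})² / Δt²
     + w_dcurv · (wrap(θ − θ_{i−1,t}) − wrap(θ_{i,t−1} − θ_{i−1,t−1}))² / Δt²
```

is kept, where ⟨I⟩_probe is the weighted mean intensity under a rotating
rectangular probe array spanning the segment. The four penalties —
curvature, translational velocity, rotational velocity, and rate of change
of curvature — keep the trace on the filament when noise, contrast or
focus make the intensity term ambiguous. Per-frame cost components are
reported with mean ± 2 SD bands so tracking failures stand out.

**Metrics.** From θ(s, t), restricted to the middle 80 % of the arc length
(base and tip excluded): amplitude (population SD of the pooled angles),
beat period and periodicity (lag and height of the first autocorrelation
peak of the band-averaged angle), frequency (1/period), length in µm, and
maximal curvature |Δθ|/Δs.

## Worked example

Simulate a default acquisition (512 × 512 at 0.35 µm/px, one frame per
2 s) of an 8 µm cilium pivoting with angular amplitude 0.3 rad and a 24 s
beat, then stabilize, trace and summarize:

```python
import ciliawave as cw
from ciliawave.pipeline import seed_from_truth

model = cw.WaveformModel(length_um=8.0, amplitude_rad=0.3, period_s=24.0)
render = cw.RenderParams(rng_seed=1, noise_sigma=18.0, n_blobs=30)
stack, truth = cw.simulate_cilium_movie(model, render, n_frames=120)

drift = cw.estimate_drift(stack)
stabilized = cw.apply_correction(stack, drift)

trace, costs = cw.trace_movie(stabilized, seed_from_truth(truth),
                              cw.TraceConfig(segment_length_px=2.5))
metrics = cw.summarize(trace)
print(metrics.to_dict())
```

```
{'amplitude_rad': 0.22926186686233097, 'period_s': 23.99970779812355,
 'frequency_hz': 0.04166717396776749, 'periodicity': 0.8992847140740794,
 'length_um': 7.874999999999999, 'max_curvature_per_um': 0.5983986006837816,
 'n_frames_used': 120, 'flags': []}
```

The recovered amplitude approaches the RMS of the generating sinusoid
(0.3/√2 ≈ 0.212 rad; the small excess is tracing noise), the period
matches the generating 24 s beat to well under one frame interval, the
periodicity near 1 reflects the regular beat, and the length (7.875 µm)
is the true 8 µm quantized to a whole number of 2.5 px segments.

For real movies the same stages run from the command line, with the seed
supplied as JSON (`{"base": [x, y], "polyline": [[x, y], ...]}`, pixel
coordinates clicked from base to tip on the first analyzed frame):

```
ciliawave stabilize movie.tif --out stab.tif --drift drift.csv \
    --pixel-size 0.35 --frame-interval 2
ciliawave trace stab.tif --seed seed.json --frames 0:300 \
    --out trace.csv --costs costs.csv
ciliawave metrics trace.csv --out metrics.json
ciliawave plot trace.csv --costs costs.csv --out-prefix cilium1
```

`ciliawave run --config run.yaml` executes the whole pipeline from a
single config, and `ciliawave simulate` renders synthetic scenes.

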