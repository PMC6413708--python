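# gevikit

Analysis toolkit for **wide-field voltage imaging** with genetically
encoded voltage indicators (GEVIs) in brain slices: ΔF/F₀ with per-pixel
photobleaching correction, stimulus-evoked activation maps with
automatic somatic-ROI segmentation, signal/noise/SNR and photon-budget
metrics, frame-rate optimization under an exponential-kinetics aliasing
model, and spatial-autocorrelation-based estimation of signal crosstalk
between neighbouring cells. A ground-truth-annotated synthetic movie
generator makes every stage testable without raw data.

**Who it is for.** Labs doing single-cell-resolution voltage imaging of
sparsely labelled neurons with cameras: the indicator sits in the plasma
membrane, bleaches under illumination, dims on depolarization
(FRET-donor polarity), and delivers fractional signals of 0.1–0.6 % that
must be pulled out of the shot-noise floor.

## The core quantities

* **ΔF/F₀**: per pixel `(p_i[n] − f_i[n]) / (f_i[n] − offset)`, where
  `f_i` is a straight-line fit to that pixel's own time course (the
  bleaching baseline) and `offset` is the camera dark level (1,600
  counts at 4×4 binning by default).
* **Photon budget**: shot-noise-limited `SNR = (ΔF/F)·√n`, so a 1 %
  signal needs 10,000 detected photons for SNR 1. Background occupying a
  fraction `f_b` of the light dilutes ΔF/F by `(1 − f_b)` and SNR by
  `√(1 − f_b)`.
* **Bleach-corrected SNR**: `SNR / √(bleach rate in %/s)` — under shot
  noise, SNR grows as √(illumination) while bleaching grows linearly, so
  the ratio compares indicators across illumination levels.
* **Optimal frame rate**: downsampling a 500 Hz trace by factors n gives
  noise `A₂x^b₂` (b₂ ≈ 0.5, shot noise) and signal `1 − A₁x^b₁` versus
  effective rate x; `SNR(x)` peaks at
  `x* = [b₂/(A₁(b₂ − b₁))]^(1/b₁)` — about 99 Hz for published-style
  exponents. Aliasing of the exponentially decaying indicator response
  (time constant τ) under full-frame integration is negligible above
  `2/τ` (167 Hz for τ = 12 ms).
* **Crosstalk**: from the activation map's spatial autocorrelation
  (ACF), the signal power a target ROI collects from neighbours at
  distances `r_i` is `1 − 1/(1 + 2·Σ ACF(r_i))`; a neighbour at the 50 %
  ACF cutoff contributes 50 % of the power.

## Worked example

Simulate four trials of a calibration-preset recording (two cells, one
driven with a 500 ms depolarization, 100 Hz, 1.04 µm pixels), run the
standard analysis, and report the Table-style metrics:

```python
import numpy as np
from gevikit.synthetic_scene import (table1_config, table1_geometries,
                                     table1_protocol, simulate_trials)
from gevikit.dff_core import average_trials, pixel_bleach_fit, compute_dff
from gevikit.activation_segmentation import (delta_f_sequence,
    preprocess_map_sequence, activation_map, segment_soma, roi_timecourse)
from gevikit.signal_metrics import snr_report

config = table1_config(seed=0)
geoms = table1_geometries(config)
protocol = table1_protocol("map", trial_count=4)
movies, truth = simulate_trials(geoms, config, protocol, active=[True, False])

avg = average_trials(movies)
stim = protocol.stim_frames(config.frame_rate, config.n_frames)
bleach = pixel_bleach_fit(avg, np.setdiff1d(np.arange(config.n_frames), stim))
dff = compute_dff(avg, bleach)
seq50, r50 = preprocess_map_sequence(delta_f_sequence(avg, bleach),
                                     config.frame_rate, "visualization")
amap = activation_map(seq50, [protocol.stim_frames(r50, seq50.shape[0])],
                      config.pixel_size)
roi = segment_soma(amap)
trace = roi_timecourse(dff, roi, config.frame_rate)
report = snr_report(trace, 100, "long_depol",
                    bleach_rate_pct_s=float(np.nanmedian(bleach.rate_map()[roi.mask])),
                    stim_duration_s=0.5, trial_count=4)
```

Output for seed 0:

```
ROI: 569 px, centroid (49.8, 30.1) um
signal      0.630 %
noise       0.060 %
SNR         10.5
bleach rate 0.51 %/s
corrected   14.7
```

The segmented ROI lands on the driven soma (true centre (50, 30) µm);
the 0.63 % depolarization signal against 0.06 % noise after 4-trial
averaging, and the recovered 0.51 %/s bleach rate (0.52 %/s configured),
are the magnitudes typical of early-generation FRET indicators at
100 Hz. The same trace/ROI machinery applied to single-spike protocols
yields ~0.1–0.2 % AP signals.

## Command line

```sh
gevikit simulate --out-dir sim --kind map --trials 4 --seed 0
gevikit run --config run.yaml          # full pipeline, writes report.json
gevikit dff sim/trial_00.tif --out dff.tif
gevikit segment sim/trial_00.tif --protocol proto.yaml --out mask.tif
gevikit framerate trace.csv --rate 500 --onset 1.0 --out fits.json
gevikit alias-check --tau 0.012        # -> 167 Hz
gevikit crosstalk sim/trial_00.tif --protocol proto.yaml --out ct.json
gevikit plan-sparsity profile.csv --max-crosstalk 0.2
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's anchor values from
scratch — the photon count required for a 1 % signal to reach SNR 1
(inverting the shot-noise relation), the noise-scaling exponent of a
downsampled shot-noise-limited trace (log-log fit over factors
1–20), and the crosstalk percentage for a single neighbour at the 50 %
ACF cutoff — and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
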