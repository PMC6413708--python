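# Methods

This note records the models behind `gevikit`, the defaults and why they
were chosen, and the limits of what a passing test establishes.

## The measurement problem

A genetically encoded voltage indicator (GEVI) sits in the plasma
membrane, so its photon budget is small and its signal spreads over the
whole labelled cell — soma, dendrites, and (with depth) a scattering
halo. For the FRET-donor indicators this package is calibrated against,
depolarization *decreases* emission, the fractional change per action
potential is ~0.1–0.2 %, and the shot-noise floor forces trial averaging:
with `n` detected photons, `SNR = (ΔF/F)·√n`, so a 1 % signal needs
10,000 photons for SNR 1. Every stage of the package follows from that
arithmetic.

## ΔF/F₀ with bleach correction (`dff_core`)

Fluorescence bleaches at 0.2–1 %/s under wide-field illumination, so the
baseline F₀ of pixel *i* is a straight line `f_i[n]` fitted by ordinary
least squares to that pixel's own time course, and

```
ΔF/F₀[i, n] = (p_i[n] − f_i[n]) / (f_i[n] − offset)
```

with `offset` the camera dark level (1,600 counts at 4×4 binning, the
default). Choices:

* **Fit frames.** When a stimulation protocol is known the line is
  fitted only to frames outside the stimulus windows (evoked transients
  are negative-going and would bias the slope); the line is still
  *evaluated* at every frame. A switch restores fitting over all frames.
* **Flagged pixels.** Any pixel whose fitted line touches the offset
  (denominator ≤ 0) is NaN throughout and excluded from all downstream
  means — never silently zero-filled.
* **Sign convention.** Traces carry an explicit `raw` (negative-going)
  or `depol_positive` tag; all amplitude rules operate on `raw` and
  report magnitudes.
* **Flattening.** Before downsampling analyses, a trace is divided by a
  polynomial (default order 3) fitted to its signal-free frames only, so
  residual bleaching does not masquerade as low-frequency noise in long
  averaging windows.

## Activation maps and segmentation (`activation_segmentation`)

The ΔF sequence `p_i[n] − f_i[n]` is block-averaged to 50 Hz, filtered
(visualization: spatiotemporal Gaussian, σ = 1 frame / 1 pixel; signal
spread: 3-point temporal median, no spatial filtering), and summed over
the stimulus frames. Active pixels go negative; noise pixels average to
zero; the map reveals the cell's anatomy.

Segmentation applies Yen's automatic threshold to the min-max-scaled,
sign-corrected map (256 bins), one round of 3×3 binary closing then
dilation, and keeps the largest 8-connected component (ties broken by
summed activation). Two additions the bare recipe needs in practice:

* **Detection gate.** A histogram threshold always "succeeds", even on
  pure noise. A map is declared empty ("no active cell detected") unless
  the mean of its suprathreshold foreground exceeds the map median by
  3.5 robust standard deviations. The constant was calibrated on the
  *null* distribution only: across 300 pure-noise maps (smoothed and
  unsmoothed) the statistic never exceeded 2.5, while a genuine soma
  scores ≳8. It was not tuned on signal cases.
* **Stimulus length for mapping.** Anatomy-quality maps need many summed
  frames; the mapping protocol uses a 500 ms depolarization (25 frames
  at 50 Hz, within the 7–30-frame range such maps are built from), while
  the signal-size measurements use the 100 ms / single-spike protocols.

## Signal, noise and SNR (`signal_metrics`)

Amplitude rules, applied to the raw trace and reported as positive
percentages:

* long depolarization: 5th percentile during the stimulus minus the
  median of the previous 10 points;
* first spike of a train: window extremum in the 50 ms after the
  stimulus minus the median of the preceding 10 points;
* later spikes: window extremum of the following 50 ms minus the
  *extremum* of the preceding 20 ms (later spikes ride on the decaying
  tail of their predecessors, where a median is biased — the
  median-vs-extremum asymmetry between the rules is intentional and
  preserved).

Noise is the SD (ddof = 1) of exactly the 20 samples before the
stimulus. `SNR = signal/noise`. The bleach-corrected SNR divides by
`√(bleach rate in %/s)`: under shot noise SNR grows as √(illumination)
while the bleach rate grows linearly with it, so the ratio is
illumination-invariant (verified by simulation: ×4 illumination doubles
raw SNR and leaves the corrected value fixed within 10 %). The linear
convention (SNR/rate) is selectable and every report records which was
used. Background occupying a fraction `f_b` of the collected light
dilutes ΔF/F by `(1 − f_b)` and, at fixed total flux, scales SNR by
`√(1 − f_b)`; the √ convention was chosen over the linear one because a
photon-level Monte-Carlo oracle reproduces √(1 − f_b) and not (1 − f_b).

## Frame-rate optimization (`framerate_opt`)

A 500 Hz AP trace is block-averaged by factors n ∈ {1,2,3,4,5,10,20},
keeping all n phases. Per factor: noise = SD of ⌊100/n⌋ signal-free
samples, signal = stimulus-window peak minus the median of ⌊20/n⌋
preceding samples, jitter = spread across phases of the peak block's
time (zero at n = 1 by construction, bounded by n × base period). Fits
are log-log-linear versus *effective rate* x (the orientation the
printed exponents b₂ ≈ +0.45, b₁ ≈ −0.13 imply), and

```
SNR(x) = (1 − A₁ x^b₁) / (A₂ x^b₂),   x* = [b₂ / (A₁ (b₂ − b₁))]^(1/b₁)
```

gives the optimal rate in closed form (cross-checked against a dense
grid search to 0.01 %; with A₁ = 1.41, b₁ = −0.13, b₂ = 0.45 the optimum
is 99 Hz).

**Aliasing model.** The optical signal is a decaying exponential
(Lorentzian power spectrum `∝ 1/(1 + (2πfτ)²)`); the camera integrates
the full frame period (frequency response `sinc²(f/rate)`). The aliased
fraction is the power above Nyquist over total power, computed by
piecewise adaptive quadrature between the sinc zeros with an analytic
tail bound (relative accuracy ≲1e-9, verified against a brute-force
trapezoid oracle). The fraction depends only on `rate·τ` and is strictly
decreasing in rate; the half-decay-constant rule `rate = 2/τ` gives
167 Hz for τ = 12 ms. At that rate the model evaluates the aliased
fraction as **0.0112** — this number is the module's named "severe
aliasing" constant. Note that the often-quoted ~0.1 figure corresponds
to the same integral *without* the integrator response; with full-frame
integration the true folded power is an order of magnitude smaller.

## Signal spread and crosstalk (`crosstalk`)

The spatial autocorrelation (ACF) of a spatially unfiltered activation
map is computed by zero-padded full correlation, normalized by the
zero-lag value, the 1-pixel central noise peak replaced by its
8-neighbour mean, then min-max normalized to [0, 1]. The map is *not*
globally mean-subtracted first: its background is zero-mean by
construction, and subtracting a global mean that contains the cell's own
signal injects a FOV-size-dependent negative plateau that corrupts the
ACF tails of extended cells. Profiles are read along the principal
(second-moment) axes of the ≥0.5 region; multiple cells are averaged
after rotating their long axes to a common direction.

Crosstalk from neighbours at distances `r_i`:

```
power fraction:      1 − 1/(1 + 2 Σ ACF(r_i))
amplitude fraction:  1 − (1 + 2 Σ ACF(r_i))^(−1/2)
```

`1 + 2Σ` is the first-order expansion of the squared amplitude ratio
`(1 + Σ)²`, so the first expression estimates the *power* not
attributable to the target (a neighbour at the 50 % ACF cutoff
contributes 50 % of the power), and the square-root companion gives the
amplitude version. The hexagonal-grid scenario enumerates lattice
neighbours to 3× the side length (configurable), evaluating the short
axis for the best case and the long axis for the worst.

**Validation oracle.** `mixing_oracle` simulates two identical neurons,
drives only the target, segments the target's ROI with the standard
pipeline, and attributes the ROI fluorescence to each neuron with the
ground-truth brightness maps (under the scenario's identical-time-course
assumption the amplitude contributions are proportional to brightness).
It reports both the amplitude fraction (exactly 0.5 for co-located
identical cells) and the power fraction; the formula is validated
against the *power* fraction, agreeing within 15 % over separations of
20–150 µm in the heavy-scattering validation scene.

## Synthetic scenes (`synthetic_scene`)

What the generator emulates: membrane-annulus somata with darker
interiors and line-segment dendrites; Gaussian defocus/scattering blur;
negative-going ΔF/F convolved with first-order indicator kinetics
(τ default 25 ms at room temperature, 12 ms for ~34 °C recordings) and
integrated over the full frame period (supersampled ≥10× and ≥10
samples per τ); single-exponential bleaching; a uniform background
contributing a configured fraction f_b of all light; Poisson shot noise
and Gaussian read noise on a 1,600-count offset. Seeding: one RNG per
trial, seeded `seed + trial index`.

Chosen once, with reasons:

* **Compartment brightness 1 / 0.45 / 0.5 (rim / interior / dendrite).**
  Wide-field imaging integrates over depth; a spherical shell of radius
  R and thickness t projects to `2tR/√(R²−r²)` — a bright rim about
  2.2× the centre for R = 10 µm, t = 2 µm — and micron-scale dendrites
  are dimmer than the soma rim.
* **Dendrite defocus = 3× somatic defocus** by default: processes rarely
  stay in the focal plane of the soma.
* **`table1` preset** (100 Hz, 3 s, 4 trials, two cells, 1 µm somatic
  defocus as fits in-focus superficial recordings): AP amplitude 0.0017
  with τ = 25 ms yields a measured first-spike signal of ~0.11–0.18 %
  after frame integration and background dilution; the 100 ms
  depolarization measures ~0.5–0.6 %; ROI noise after 4-trial averaging
  is ~0.04–0.07 %; bleach 0.52 %/s.
* **`scatter_pair` validation scene**: two somata with an 80 µm Gaussian
  halo (the upper end of observed ACF 50 % cutoffs, ~135 µm), 2.08 µm
  pixels, high photon counts — crosstalk validation probes the mixing
  geometry, not shot noise.

What the generator does **not** model — and therefore what a green test
does not establish: real optical PSFs and depth-dependent scattering
(only Gaussian blur), membrane-potential biophysics (AP waveforms are
stereotyped templates), motion, heartbeat/respiration artifacts, and
dark/hot camera pixels. Recovery results on this world demonstrate that
the *analysis* machinery is correct and internally consistent, not that
it is robust to every artifact of real recordings.

## Numerical conventions

Distances in µm, times in s, rates in Hz; ΔF/F stored as fractions and
printed as percent. Time windows convert to frame counts by rounding
half-up at the trace's rate. Report JSON fixes floats to 9 significant
digits so reruns are byte-identical. Argmax ties in peak localization
resolve to the earlier frame; equal-size segmentation components resolve
to the larger summed activation; principal-axis ties resolve to 0°.

## Known limitations

* Yen's threshold acts as a background/signal split, so the segmented
  ROI includes the near halo of the soma; the achievable soma IoU
  degrades with defocus (≈0.5 at σ = 2 µm).
* The later-spike amplitude rule's extremum baseline makes its estimates
  systematically larger (and noisier) than the first-spike rule's — this
  mirrors the printed procedure rather than improving on it.
* The crosstalk formula's first-order character means it overestimates
  power crosstalk by ~10 % at large ACF values and degrades in relative
  terms wherever the ACF falls below ~0.1; the validation scene
  deliberately keeps neighbours inside the ACF support.
* `aliased_power_fraction` describes a single-exponential indicator; for
  multi-component kinetics the slowest component dominates the rule of
  thumb.
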