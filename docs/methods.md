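# Methods

This note documents the models, defaults and numerical choices behind
`meanet`, and what the synthetic ground-truth generator does and does not
emulate.

## Signal model and detection chain

A recording is a matrix of extracellular voltages (µV) at a per-channel
sampling rate, 20 kHz by default, with an electrode layout in µm. Filtering
is an order-4 Butterworth high-pass applied forward–backward
(`sosfiltfilt`), so the effective gain is |H(f)|² and the phase is zero;
1 Hz is used for field potentials and 100 Hz for the spike band. Only the
cutoffs are externally prescribed; the order-4 zero-phase realization is
this package's choice, and filtered recordings carry an `hp_cutoff_hz` tag
that `detect_spikes` checks so spike detection cannot silently run on
wide-band data.

The baseline noise σ is the MAD-based robust SD (MAD/0.6745). "Quiescent
periods" are not segmented explicitly: for traces whose spikes occupy a
few percent of samples the MAD tracks the quiescent SD to within a few
percent, which the tests verify at 10 injected 60 µV spikes/s on σ = 4 µV
noise. An iterative-exclusion estimator (drop |v| > 4σ, re-estimate,
2 passes) is available for comparison.

A spike is an upcrossing of |v| ≥ kσ (k = 5 default, per electrode), timed
and measured at the signed extremum within ±0.5 ms of the crossing. The
dead time (1 ms default) is anchored at the previous event's extremum
rather than its crossing sample: the positive rebound lobe of a biphasic
waveform peaks ~1 ms after the trough, and anchoring at the trough keeps
that lobe inside the refractory window so one action potential yields one
event. Dead time, alignment window and k are all configurable. Detected
counts are monotone non-increasing in k (greedy acceptance of a subset of
crossings can only shrink).

## Network bursts and the parameter panel

Burst detection is pooled across all electrodes of a well — the standard
reading of a *network* burst — and is exactly the 4-step procedure: ISI
joining (≤ 10 ms), candidate-size filter (≥ 50), gap merging (< 100 ms,
with spikes between merged candidates absorbed into the burst), and a
final size threshold (> 500). The published operating ranges for the four
parameters are 5–15 ms, 50–100, 100–200 ms and 500–1500; the defaults
(10 ms, 50, 100 ms, 500) sit inside those ranges and all four are exposed.
The size filter is applied per candidate; an interpretation under which a
whole well is excluded when its largest candidate is small is available as
a QC flag downstream rather than baked into detection.

Burst boundaries are the first and last member spike. The peak rate uses
50 ms bins anchored at burst start, ties resolved to the earliest bin, and
the IMFI is defined as the interval between consecutive bursts' peak-rate
times (the natural reading of "inter-maximum-frequency interval"; no
formal definition is published). CVs use the sample SD (n−1). With fewer
than 2 bursts the CVs are NaN; the IMFI statistics need one burst more
(mean from 2, CV from 3). Whether the "maximum frequency" should be a
count per 50 ms bin or a rate in Hz is ambiguous; the panel stores
counts/bin, and the conversion is a fixed ×20.

## Wavelet quantification

The CWT uses the complex Morlet G(x) = (πF_B)^(−1/2) exp(−x²/F_B)
exp(2πiF_C x) with F_B = 5, F_C = 1, scales a = 1/f on a 181-row
logarithmic grid from 0.1 to 250 Hz (the published specification fixes the
endpoints and row count; log spacing is the scalogram convention). The
transform is evaluated per scale in the Fourier domain using the analytic
Gaussian spectrum of G, mathematically equal to convolution with the
wavelet truncated at |x| ≥ 4√F_B (envelope < e⁻¹⁶) but without
materializing ~90 s kernels at 0.1 Hz. The printed transform correlates
with the *unconjugated* wavelet; for real signals the magnitude is
identical to the conjugated convention, which is what every downstream
quantity consumes, and the tests pin the row energies to an independent
CWT implementation (PyWavelets `cmor5-1`) after converting its
discrete-time normalization (a factor √fs).

Scalogram pixels are 50 µs on the time axis (exactly one sample at
20 kHz; at lower rates the pixel is one sample — pixelization never
upsamples). WT_A is the mean |W| per pixel in a band, i.e.
WT_S/(N_X·N_Y) exactly when no pixels are excluded. By default, pixels
inside the per-row cone of influence (half-width 4√F_B·a seconds) are
excluded and the denominator is the retained-pixel count; rows that are
entirely edge-dominated drop out. Whether the published statistic used
|W| or |W|² is ambiguous ("power spectrum" vs "absolute value"); this
package uses |W| as explicitly stated, and percent changes of WT_A are
insensitive to that choice for amplitude-scaled signals. Band
quantification can be run on whole recordings or on windows around
individual bursts; the drug-effect workflow uses per-burst windows.

## Velocities

*Pairwise (spheroid) case.* The per-burst onset of an electrode is its
first spike inside the pooled burst window; the delay series between a
reference and target electrode drops bursts where either is silent (and
counts them). Velocity = electrode distance / mean delay, in mm/s.

*Network case.* Each burst contributes (distance to reference electrode,
onset delay) points for every firing electrode; points are fit jointly
across bursts by OLS of distance on latency. Optionally delays are first
averaged per electrode across bursts, which turns the per-burst jitter of
the reference onset into a pure intercept shift and markedly stabilizes
the slope; the joint fit is the default because its R² reflects the
burst-to-burst variability an experimenter would see.

*Axonal case.* Somata are local maxima of the spike-amplitude map with a
minimum amplitude and pairwise separation (greedy suppression, ties to the
larger amplitude then the lower electrode id). The spike-triggered
average spans −1.5 to +2.5 ms (4 ms, 80 samples at 20 kHz) around the
soma firing times, dropping edge-clipped triggers. Published pathway
selection was manual; here an electrode joins the path when its STA trough
reaches `amp_min` and its maximal normalized cross-correlation with the
soma STA reaches `rho_min` (default 0.7). Path order is by STA trough
latency, refined to sub-sample precision with a three-point parabola
(at 20 kHz one sample is 50 µs, comparable to inter-electrode conduction
latencies). The conduction velocity is the OLS slope of cumulative
along-path distance on trough latency. Regressing distance on latency
(not the reverse) follows the stated fit orientation; the intercept is
left free in µm and absorbs alignment offsets, and R² is reported for the
same fit. Two-point fits are allowed but flagged exact.

## Dose–response statistics

Dunnett's many-to-one comparisons use `scipy.stats.dunnett`
(equicorrelated multivariate-t distribution, seeded integration), pooled
control across its concentrations, with NaN panel entries (wells without
enough bursts) dropped pairwise and counted. PCA z-scores the 5-parameter
set (correlation structure — the parameters have incommensurate units),
drops zero-variance columns with a warning, and fixes each component's
sign so its largest-|loading| entry is positive. Pairwise MANOVA uses
Wilks' Λ with its F approximation (statsmodels) on the first two scores,
requiring n ≥ 3 per group. The paired t-test is two-tailed, with the
convention t = 0, p = 1 for identical pairs. No correction is applied
across the 10 panel parameters, matching the heat-map practice this
package reproduces.

## Synthetic ground truth

The generator emulates what the analysis consumes, not membrane biophysics:

* **Spike trains** (`gen_spiketrains`): each scheduled burst gives every
  active electrode a firing window offset by distance-to-source/velocity
  plus Gaussian onset jitter; the electrode's first spike sits exactly at
  its window start (a well-defined planted onset), the rest of its share
  of the pooled count is truncated-Gaussian within the window (uniform
  optionally, used where a dense leading edge matters); background firing
  is homogeneous Poisson.
* **Traces** (`render_traces`): Gaussian noise plus a biphasic template
  (1 ms trough lobe, 2 ms total, 0.4 overshoot) placed trough-on-spike
  and scaled per spike, plus optional burst-gated sinusoidal field
  components shared across channels.
* **Axon datasets** (`gen_axon_dataset`): electrodes near a polyline carry
  the template scaled by exp(−d/λ) and delayed by arc-length/velocity,
  rendered with fractional-sample delays so planted latencies are not
  quantized to the sampling grid.
* **Panel samples** (`gen_param_samples`): multiplicative effects
  interpolated across a concentration ladder with multiplicative Gaussian
  noise (CV 0.12).

Every generator is a pure function of (configuration, seed).

Preset study conditions: `burst16` — 4×4 grid, 450 µm pitch, 20 bursts of
600 spikes over 0.5 s every 2.5 s, 32 µV spikes on 4 µV noise (SNR 8),
0.1 Hz background; `spheroid-pair` — two active electrodes 1398.75 µm
apart, 31 bursts, 375 ms mean onset lag (3.73 mm/s) with 166 ms delay SD
(per-electrode jitter 166/√2 ms since the delay is a difference of two
onsets), 1.2 s bursts of 3000 spikes so the leading single-spheroid span
never fragments at the 10 ms join ISI; `network7` — 7 sites over 1.8 mm,
0.14 m/s, 0.8 ms first-spike jitter, 4 bursts; `cmos-axon` — 24×24 grid at
17.5 µm pitch, a 367 µm straight axon at 0.57 m/s, 120 µV soma amplitude
decaying with λ = 10 µm, 100 triggers; `dose-response` — vehicle plus four
compounds, 5 doses, n = 4, with monotone planted effects (burst-count
increases for the convulsants, activity suppression for the NMDA
antagonist, CV reductions for the muscarinic agonist).

What passing tests show — and what they do not: recovery of planted
structure demonstrates that the estimators are unbiased and correctly
implemented under Gaussian noise, Poisson background, stationary
oscillations and noiseless geometry. Real recordings add electrode-drift,
non-Gaussian artifacts, overlapping units, bursts with ragged onsets, and
amplitude footprints that are not isotropic exponentials; performance
there depends on the thresholds (k, burst parameters, `rho_min`,
`amp_min`) that this package deliberately exposes rather than fixes.

## Problem sizes and tolerances

The test suite and the acceptance script run the presets at the sizes
above (e.g. 50 s × 16 channels at 20 kHz for burst recovery; 4 s
single-channel windows for band quantification; 300–500 replicates for
statistical calibration), chosen to keep estimator sampling error well
inside the asserted tolerances. Stochastic checks are seeded and assert
bounds with explicit sampling-error margins (e.g. delay SD within 10% at
n = 500; STA residual within 30% of σ/√N); exact checks (brute-force
oracle equivalence, SVD score agreement at 1e−10, byte-identical pipeline
reruns) have no tolerance to tune.

## Known limitations

* No spike sorting: a threshold event is an event, not a unit; overlapping
  units on one electrode merge.
* Burst detection is pooled-only; per-electrode bursting and adaptive
  detectors (e.g. rank-surprise) are out of scope.
* The axon tracer returns an ordered polyline of electrodes; it does not
  reconstruct curvature between electrodes or handle branching axons.
* The Fourier-domain CWT zero-pads to twice the signal length; rows whose
  cone of influence exceeds the window carry no valid pixels and drop out
  of WT_A, so very low frequencies need proportionally long windows
  (≈ 90 s for meaningful 0.1 Hz content).
* Vendor file formats are not read; recordings enter as raw float32
  matrices with a JSON sidecar, events and layouts as TSV.
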