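# Methods

This document describes the generative models, the analysis chain, the
default parameters, and the numerical choices behind `gaiteeg`.  The
package simulates multi-subject mobile gait-EEG studies with known ground
truth and provides the full analysis chain needed to recover that truth:
gait-event detection and variability metrics, dual-layer EEG cleaning with
ICA and equivalent-dipole clustering, gait-cycle time-warped spectral
analysis with muscle-artifact correction and aperiodic/periodic
parameterization, and resampling plus mixed-model statistics.

## 1. Synthetic data generation

### 1.1 Gait kinetics and kinematics (`synthgen.simulate_gait`)

Stride durations are drawn i.i.d. from a normal distribution truncated at
±3 SD, parameterized by a mean (default 1.2 s) and a coefficient of
variation (CoV).  Within each stride, the four remaining events are placed
at fixed phase fractions of that stride's duration: left foot off at 0.12,
left foot strike at 0.50, right foot off at 0.62 (right foot strike
anchors the stride at phase 0).

Per-foot vertical insole forces are trapezoidal loading curves (plateau
700 N, linear ramps of 0.1 s) constructed so that the rising edge crosses
the 20 N contact threshold *exactly* at the scheduled foot-strike time and
the falling edge crosses it exactly at the foot-off time.  This makes the
ground truth of threshold-based event detection exact by construction
rather than approximate.

Sacral anteroposterior/mediolateral excursions are per-stride sinusoids
whose peak-to-peak amplitudes are truncated-normal draws with a stated
mean (20/30 mm) and CoV, so the behavioral CoV pipeline has a known
target.

### 1.2 Cortical sources (`config.SourceSpec`, `synthgen.simulate_recording`)

Each source is colored noise shaped in the frequency domain to the target
one-sided PSD

```
PSD(f) = 10^(offset − exponent·log10 f) · 10^(Σ peaks h·exp(−(f−c)²/2w²))
```

i.e. an aperiodic 1/f component (offset in log10 µV²/Hz at 1 Hz) with
Gaussian oscillatory bumps in log-power.  A white-noise realization is
multiplied in the rFFT domain by `sqrt(PSD / (2/fs))` (the white PSD of a
unit-variance sequence is 2/fs one-sided), which gives exact expected
spectra.

**Band-limited effects.**  Condition, group, and subject-intercept effects
are specified as dB shifts of band power.  To make an injected −2 dB shift
recoverable as −2 dB through any band-power estimator, the source signal
is decomposed into per-band components using a *power-domain partition of
unity*: frequency windows with raised-cosine crossfades whose squared
magnitudes sum to one across bands plus a remainder window.  Each band
component is scaled by `10^(dB/20)` (amplitude gain = half the power gain
in dB), so band powers shift by exactly the requested dB while total
phase/waveform continuity is preserved.

**Gait-phase modulation.**  A band's amplitude can additionally be
modulated within each stride by `10^(m(φ)/20)` where `m` is a zero-mean dB
profile of the gait phase φ ∈ [0, 100)% (piecewise-linear phase computed
from the simulated stride events).  The default profile is a sinusoid
with a stated peak-to-peak dB depth and an integer number of cycles per
stride, giving a closed-form target for ERSP peak-to-peak recovery.

### 1.3 Forward model (`forward`)

Sources are mixed to scalp electrodes through a three-shell concentric
spherical conductor (brain/skull/scalp radii 73.95/78.2/85 mm,
conductivities 0.33/0.0042/0.33 S/m).  The potential of a current dipole
is computed from the Legendre series solution; for each degree *n* the
radial solution coefficients in the three shells are obtained by solving
the boundary-condition linear system (continuity of potential and of
radial current at the two interfaces, insulating outer boundary).  These
per-degree surface factors depend only on the geometry, so they are
computed once per head model and cached; the dipole-position dependence
enters only through `b^(n−1)` and the Legendre polynomials.  Tangential
moments use the regular form `sin γ cos φ · P′_n = ((ê − cos γ r̂₀)·t̂) ·
P′_n`, which avoids the coordinate singularity at γ = 0.  Electrode
montages are Fibonacci-spaced points on the upper scalp cap.

The model is verified against closed forms: a central dipole in a
homogeneous sphere has `V = 3 (q·r̂) / (4π σ R²)`; the series is
rotation-invariant and linear in the moment, and converges at the default
40 terms.

### 1.4 Artifacts

* **EMG**: broadband noise whose PSD is flat below 20 Hz, rises at
  +0.3 dB/Hz to a plateau at 120 Hz — the spectral signature that spectral
  PCA (PC1) is designed to capture.  EMG channels carry it directly;
  a configurable fraction (default 30%) of scalp channels receives an
  attenuated copy.
* **Line noise**: 60 and 120 Hz sinusoids with per-channel random gains.
* **Dual-layer noise electrodes**: each scalp electrode has a paired
  "noise" electrode carrying the same artifact/line mixture but *no*
  cortical signal — the mechanically coupled reference layer that
  CCA-based cleaning exploits.
* **Sensor noise**: white, 0.5 µV RMS.

### 1.5 Scenarios and datasets

`make_scenario("null")` has all effects zero — every downstream statistic
should then reject at nominal rates.  `make_scenario("paper-like")`
encodes the qualitative target pattern: terrain-graded alpha/beta
reductions at parieto-occipital sources that are steep in young subjects
and shallow in old (terrain × age interaction), a common terrain-graded
beta reduction plus intra-stride beta modulation at sensorimotor sources,
a terrain-graded theta increase at the occipital source, and
terrain-graded gait variability (CoVs rising from flat to high terrain,
more steeply for old subjects).  `generate_dataset` lays out
subjects × conditions × trials with per-subject random intercepts
(SD 0.3 dB per source-band) and group-specific walking speeds; all
randomness descends deterministically from one seed via
`SeedSequence([seed, subject, condition, trial])`.

## 2. Analysis chain

### 2.1 Gait behavior (`gait_behavior`)

Events are detected as threshold crossings of each insole force (20 N,
first sample at/past the threshold, 50 ms debounce) and assembled into
strides (RFS → LFO → LFS → RFO → next RFS); strides with missing,
duplicated, or out-of-order interior events are dropped.  Step durations
and per-stride sacral excursions are outlier-trimmed per trial (single
non-iterative ±2.5 SD pass), pooled across a condition's trials, and
summarized as CoV (sample SD over mean).  Cells with fewer than 5 strides
are excluded.

### 2.2 EEG cleaning (`preprocess.clean_recording`), fixed order

1. 1 Hz zero-phase FIR high-pass (−6 dB at 0.5 Hz, Hamming window);
2. 20 Hz high-pass on EMG channels only;
3. sliding-window (4 s, Hann-weighted overlap-add) sinusoidal regression
   at 60/120 Hz;
4. bad-channel rejection: robust z-score (median/MAD) of channel log-RMS
   > 3 within each of the scalp and noise layers;
5. per-layer average re-referencing;
6. reference-guided CCA cleaning against the noise layer (canonical
   correlation ρ² ≥ 0.65, 4 s windows, Hann overlap-add removal), then
   against the EMG channels (ρ² ≥ 0.4);
7. window rejection: 1 s windows flagged when > 40% of channels are
   poorly predicted by the others (correlation < 0.7) or show robust
   amplitude z > 10; flagged windows form a boolean sample mask (data are
   kept continuous, the mask gates later fitting/epoching);
8. final average re-reference.

Every rejection (channel, window, component) is appended to a log with
its criterion value.

### 2.3 Decomposition and component selection

FastICA (unit-variance whitening, deterministic seed) is fit per subject
on the concatenation of all trials' cleaned scalp data (channels reduced
to those surviving in every trial; masked samples excluded from fitting,
activations computed over the full recordings).  Components are scored by
a transparent three-part brain score — dipolarity (1 − residual variance
of the best single-dipole fit), steepness of the negative 2–40 Hz
spectral slope, and low 20–45 Hz power fraction — and retained when score
≥ 0.5, slope < 0, dipole RV < 0.15, and the dipole lies inside the brain
shell.  Retained dipoles from all subjects are pooled and k-means
clustered on location (k = 11 by default, capped by the data); ±3 SD
location outliers are removed, clusters must contain at least half of
each group's subjects to be retained, and only the highest-scoring
component per (subject, cluster) enters group statistics.

### 2.4 Spectral analysis (`spectral`)

Walking epochs span −1.0 to +4.25 s around each right foot strike
(total 5.25 s); epochs overlapping masked samples are dropped, and epochs
whose gait-event latencies deviate > 3 SD are rejected.  Morlet wavelet
power uses the `[3, 0.8]` cycle convention — `cycles(f) = 3·(f/f_min)^0.2`
— on a 3–40 Hz, 1 Hz grid, decimated ×4, in dB.  Each epoch's stride is
warped to a common 0–100% gait grid (200 points) by piecewise-linear
remapping of its five event anchors onto the template (median) anchor
positions.

Muscle-artifact correction is spectral PCA: PCA over the subject's
component-by-frequency PSD-change-vs-rest observations averaged across
conditions, removal of PC1, back-projection, and addition of the rest
PSD — the *same* eigenbasis is applied to every condition of a subject so
between-condition contrasts are not distorted.

Corrected PSDs are parameterized into an aperiodic component (offset,
exponent; robust log-log fit refit on the lowest-residual 40% of points)
plus up to 2 Gaussian peaks over 3–40 Hz (width limits 1–8 Hz SD, minimum
height 0.05 log10 units), with joint curve-fit refinement and a final
aperiodic refit on the peak-subtracted spectrum.  Band power is the mean
*flattened* (aperiodic-subtracted) log-power over half-open bands
(θ 4–8, α 8–13, β 13–30 Hz).  Intra-stride peak-to-peak fluctuation is
the range of the band-average gait-cycle curve of the within-condition
normalized map (gait-cycle mean removed per frequency); common-baseline
normalization (mean across conditions) preserves between-condition
offsets instead.

### 2.5 Statistics (`stats`)

* **Bootstrap ERSP mask**: per-bin statistic is the epoch-mean deviation
  from each epoch's own gait-cycle mean; the null resamples epochs with
  replacement while shuffling each epoch's gait axis (destroying phase
  structure, preserving marginal power); two-sided p-values
  `(1+count)/(n+1)` are BH-FDR corrected over the grid (default 4000
  iterations).
* **Permutation PSD test**: between-subject factor (age) uses squared
  two-sample t per frequency with label permutation; within-subject
  factor (terrain) uses the repeated-measures F with condition labels
  permuted within subject (default 2000 permutations), BH-FDR across
  frequency.
* **Cluster-based permutation** for time-frequency maps: threshold-free
  clusters at the two-sided t criterion, max-|cluster-sum| null (default
  10000 permutations).
* **BH-FDR** is implemented directly (step-up with cumulative minimum of
  `p·m/rank`) and cross-checked against statsmodels in the tests.
* **Mixed models**: `value ~ terrain * age + speed` with a subject random
  intercept (REML; ordinary least squares fallback with a logged warning
  if the random-effect fit is singular).  Wald F tests use the
  between-within denominator-df approximation
  `df2 = n_obs − n_subjects − n_fixed + 1`; partial η² is
  `F·df1/(F·df1+df2)`.  Values beyond ±8 SD are excluded.  If the
  interaction is not significant the model is refit without it; pairwise
  terrain contrasts (estimated cell means at the mean speed, within each
  group under an interaction) are BH-FDR adjusted.

## 3. Default parameters

| Parameter | Default | Unit / note |
|---|---|---|
| Sampling rate | 500 | Hz |
| Scalp / noise / EMG channels | 32 / 32 / 4 | desk scale |
| Trial duration, walking trials | 60 s, 2 | per condition |
| Conditions | rest, Flat, Low, Med, High | |
| Stride mean, CoV | 1.2 s, 0.05 | |
| Contact threshold | 20 | N |
| Behavioral outlier cut | ±2.5 | SD, single pass |
| High-pass / EMG high-pass | 1 / 20 | Hz (−6 dB at half cutoff) |
| Line frequencies | 60, 120 | Hz |
| Bad-channel cut | 3 | robust SD |
| CCA thresholds (noise / EMG) | ρ² 0.65 / 0.4 | 4 s windows |
| Window rejection | chan 0.7, win 0.4, amp z 10 | 1 s windows |
| Brain-score / RV retention | ≥ 0.5 / < 0.15 | |
| Clusters (k), outlier cut | 11, 3 SD | |
| Epoch window | −1.0 … +4.25 | s around RFS |
| Morlet cycles | [3, 0.8] | expansion convention |
| ERSP grid | 3–40 Hz × 200 gait points | 1 Hz steps |
| Welch window | 2 | s |
| Fit range, peak limits | 3–40 Hz, width 1–8 Hz, height 0.05, ≤2 peaks | |
| Bands | θ 4–8, α 8–13, β 13–30 | Hz, half-open |
| sPCA removal | PC1 | |
| Bootstrap / PSD perms / cluster perms | 4000 / 2000 / 10000 | |
| LMM outlier cut | 8 | SD |

## 4. Numerical choices

* Zero-phase filtering by reflection-padded FFT convolution applied
  forward-backward; filter length ≈ 3.3/cutoff s (Hamming), so the −6 dB
  point sits at half the nominal cutoff, matching common EEG practice.
* CCA via Cholesky whitening + SVD with 1e-9 ridge regularization.
* Warping interpolates fractional indices of the decimated wavelet time
  axis linearly; template anchors are medians, making them robust to
  stride outliers that survive epoch rejection.
* All derived seeds are reduced modulo 2³¹ so they remain valid for
  every RNG consumer.
* EDF export scales each channel to its own 16-bit physical range
  (quantization ≤ (max−min)/65535) and stores roles/positions/metadata in
  a JSON sidecar; reading goes through MNE's independent EDF parser.

## 5. What the generator emulates — and what it does not

Emulated: 1/f-plus-peaks cortical spectra with dipolar scalp topographies;
band-limited condition/group/subject effects and stride-locked spectral
modulation; realistic stride-timing jitter; EMG, line, and sensor noise;
the dual-layer (paired noise electrode) recording concept; insole force
curves with exact threshold-crossing semantics; terrain-graded gait
variability with group differences.

Not emulated: volume-conduction inaccuracies beyond the spherical model
(no realistic anatomy), non-stationary artifact dynamics (motion
transients locked to steps, electrode pops, sweat drifts), source
non-stationarity beyond gait-phase gain modulation, eye/cardiac
artifacts, skull-conductivity variability, or any cross-frequency
coupling.  Statistical acceptance therefore targets error rates, parameter
recovery, and qualitative effect patterns — not the headline F statistics
of any particular human dataset, which depend on sample sizes and
physiological variance this generator does not claim to reproduce.

## 6. Limitations

* The dipole fit assumes a single source per scalp map; mixed maps from
  imperfect ICA separation inflate residual variance and can drop true
  cortical components at small channel counts.
* FastICA on short desk-scale recordings may not converge to a stable
  rotation; the seed is fixed and non-convergence is logged.  Study-scale
  durations behave better.
* The between-within df2 approximation is conservative for unbalanced
  data; exact Satterthwaite df are not computed.
* sPCA assumes the muscle spectrum is the dominant variance direction of
  the PSD-change observations; at very low artifact levels PC1 can
  instead capture a cortical direction and slightly bias band power — the
  same trade-off the procedure has on real data.
* The EDF writer emits plain EDF (not EDF+); annotations are carried in
  sidecars, not embedded.
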