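# Methods

## The prediction problem

Spike-and-wave discharges (SWDs) — the electrographic signature of absence
seizures — appear spontaneously, several hundred times a day, in the
cortico-thalamic system of the GAERS and WAG/Rij rat strains.  A transient
5–10 Hz oscillation near the somatosensory (S1) initiation network precedes
SWD onset by roughly 0.3–0.9 s.  `swdpredict` implements a complete
detection-and-filtering chain for this precursor:

1. **Band energies.**  For every channel, the magnitude-squared of a
   complex-Morlet continuous wavelet transform is averaged over three
   frequency bands — precursor 5–10 Hz, light slow-wave sleep 3–5 Hz,
   sleep spindles 7–20 Hz — and over a causal 500-ms window ending at each
   time point *t*, giving W_b,c(t).
2. **Cross-site products.**  W values of two or three recording sites are
   multiplied per band: P_b(t) = Π_c W_b,c(t).  Coincident elevation across
   sites (cortico-thalamic synchronization) produces large products;
   isolated fluctuations do not.
3. **Three detection criteria.**  A precursor is flagged when
   P_precursor(t) exceeds (i) a detection threshold, (ii) P_sws(t) and
   (iii) P_spindle(t).
4. **Labeling.**  Alarms within the 1-s preictal window before an SWD
   onset are true positives (TPs); alarms during the discharge or within
   1 s after its offset are discarded; all other (interictal) alarms are
   false positives (FPs).  Onsets follow the standard visual-scoring rule:
   the peak of the first spike reaching twice the background amplitude,
   earliest channel first.
5. **Random-forest filtering.**  A 1000-tree forest, fed the 6 or 9 W
   values of each alarm and trained on a class-balanced set (undersampling,
   or replication-oversampling of the TPs by a factor of 2–7, default 4),
   votes by strict majority whether an alarm is a TP; FP-voted alarms are
   suppressed.  Performance is summarized by balanced accuracy
   ((sensitivity + specificity)/2) and F1.
6. **Surrogate statistics.**  Chance level is estimated by permuting the
   training labels (class sizes preserved), retraining, and scoring the
   untouched evaluation set; performance is significant when the observed
   balanced accuracy exceeds the 95th percentile of the permutation null.

## Wavelet implementation and normalization

The CWT uses an analytic Morlet atom with dimensionless center frequency
ω₀ = 2π: in the frequency domain a Gaussian of width σ_f = f₀/ω₀ with unit
peak gain and zero response at negative frequencies, evaluated on a 0.5-Hz
grid inside each band.  A unit-amplitude tone therefore yields |coef|² =
1/4 at its own frequency regardless of f₀, and the transform is linear in
power.  The transform is computed by one FFT per channel and one inverse
FFT per analysis frequency (reflection padding of 2 s at the edges), which
keeps memory flat and makes 24-h records tractable on a single core; the
`pywt` cmor implementation (`cmor2.0-1.0`, the same atom) serves as an
independent cross-check in the tests.  Being constant-Q, the atom smears a
tone over a bandwidth proportional to its frequency; in-band energy of a
15 Hz tone inside a 2-Hz band therefore under-counts relative to a 4 Hz
tone by its analytic capture mass — tests account for this closed-form
factor when comparing against periodogram band powers.

Band energies are **normalized per channel and band** by the
whole-recording median of the windowed series, then multiplied by a fixed
scale `norm_scale = 0.25`.  Median division makes W dimensionless and
transferable across recording gains.  The scale pins the *operating range*
of the three-site product: baseline products sit near 0.25³ ≈ 0.016, well
below the standard 14-value threshold grid [0.1, 0.75], while precursor
products (per-channel boost ≈ 4–8× the median under the generator's
default conditions) land inside and above it.  No single normalization can
make the historical two-site grid [0.005, 0.04] operative at the same
time — the magnitude gap between published two- and three-factor
thresholds reflects the product order, not a transferable scale — so the
default two-site grid keeps its 16 values but spans [0.2, 2.4] in package
units, with endpoints at sensitivity/false-alarm saturation, the same
principle used to set the original ranges.

## Alarm semantics

At sample-by-sample stride, one precursor would cross the threshold
hundreds of times.  The detector therefore fires at the *first*
super-threshold sample and re-arms only after a refractory dead time
(default 1.0 s), exactly like an online alarm system.  This greedy
extraction is the maximum packing of the super-threshold time-set at the
given minimum separation, which makes the alarm count provably
non-increasing in the threshold — the property that grid sweeps and their
monotonicity checks rely on.  (Merging adjacent runs instead, a plausible
alternative, loses this guarantee: runs split as the threshold rises.)
Alarms during the discharge and in the 1 s after offset are discarded
rather than counted as false alarms, because the causal 500-ms window and
the wavelet tails still contain ictal signal there.

Threshold calibration ("reach X% sensitivity") probes a descending log
grid from the maximum product and bisects within the bracketing interval,
returning the largest threshold that still reaches the target.
Sensitivity is monotone only on this upper branch; far below the baseline
product the dead-time extraction saturates and sensitivity *falls* again,
so a bottom-up search would fail.  An unreachable target returns the
argmax-sensitivity threshold, flagged.

## Synthetic recordings

No public recordings accompany the method, so the generator produces
annotated surrogates with the statistical structure the pipeline assumes.

| ingredient | default | rationale |
|---|---|---|
| background | 1/f¹ Gaussian noise, σ = 150 µV | typical LFP spectrum; 2×p99 ≈ 700 µV matches cortical spike amplitude |
| SWD rate | 17/h (GAERS), 10/h (WAG/Rij) | reported strain averages |
| SWD morphology | Gaussian spike + opposing half-sine per cycle, 5–7 Hz (GAERS) / 8–10 Hz (WAG/Rij), 10–30 s / ~7 s | harmonic-rich spike-wave train; spike peak = 2 × p99(|background|), so the onset rule is exactly satisfiable; thalamic channels 500 vs 700 µV, broader, reversed polarity |
| diurnal modulation | ±50% cosine, peak at hour 12 | documented dark-phase maximum of SWD occurrence |
| precursor | 5–10 Hz burst, 0.3–0.9 s lead, Tukey(0.25) envelope; 1.0 σ in S1-role channels, 0.3 σ thalamic, 0 elsewhere | strong cortical expression near the initiation network, weak thalamic spread |
| arousal theta | 480/h, 5–9 Hz, 0.4–1.0 σ, full 2nd harmonic, uneven channel gains | dominant false-alarm source; sawtooth-like rodent theta puts its harmonic (10–18 Hz) in the spindle band, which is what makes TP/FP discrimination learnable |
| spindles | 60/h, 8–16 Hz, 0.5–1.5 s, 1.0 σ | vetoed mostly by criterion 3; residual confounder |
| slow-wave sleep | 10 epochs/h, 30–120 s, 3–5 Hz, 0.8 σ | vetoed by criterion 2 |
| confounder gain | 1.0 cortical, 1.5 thalamic | sleep oscillations and volume-conducted theta are more prominent in thalamic recordings, making intrathalamic combinations the most false-alarm-prone |

Seizure times are an inhomogeneous Poisson draw (thinning) with rejection
placement enforcing a 5-s minimum gap; up to 1000 rejections, then the
remainder is dropped.  Everything is driven by one `numpy` Generator seed
and is bit-reproducible.

**What the generator does not emulate:** real spike-wave waveforms (only
their frequency/amplitude/duration statistics), behaviorally coherent
sleep architecture, movement and electrode artifacts, inter-animal
variability, and volume-conduction correlations beyond the simple shared
bursts.  Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes — site ordering, threshold monotonicity,
separable TP/FP spectra — not that it would reach the same numbers on rat
recordings.  One visible consequence: within each cluster of
combinations, sensitivity and false-alarm rate are negatively related
(intrathalamic triples are the most false-alarm-prone and least
sensitive; the S1 triple the opposite), but the *overall* Pearson
correlation across all 85 combinations is only weakly negative, because
the relative false-alarm level of two- versus three-site analyses
depends on real-data noise structure the generator does not model.

## Protocols and problem sizes

In-sample evaluation splits each recording chronologically at 70% of its
duration (train early, evaluate late — pseudo-prospective; a random split
is not offered because it would leak temporally adjacent alarms).  One
hundred forests are trained on fresh false-positive samples and the forest
closest to the mean hold-out balanced accuracy is retained as
representative; tests and the acceptance script use 10 forests of
500–1000 trees, which reproduces the mean within ~1 SD at a fraction of
the cost.  The permutation test retrains per randomization (not merely
permuting predictions); the CLI default is 200 randomizations with
`--n-perm` available for the full 1000.

Analysis runs in tests and the acceptance script use 128 Hz recordings
with a 50-ms stride: all analysis bands lie below 20 Hz, so nothing
spectral is lost, and a full synthetic day processes in ~4 minutes of
single-core time.  At these settings the 24-h end-to-end run (threshold
calibrated to 90% sensitivity, 4× oversampled forest) yields ~80–100
false alarms/h before filtering, ~92% false-alarm reduction, 45–54% of
held-out SWDs still predicted, and hold-out balanced accuracy of 72–76% —
the same qualitative trade-off reported for the method on real data
(strong false-alarm reduction bought with roughly half of the prediction
sensitivity, low F1 driven by the residual class imbalance).

## Numerical conventions and edge cases

* Time is seconds from record start; conversions round half away from
  zero to the nearest sample.
* Band-energy timestamps are the right edges of causal windows; the first
  valid time is one window length into the recording.  Values at shared
  timestamps are stride-invariant (the normalizing median is computed at
  full sample resolution).
* A zero or constant channel has zero median band energy and raises a
  degenerate-signal error rather than returning NaNs.
* Filtering is zero-phase (forward–backward Butterworth band-pass 1–100 Hz
  plus a Q=30 notch at 50 Hz), diverging from the causal acquisition
  hardware so that event times are not shifted.
* EDF files are plain EDF, 16-bit, physical range ±5000 µV (quantization
  step ≈ 0.153 µV); annotations live in a sidecar CSV.
* Majority-vote ties in the forest (even tree counts) suppress the alarm.
* The add-one permutation p-value (1 + #{null ≥ obs})/(1 + n) is never
  zero; the 95th percentile uses linear interpolation.

## Known limitations

* Absolute detection thresholds are meaningful only within this package's
  normalization; thresholds from other implementations cannot be compared
  directly (only grid sizes and calibration targets transfer).
* The classifier's feature vector is sampled at the alarm instant, where
  criterion 1 pins the precursor-band product near the threshold for both
  classes; discrimination rests on the slow-wave and spindle bands.  Real
  false alarms with precursor-band-only signatures would be
  indistinguishable, as they are for the original method.
* `calibrate_threshold` assumes at least five annotated SWDs and a
  precursor expressed in the analyzed channels; records without
  precursors return a flagged, unreached calibration.
* The generator's confounder rates set the difficulty of the filtering
  stage; conclusions about absolute false-alarm rates do not transfer to
  real data.
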