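# swdpredict

Prediction of spike-and-wave discharges (SWDs) — the electrographic
signature of absence seizures — from multichannel local field potential
(LFP) recordings of the rodent cortico-thalamic system, for
electrophysiologists and methods researchers working with the GAERS and
WAG/Rij genetic absence-epilepsy models.

SWDs are preceded, ~0.3–0.9 s before onset, by a transient 5–10 Hz
oscillation near the cortical initiation network in deep somatosensory
cortex (S1).  `swdpredict` implements the full wavelet-product prediction
chain around this precursor:

* **Spectral features** — per channel *c* and band *b*, the mean Morlet
  wavelet energy W<sub>b,c</sub>(t) over a causal 500-ms window, in three
  bands: precursor 5–10 Hz, slow-wave sleep 3–5 Hz, spindles 7–20 Hz;
  cross-site synchrony as the product over 2–3 recording sites,
  P<sub>b</sub>(t) = Π<sub>c</sub> W<sub>b,c</sub>(t).
* **Detection** — an alarm fires when P<sub>precursor</sub>(t) > θ and
  P<sub>precursor</sub>(t) > P<sub>sws</sub>(t) and
  P<sub>precursor</sub>(t) > P<sub>spindle</sub>(t), with a 1-s dead time;
  thresholds are swept over standard grids or calibrated to a target
  sensitivity.
* **Evaluation** — alarms in the 1-s preictal window are true positives;
  sensitivity = predicted SWDs / all SWDs × 100%, plus false alarms per
  hour; site combinations are grouped (CC, CT, TT, CCC, CCT, CTT, TTT,
  MCCC) by cortical/thalamic membership.
* **False-alarm filtering** — a 1000-tree random forest over the 6–9
  band-energy features of each alarm, trained on class-balanced sets
  (undersampling or 4× replication-oversampling), majority vote, evaluated
  by balanced accuracy and F1 on a chronological 70/30 split.
* **Surrogate statistics** — label-permutation retraining (default 200,
  up to 1000 randomizations); performance counts as above chance when it
  exceeds the 95th percentile of the null.
* **Synthetic recordings** — a seeded generator of annotated GAERS- and
  WAG/Rij-like LFPs (1/f background, spike-wave trains with the strains'
  rates/frequencies/durations, diurnal rate modulation, S1-weighted
  precursors, arousal-theta / spindle / slow-wave confounders), so the
  whole pipeline is testable without animal data.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

Simulate one hour of a GAERS-like animal recorded in the three deep S1
layers, then sweep the standard 14-value threshold grid for the
intracortical triple (CCC):

```sh
swdpredict simulate --strain gaers --duration 3600 --fs 200 --seed 7 \
    --out rec.npz --annotation-out ann.csv
swdpredict sweep --record rec.npz --annotation ann.csv \
    --sites S1_L4,S1_L5,S1_L6 --stride 0.05 --out sweep.csv
```

The simulate step prints

```
wrote rec.npz (3 ch, 3600 s) with 9 SWDs
```

and the sweep table starts

```
      combination group  threshold  sensitivity_pct  fp_per_h  n_tp  n_fp  n_swd
S1_L4+S1_L5+S1_L6   CCC       0.10            100.0     230.0     9   230      9
S1_L4+S1_L5+S1_L6   CCC       0.15            100.0     183.0     9   183      9
S1_L4+S1_L5+S1_L6   CCC       0.20            100.0     155.0     9   155      9
```

Read: at a detection threshold of 0.1 (normalized product units) all 9
SWDs in this hour are predicted (an alarm falls in the 1-s window before
their onsets), at the cost of 230 interictal false alarms per hour; both
sensitivity and the false-alarm rate fall monotonically as the threshold
rises.  The `swdpredict run` command chains the remaining stages —
threshold calibration, random-forest training, filtering and the
permutation test — from a YAML config (see `swdpredict run --help`; the
built-in smoke configuration runs a 10-minute record end to end in under
two minutes).

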