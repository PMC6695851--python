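# avfppg

PPG-based assessment of arteriovenous-fistula (AVF) quality for
hemodialysis patients: a hemodynamic forward model linking vessel
stenosis and blood-flow volume to measurable photoplethysmography
features, a software emulation of the sensor readout chain, and three
machine-learning classifiers with a subject-level cross-validation
protocol.

## What is in the box

| module | what it does |
| --- | --- |
| `avfppg.hemodynamics` | Beer–Lambert optics, perfusion index (AC/DC), Womersley-corrected transmission-line vessel model (R, L, G, C, propagation constants, characteristic impedance), degree of stenosis (DOS, %) and average blood-flow volume (BFV, mL/min) — both forward (vessel → features) and inverse (features → DOS/BFV) |
| `avfppg.readout_dsp` | heart-rate estimation, heart-rate-adaptive 4th-order Butterworth band-pass (0.2–0.8 / 5–10 Hz clips), PGA + ADC emulation, pulse-foot beat segmentation, per-beat perfusion-index extraction |
| `avfppg.classify` | min/max normalization to [−1, 1], kNN, Gaussian naive Bayes, soft-margin RBF SVM (kernel `exp(−‖xi−xj‖²/σ)`), nested grid search, stratified 10-fold subject-level CV, confusion-matrix metrics (accuracy, type I/II error) |
| `avfppg.synthetic_data` | seeded synthetic hemodialysis cohorts generated through the forward model (noise-free cohorts close the feature→DOS/BFV inverse exactly) and raw PPG waveform records (>90 % DC, mains interference, drift, noise) |
| `avfppg.cli` | `avfppg simulate / extract / evaluate / report` |

The two screening tasks use the feature sets
`(PI_max, PI_min, SpO2, SBP, DBP)` for DOS and the same plus heart rate
for BFV. Label polarity follows the clinical convention: *positive*
means the fistula passes the check (DOS < 30 %, BFV > 600 mL/min), so
the type II error `FN/(TP+FN)` is the rate of flagging a passing access
as failing.

## CLI

```sh
# 1. generate a synthetic cohort (features + raw PPG records + manifest)
avfppg simulate --seed 1 --n 74 --task dos --out scratch/sim

# 2. extract PI_max / PI_min / HR from the raw waveforms
avfppg extract --in scratch/sim --out scratch/features.csv

# 3. cross-validate the classifiers and write a JSON report
avfppg evaluate --features scratch/features.csv --task dos \
    --classifier all --seed 1 --out scratch/report.json

# metrics from an externally produced prediction file
avfppg report --predictions preds.csv
```

Exit codes: 0 success, 2 configuration error, 3 data error. A YAML
config (`--config`) can override physics constants (`physics:`),
cohort/waveform generation (`synth:`), classifier grids (`classify:`)
and the readout model (`readout:`); unknown keys are warned about and
ignored.

Waveforms are plain CSV, either `time,amplitude` columns or a single
`amplitude` column with a `# fs=<Hz>` header line. Feature tables are
CSV with columns
`subject_id,pi_max,pi_min,spo2,sbp,dbp,hr,dos_pct,bfv_ml_min,dos_label,bfv_label`.

## Notes

- Internal physics is CGS; blood pressures enter in mmHg
  (1 mmHg = 1333.22 dyn/cm²) and flows are reported in mL/min.
- The characteristic impedance uses the standard radical form
  `Z0 = sqrt((R + jωL)/(G + jωC))`, with `G = 0`.
- `poiseuille_pi: false` in the physics config reproduces the
  non-standard Poiseuille bookkeeping without the 1/π.
- All randomness flows through explicit integer seeds; reruns are
  byte-identical.
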