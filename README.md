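# pulsebp

Cuffless, continuous blood-pressure estimation from coupled
photoplethysmogram (PPG) and electrocardiogram (ECG) waveforms.

Invasive arterial lines measure blood pressure continuously but require
clinical expertise; cuff devices are intermittent and motion-sensitive. A
long line of work instead infers pressure from the *timing* between the
electrical heartbeat (the ECG R peak) and the arrival of the pressure pulse
at an optical sensor (the PPG) — the pulse arrival time, PAT — together with
heart rate. `pulsebp` implements a complete such system for researchers
working with monitor waveform archives (PPG + ECG + an arterial-pressure
channel for labels, 125 Hz):

- **Preprocessing** — eligibility filtering (PPG, ABP, limb-lead I/II/III
  ECG), 8-s windowing with flat/missing-value rejection, zero-phase
  bandpass (0.5–20 Hz PPG, 2–20 Hz ECG), Pan–Tompkins R-peak detection,
  two-beat segmentation resampled to 200 points, systolic/diastolic label
  extraction from the raw ABP (SBP = peak, DBP = trough), and exclusion of
  segments outside 90–200 / 50–110 mmHg with pulse pressure 20–70 mmHg.
- **Model** — two stride-2 Conv1D encoder branches (64×2, 32×4, 16×6, 16×4
  filters×kernel; feature maps 200 → 100 → 49 → 22 → 10), batch norm + ELU
  throughout, max-pooled to length-32 latents `Z_PPG`, `Z_ECG`, fused by
  concatenation into the 64-long hybrid vector `Z_hybrid = Z_PPG ++ Z_ECG`,
  processed by a 32-unit LSTM, then a head on `Z̄ ++ rr1 ++ rr2` with a
  16-unit ELU hidden layer and a softplus output:
  `ŷ = softplus(ELU((Z̄ ++ x_RR1 ++ x_RR2)·W_h + b_h)·W_out + b_out)`.
  One network per target (SBP, DBP), trained under MSE; ~38.7k trainable
  parameters. Implemented in pure NumPy with explicit backpropagation and
  Adam — no deep-learning framework required.
- **Protocol** — per-subject 77/23 train/test split, tenfold
  cross-validation, best-on-test model selection.
- **Evaluation** — Pearson r, MD, MAE, SD (population form), cumulative
  error percentages at 5/10/15 mmHg, BHS letter / AAMI pass-fail / IEEE
  letter grading, and Bland–Altman agreement summaries.
- **Synthetic generator** — coupled 125 Hz ECG/ABP/PPG records with known
  beat times, PAT, and a known (PAT, HR) → pressure mapping plus controlled
  corruption, so every stage is testable without access to clinical data.

See `docs/methods.md` for the model conventions, design decisions, and what
the synthetic validation does and does not demonstrate.

## Worked example

The full chain on synthetic data, from the library:

```python
from pulsebp import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=101, out_dir="demo_out")
cfg.synth.n_subjects = 10
cfg.synth.record_seconds = 150.0
cfg.train.max_epochs = 35
cfg.train.patience = 5
cfg.train.learning_rate = 2e-3
manifest = run_pipeline(cfg)
```

or equivalently from the shell with `bp-pipeline run --config demo.yaml`
(`bp-pipeline init-config demo.yaml` writes the editable defaults). The run
prints per-stage tallies and finishes with an evaluation summary:

```
simulate   {'n_records': 10, 'n_beats': 2098}
preprocess {'windows_total': 180, 'windows_flat_or_missing': 0,
            'segments_raw': 1639, 'segments_bp_excluded': 75,
            'segments_kept': 1564}
train      {'target': 'sbp', 'n_segments': 1564, 'n_test': 361,
            'n_folds_trained': 10, 'selected_fold': 0}
evaluate   {'n_test': 361, 'mae': 2.678, 'sd': 3.424, 'r': 0.9589,
            'grades': {'bhs': 'A', 'aami': 'Pass', 'ieee': 'A'}}
```

Reading: 1,564 two-beat segments survived quality control and the pressure
exclusions; ten models were trained by cross-validation and the best on the
test split was selected. On the 361 held-out segments its systolic
predictions err by 2.68 mmHg on average (error SD 3.42 mmHg, correlation
0.959 with the true labels) — grade A under the BHS cumulative-percentage
criteria, a pass under the AAMI bias/spread bounds, and grade A under the
IEEE MAE bands. `demo_out/report.json` additionally carries the
Bland–Altman summary (here: mean difference +0.18 mmHg, limits of agreement
−6.53 to +6.90 mmHg).

Because the generator's subjects encode pressure purely through PAT and
heart rate, and subjects appear on both sides of the split, these numbers
characterize the pipeline's correctness, not expected clinical accuracy.

## Layout

```
src/pulsebp/
  records.py     record containers, CSV container I/O, segment store
  preprocess.py  the seven-stage chain
  qrs.py         Pan–Tompkins R-peak detector
  layers.py      NumPy layers with explicit backprop
  network.py     the Conv1D-LSTM regressor
  training.py    split / folds / Adam / cross-validation / selection
  evaluation.py  metrics, grading standards, Bland–Altman
  synthetic.py   coupled-waveform generator with ground truth
  config.py      YAML pipeline configuration
  pipeline.py    stage orchestration + manifest
  cli.py         the bp-pipeline command
```
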