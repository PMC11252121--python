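# Methods

`pulsebp` estimates systolic (SBP) and diastolic (DBP) arterial pressure from
simultaneously recorded photoplethysmogram (PPG) and electrocardiogram (ECG)
waveforms, using the invasive arterial blood pressure (ABP) channel only to
derive training labels. This note documents the model, the preprocessing
conventions, the synthetic data the package is validated on, and the design
choices made where more than one reasonable construction existed.

## Physiological premise

Pressure information reaches the PPG/ECG pair through timing: the pulse
arrival time (PAT) — the delay between the ECG R peak and the arrival of the
pressure pulse at the optical sensor — shortens as pressure rises (stiffer,
faster-conducting arteries), and heart rate co-varies with pressure. The
network is therefore given a two-beat excerpt of both waveforms, aligned at R
peaks, plus the two R-R interval durations as explicit scalar features.

## Preprocessing chain

Records must contain PPG, ABP and a limb-lead (I/II/III) ECG, all resampled
to 125 Hz. Processing order, applied per record:

1. **Windowing** — consecutive non-overlapping 8-s windows (1000 samples);
   a trailing remainder is discarded.
2. **Quality control** — a window is rejected if its PPG or ECG contains any
   non-finite sample or has peak-to-peak range ≤ `flat_tolerance` (default
   1e-6 amplitude units; sensor dropouts produce exactly this signature).
   Windows whose ABP contains non-finite values are also rejected, since
   their labels would be meaningless.
3. **Bandpass** — 4th-order Butterworth, 0.5–20 Hz for PPG and 2–20 Hz for
   ECG, applied forward-backward (zero phase). Zero-phase filtering is
   load-bearing: a causal filter would delay the two channels differently
   and corrupt the PAT information the model relies on.
4. **R-peak detection** — Pan–Tompkins on the filtered ECG: 5–15 Hz QRS
   emphasis, five-point derivative, squaring, 150-ms moving-window
   integration, adaptive dual thresholds learned from the first 2 s with a
   200-ms refractory period and a search-back pass; detected integration
   peaks are refined to the nearby absolute ECG maximum.
5. **Two-beat segmentation** — for every triple of consecutive R peaks
   (r_i, r_{i+1}, r_{i+2}) inside a window, the span [r_i, r_{i+2}) is cut
   identically from PPG, ECG and ABP; rr1 and rr2 are the two R-R intervals
   in seconds. Segments slide one beat at a time (overlapping); two-beat
   tiling is available via `beat_stride=2`. Segments never straddle window
   boundaries.
6. **Resampling** — PPG and ECG spans are linearly interpolated to exactly
   200 points.
7. **Labels and exclusion** — SBP = max, DBP = min of the *raw* (unfiltered)
   ABP over the span; filtering ABP would distort absolute pressure.
   Segments are kept only if 90 ≤ SBP ≤ 200, 50 ≤ DBP ≤ 110 and
   20 ≤ PP ≤ 70 mmHg (PP = SBP − DBP), all bounds inclusive.

## Network

Two weight-independent encoder branches process the 200-point PPG and ECG.
Each branch stacks four valid (no-padding) stride-2 Conv1D layers — 64×2,
32×4, 16×6, 16×4 (filters × kernel) — each followed by batch normalization
and an ELU (α = 1). Feature-map lengths are 200 → 100 → 49 → 22 → 10.
Temporal max pooling (size 5, stride 5) reduces the final 16 × 10 map to
16 × 2, flattened channel-major to a latent vector of length n = 32.

The two latents are concatenated PPG-first into a 2n = 64 hybrid vector,
batch-normalized, and passed to an n-unit LSTM whose final short-term state
is the summary Z̄. Z̄ is concatenated with (rr1, rr2), passed through
dropout (rate 0.2), a 16-unit ELU hidden layer, and a single softplus output
neuron, so predictions are strictly positive. Inputs are z-scored per
segment before the encoders; rr1/rr2 enter in raw seconds. One such network
is trained per target under a mean-squared-error loss; the R-R features can
be ablated (`use_rr=False`), which narrows the head input from n+2 to n.

**LSTM input shaping.** The hybrid vector admits two readings: a sequence of
2n scalar timesteps, or a single timestep carrying all 2n features. Both are
implemented (`lstm_mode`); the single-timestep form is the default. In the
scalar-sequence form the PPG half of the vector must survive 32+ recurrent
steps before reaching the output, and at desk scale training reliably
plateaus at the target mean (r ≈ 0.07 in our experiments), while the
single-timestep form trains to r > 0.95 on the same data. The
single-timestep form also gives 38,721 trainable parameters, consistent with
the ~37k scale this architecture is known for (the scalar-sequence reading
gives 30,657). Parameter counts exclude batch-norm running statistics.

**Initialization.** Uniform fan-in scaling for convolutional and dense
weights, orthogonal recurrent blocks, forget-gate bias 1, and — importantly —
the output bias starts at softplus⁻¹(100 mmHg). Softplus(0) ≈ 0.69 mmHg is
two orders of magnitude below any arterial pressure, and with a unit-scale
bias the optimizer spends >10⁴ steps climbing to the right range before any
feature learning happens. All initialization is driven by a recorded seed;
compute runs in float32 by default (float64 available, used by the gradient
tests).

## Training protocol

Segments are split per subject ≈77 % / 23 % into train and test (random
within subject, seeded; rounding to the nearest integer with at least one
segment on each side). The training portion is shuffled into ten folds of
near-equal size; one model is trained per fold on the other nine (Adam,
default lr 1e-3, batch 256, early stopping on held-out-fold MAE), and the
model with the lowest *test-set* MAE is selected (ties: lower error SD, then
lower fold index).

Two caveats are inherited deliberately rather than "fixed", because they are
part of the protocol being reproduced: every subject contributes to both
train and test (within-subject information sharing), and model selection
uses the test set. Both inflate apparent accuracy relative to a
subject-held-out evaluation.

## Evaluation

For errors e_t = ŷ_t − y_t: MD = mean(e), MAE = mean|e|, SD = the
*population* (divisor m) standard deviation of e about MD, Pearson's r
between y and ŷ, and cumulative percentages CP5/CP10/CP15 of |e| ≤ 5/10/15
mmHg (inclusive). Grading:

- **BHS**: A requires CP5 ≥ 60, CP10 ≥ 85, CP15 ≥ 95 (%); B: 50/75/90;
  C: 40/65/85; else D. Comparisons inclusive.
- **AAMI**: pass iff |MD| ≤ 5 and SD ≤ 8 mmHg. The absolute value matters: a
  −0.5 mmHg bias passes exactly as +0.5 does.
- **IEEE**: by MAE band, A ≤ 5 < B ≤ 6 < C ≤ 7 < D (7 exactly grades C).

The Bland–Altman summary reports MD, limits of agreement MD ± 1.96·SD, the
95 % CI of MD (± 1.96·SD/√m), and the same three band percentages.

## Synthetic data generator

The generator emulates exactly the statistical structure the model assumes —
pressure encoded in PPG–ECG timing and heart rate — with analytic waveform
templates (Gaussian QRS complex with Q/S/T companions; raised-cosine
pressure and volume pulses with a small dicrotic bump) so that every beat
time, PAT and pressure is known exactly. Per subject, heart rate
(60–100 bpm) and PAT (0.20–0.40 s) evolve as bounded random walks
(steps 1 bpm and 8 ms per beat), and each beat's pressures follow

    SBP = 40 + 18/PAT + 0.15·HR + ε,   ε ~ N(0, 3 mmHg)
    DBP = 30 +  8/PAT + 0.08·HR + ε

clamped to 90–180 / 50–110 mmHg. The inverse-PAT form echoes
pulse-wave-velocity physiology; the coefficients place typical subjects near
120/70 mmHg with realistic spreads. Corruption modes inject constant-PPG
8-s windows, NaN runs in ECG, and runs of beats forced past each of the six
pressure bounds (corrupted-pressure beats never share a window with
flat/missing corruption, so each exclusion rule remains observable).

What the generator does **not** emulate: waveform-morphology changes with
pressure (real PPG shape carries additional pressure information), baseline
wander, motion artifacts beyond flat/missing, arrhythmias, sensor-specific
noise spectra, or inter-subject template variability. Passing tests
therefore demonstrate that the pipeline and model recover pressure when the
assumed timing information is present — not that clinical-grade accuracy
would be achieved on hospital waveforms.

## Problem sizes and numerics

The end-to-end validation trains the full tenfold protocol on 20 synthetic
subjects × 150 s (≈3,000 two-beat segments; the test suite uses a
10-subject variant) with lr 2e-3, ≤35 epochs, patience 5 — sizes chosen so
the whole chain runs in minutes on one CPU while leaving the pass margins
wide (observed test MAE ≈ 2.7 mmHg against thresholds of 5, r ≈ 0.96
against 0.85). Degenerate inputs are defined, not silently handled:
zero-variance inputs make Pearson's r undefined (reported as NaN with a
flag), empty prediction sets raise, sub-2-point resampling raises, and a
diverging fold (non-finite loss) is aborted with a diagnostic rather than
propagated. Pearson/SD/CP computations follow the definitional formulas
exactly; tests pin them to plain-loop oracles at 1e-12 relative error.

## Known limitations

- No real-waveform reader beyond the CSV-per-record container; hospital
  archive formats must be converted first.
- The Pan–Tompkins constants are tuned for adult resting rhythms; extreme
  tachycardia (>180 bpm) would collide with the 0.2-s refractory period.
- Within-subject splitting means reported metrics should not be read as
  generalization to unseen subjects.
- The LSTM consumes one fused vector per segment; no state is carried across
  segments, so slow per-subject drifts are visible to the model only through
  rr features and waveform shape.
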