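# Methods

`pulse2abp` implements a signal-to-signal approach to cuff-less blood
pressure estimation: a photoplethysmogram (PPG) is translated into a
continuous arterial blood pressure (ABP) waveform by a recurrent
autoencoder, and systolic/diastolic pressures (SBP/DBP) are read off the
translated waveform as its per-segment extrema. This note records the
model, the preprocessing and quality-control conventions, the synthetic
data generator, and the numerical and design choices that were genuinely
open.

## Signal model and preprocessing

Both channels are sampled at 125 Hz. Records are cut into fixed-length
segments (half-open windows, non-overlapping by default); the default
segment length for full-length synthetic data is 1024 samples (≈8.2 s).

1. **Denoising.** The PPG is bandpass filtered with a third-order
   Butterworth, passband 0.5–8 Hz. The filter is applied
   forward-backward (zero phase): the inter-channel phase lag is
   estimated and corrected separately, and phase distortion inside a
   pulse would corrupt the derivative channels. A zero-phase cascade
   squares the magnitude response, which only sharpens the band edges;
   the passband gain at 2 Hz changes by well under 5% and the stopband
   attenuation at 0.1 Hz exceeds 20 dB. The ABP is not filtered — it is
   the regression target and the source of SBP/DBP ground truth.
2. **Normalization.** Each training PPG is z-scored with its own mean μ
   and *population* (ddof = 0) standard deviation σ. At test time the
   averages (μ̄, σ̄) of the per-signal training parameters are applied to
   every signal, so inference needs only a stored two-number sidecar.
   The ABP target is scaled with a single global (μ̄, σ̄) fit the same way
   on the training ABP, and predictions are inverted back to mmHg with
   it. The target-side convention is an implementation choice: some
   global, invertible scaling is required for a mean-squared-error loss
   in normalized units, and averaging per-signal parameters mirrors the
   input-side convention.
3. **Alignment.** The PPG lags the ABP by less than one pulse period.
   The lag Δt is the argmax over Δt ∈ [0, max_lag) of the valid-overlap
   cross-correlation g(Δt) = Σₜ ABP[t]·PPG[t+Δt]. Both series are
   mean-removed before the search: with a positive-offset ABP the
   truncated overlap otherwise biases the argmax by ±1 sample, while on
   mean-removed series the recovery is exact for every lag (verified
   exhaustively in the tests). The PPG is advanced by Δt; the ABP is
   never shifted; the trailing Δt samples exposed by the shift are
   dropped and both channels trimmed equally, so no samples are
   invented. For batching, all aligned pairs are finally cropped to the
   common length `segment_len − max_lag`.
4. **Derivatives.** The model input is the 3-channel stack (PPG, dPPG,
   sdPPG): the blood-volume-change velocity and acceleration carry the
   vessel-state information that correlates with pressure. Derivatives
   use the two-point central difference [f(x₊₁) − f(x₋₁)]/(2h) with
   h = 1/125 s (O(h²) at interior points) and first-order one-sided
   differences at the two endpoints so every channel keeps the input
   length; `numpy.gradient` implements exactly this stencil.

## Quality control

Four retention rules are evaluated on every aligned segment and all are
always reported, so the elimination funnel can be audited per reason:

| rule | condition to pass | note |
|---|---|---|
| sbp_range | 80 ≤ max(ABP) ≤ 180 mmHg | strict beyond-bounds elimination: 180 itself passes |
| dbp_range | 60 ≤ min(ABP) ≤ 130 mmHg | likewise at 60 |
| low_correlation | Pearson r(PPG, ABP) ≥ 0.8 after alignment | r computed per segment on the whole aligned pair |
| no_peak | ≥ 2 usable PPG systolic peaks | see detector below |

SBP/DBP for QC are taken from the raw (unnormalized) ABP in mmHg. A
constant PPG has undefined correlation and is reported as
`low_correlation` (and fails peak detection as well).

**Peak detector.** The systolic peak detector is a moving-average
adaptive threshold: the filtered PPG is compared against its 0.75 s
rolling mean raised by a swept percentage (0–50%) of the signal's
mean-to-maximum span; region maxima above the threshold are candidates;
candidates implying an instantaneous rate above 180 bpm are merged
(higher peak wins) and boundary-sample maxima (truncated beats) are
dropped. Among sweep settings whose implied rate lies in 40–180 bpm,
the one with the most regular inter-peak intervals is kept — a low
threshold lets dicrotic waves through as spurious "beats", which this
regularity criterion rejects. A segment has usable peaks only if at
least two survive, the median-interval rate is in 40–180 bpm, the
interval coefficient of variation is ≤ 0.5, and the signal's
autocorrelation at the median interval is ≥ 0.3; the last check is what
separates genuinely periodic pulse trains from band-limited noise, whose
threshold crossings can be deceptively regular.

## Translator

The translator is a sequence-to-sequence LSTM autoencoder:

* encoder: 2 stacked LSTM layers (standard forget/input/output-gate
  cell), default 128 hidden units each;
* decoder: 2 stacked LSTM layers, a dropout layer (rate 0.2) at the end
  of the decoding phase, and a per-timestep linear projection to one
  output channel.

The latent representation is the full per-timestep hidden-state
sequence (T × H), not a single bottleneck vector, so an input of any
length T ≥ 3 maps to an output of the same length.

Training is two-stage transfer learning:

1. **Reconstruction.** The full network is trained to reproduce the
   PPG channel (channel 0 of the stack) from the 3-channel input. The
   target is PPG-only so the decoder head already has the one-channel
   shape it keeps in stage 2.
2. **Translation.** The encoder is frozen — bit-exact parameter
   invariance is enforced and tested via SHA-256 digests — and the
   decoder (carried over from stage 1, not re-initialized) is retrained
   against the globally z-scored ABP. Training a translation-stage
   model with an unfrozen encoder is a contract violation and raises.

Loss is mean squared error (the natural choice for waveform
reconstruction error; no other loss is implied by the task). The
optimizer is Adam at learning rate 0.0025 with up to 50 epochs by
default; batches of 128; gradients are clipped at global norm 5 for
robustness; early stopping monitors validation loss with patience 5 and
the best-epoch parameters are restored. Non-finite losses abort with
the learning rate, batch and epoch in the message. Data are split
70/10/20 into train/validation/test at the *subject* level so no
subject's segments leak across partitions.

The network engine is written directly in NumPy (LSTM forward pass,
full backpropagation through time, inverted dropout, Adam), with
float32 parameters and a Python loop only over time steps. Gradients
are verified against central finite differences in the test suite.
Because the frozen encoder is deterministic, stage 2 encodes the corpus
once and trains the decoder on cached latent sequences — identical
arithmetic, computed once. All randomness flows from explicit seeds;
runs are bit-reproducible in a single-threaded environment.

## Evaluation

The unit of error is the per-segment SBP/DBP: maxima/minima of the
predicted and observed ABP segments, error = predicted − observed in
mmHg. Reported metrics: MAE, RMSE, population STD of the signed error,
Pearson correlation between predicted and observed SBP (and DBP)
values, and an absolute-error histogram (≤5 / 5–10 / 10–15 / >15 mmHg).

**BHS grading** scores the cumulative percentages of |error| within
5/10/15 mmHg against grade rows A: 60/85/95, B: 50/75/90, C: 40/65/85;
an error exactly on a threshold counts as within it, and a grade
requires all three of its percentages.

**AAMI-style check** follows the convention of this model family — MAE
< 5 mmHg, error STD < 8 mmHg, on more than 85 subjects, all strict —
rather than the formal standard's mean signed error; the convention is
reproduced deliberately, not corrected, so results remain comparable.

## Synthetic data generator

No public waveform database ships with the package; a generator
produces paired segments with known ground truth so every stage is
testable offline.

Each beat is the sum of two Gaussian lobes — systolic at 30% of the
pulse period and dicrotic at 65% with configurable relative amplitude —
which reproduces the four pulse landmarks (foot, systolic peak,
dicrotic notch, diastolic peak) with two shape parameters. The ABP
waveform is affinely rescaled so its extrema equal the configured
SBP/DBP *exactly* when noise is off; the PPG is emitted in arbitrary
units centred near 0 and circularly shifted by the configured lag.
Optional additive Gaussian noise (scaled by each channel's pulse
amplitude), sub-0.5 Hz sinusoidal baseline wander, and beat-to-beat
heart-rate jitter emulate acquisition imperfections.

**BP-to-morphology coupling.** Per-signal normalization erases absolute
PPG amplitude, so the pressure information must live in waveform shape
for the translation task to be well-posed. The generator couples the
PPG systolic lobe width inversely to SBP (a stiffer, higher-pressure
vessel transmits a faster, narrower pulse) and the PPG dicrotic
amplitude to DBP (stronger reflection under higher diastolic tone); the
ABP shares the SBP-dependent systolic width so the channels stay
morphologically correlated (r ≥ 0.8 across the generated BP range, the
same threshold QC enforces). This makes the synthetic PPG→ABP map
deterministic and learnable — and is exactly what passing the
end-to-end tests shows: that the pipeline can recover pressure
information *that the morphology actually carries*. Real PPG encodes
pressure far more weakly and variably; synthetic recovery is a
correctness check of the machinery, not evidence of clinical accuracy.

Corruption modes map to QC failure reasons so QC tests have labelled
ground truth: `flatline` (constant PPG → no usable peak),
`dropout_burst` (45% of the PPG zeroed → morphology correlation below
0.8), `saturation` (pressure transducer railed at 195 mmHg → SBP out of
range). Datasets draw per-subject heart rate (65–85 bpm), DBP
(63–105 mmHg), SBP (DBP + 25 up to 172 mmHg) and lag (0–55 samples)
from sub-seeded generators, so subjects differ but any seed reproduces
the corpus bit-for-bit (SHA-256 dataset digests are part of the run
manifest).

## Desk-scale study conditions

End-to-end validation runs on one CPU with a deliberately small
operating point: 100 subjects × 20 segments of 300 samples (2.4 s),
mild noise (1% of pulse amplitude) and wander (5%); alignment search
window 72 samples, hence a common cropped length of 228 samples; a toy
translator with 32 hidden units, batch 64, learning rate 0.005, 15
epochs per stage without early stopping; and three model seeds with the
dataset held fixed. Under these conditions the two-stage model reaches
a median absolute SBP error of ~4–6 mmHg with r(SBP) ≈ 0.95–0.98 on
held-out subjects, and the reconstruction-pretrained encoder reaches a
validation loss at least as good as an identically initialized but
never-pretrained encoder at the same stage-2 budget. The full-size
default configuration (128 hidden units, 50 epochs, 1024-sample
segments) is exercised only for shape/contract tests.

## Known limitations

* The generator's two-lobe beats cannot represent arrhythmia, pulsus
  alternans, reflected-wave timing changes, motion artefacts beyond the
  three stylized corruption modes, or drug-driven pressure swings of
  ICU data; QC and model results on it bound only implementation
  correctness.
* The BP-to-morphology coupling is a modelling convenience with the
  right sign, not a calibrated physiological law.
* The AAMI-style verdict uses MAE by convention of this model family;
  it is not a regulatory compliance statement.
* Per-segment SBP/DBP extrema are sensitive to single-sample noise on
  the predicted waveform; no smoothing is applied before extraction.
* Training is single-threaded NumPy; it is deliberately sized for
  correctness checks, not for full-database experiments.
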