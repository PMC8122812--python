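# pulse2abp

Continuous, cuff-less blood pressure estimation by **signal-to-signal
translation**: a raw photoplethysmogram (PPG) — together with its first
and second derivatives (dPPG, sdPPG) — is mapped to a continuous
arterial blood pressure (ABP) waveform by a two-stage LSTM autoencoder,
and systolic/diastolic pressures are extracted from the translated
waveform as

```
SBP = max(ABP),   DBP = min(ABP)        (per segment, in mmHg)
```

The package is aimed at researchers working with paired PPG/ABP
recordings (e.g. ICU monitor exports at 125 Hz) who want a reproducible,
auditable implementation of the whole chain:

1. **Preprocessing** — 3rd-order Butterworth bandpass 0.5–8 Hz
   (zero-phase) on the PPG; per-signal z-scoring `x′ = (x − μ)/σ` with
   train-averaged parameters applied at test time; cross-correlation
   alignment `Δt = argmax Σₜ ABP[t]·PPG[t+Δt]` of the lagging PPG;
   central-difference derivative channels.
2. **Quality control** — segments are eliminated when SBP ∉ [80, 180]
   mmHg, DBP ∉ [60, 130] mmHg, PPG/ABP morphology correlation r < 0.8,
   or no usable systolic peak is found (adaptive moving-average
   detector); every rule is reported per segment.
3. **Two-stage transfer learning** — the autoencoder (2 LSTM layers per
   phase, 128 hidden units, dropout 0.2 at the end of decoding, Adam,
   lr 0.0025, ≤50 epochs, subject-level 70/10/20 split) first learns
   PPG→PPG reconstruction; the encoder is then frozen (bit-exact,
   digest-verified) and the decoder retrained for PPG→ABP translation.
4. **Evaluation** — MAE = (1/N)Σ|eᵢ| and RMSE = √((1/N)Σeᵢ²) of the
   SBP/DBP errors, BHS cumulative-error grading (A: 60/85/95% within
   5/10/15 mmHg) and the AAMI-style criterion (MAE < 5, STD < 8 mmHg,
   > 85 subjects), plus predicted-vs-observed Pearson correlations.

A **synthetic paired-waveform generator** (two Gaussian lobes per beat:
systolic + dicrotic; exact SBP/DBP by construction; controllable lag,
noise, wander, and labelled corruption modes) stands in for the external
waveform database, so the entire pipeline is testable offline. The
recurrent network, backpropagation through time, and Adam are
implemented directly in NumPy and are finite-difference-verified in the
test suite.

## Worked example

```python
from pulse2abp.config import validate_config
from pulse2abp.pipeline import run_pipeline

config = validate_config({
    "seed": 11,
    "synth": {"n_subjects": 100, "segments_per_subject": 20,
              "segment_len": 300, "noise_sd": 0.01,
              "baseline_wander_amp": 0.05},
    "model": {"hidden_units": 32, "max_epochs": 15, "batch_size": 64,
              "learning_rate": 0.005, "patience": 0},
})
result = run_pipeline(config)
ev = result.evaluation
print(f"SBP MAE {ev.sbp_mae:.2f} mmHg, r {ev.r_sbp:.3f}, "
      f"BHS {ev.bhs_sbp.grade}")
print(f"DBP MAE {ev.dbp_mae:.2f} mmHg, r {ev.r_dbp:.3f}, "
      f"BHS {ev.bhs_dbp.grade}")
```

prints (about two minutes on one CPU):

```
SBP MAE 6.69 mmHg, r 0.950, BHS C
DBP MAE 5.02 mmHg, r 0.762, BHS B
```

i.e. on held-out synthetic subjects the translated waveforms recover
systolic pressure to ~6–7 mmHg mean absolute error with correlation
0.95 against ground truth, from morphology alone, after per-signal
amplitude normalization has removed all scale information (the toy
32-unit model reaches BHS grade C/B at this desk scale; the grades are
a function of training scale, not of the pipeline logic, which the
worked BHS examples in the tests pin down exactly). The run
manifest (`result.manifest`) records the QC elimination funnel per
reason, dataset and model SHA-256 digests, and the full configuration,
so the run is reproducible bit-for-bit from the manifest.

The same pipeline is available from the shell:

```bash
pulse2abp synth --n-subjects 10 --segments-per-subject 5 --seed 1 --out data/
pulse2abp qc --in data/ --out qc_report.csv
pulse2abp train --data data/ --checkpoint model.npz
pulse2abp translate --model model.npz --in data/ --out pred/
pulse2abp evaluate --pred pred/ --out report.json
pulse2abp run-all --seed 1 --out run/          # everything end to end
```

The sklearn-style estimator wraps the two training stages behind the
usual interface, and composes with scikit-learn tooling:

```python
from pulse2abp.translator import PpgToAbpTranslator
est = PpgToAbpTranslator(hidden_units=32, max_epochs=15, seed=0)
est.fit(X, y)          # X: (n, T, 3) feature stacks, y: (n, T) ABP in mmHg
abp_pred = est.predict(X_test)   # mmHg waveforms
```

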