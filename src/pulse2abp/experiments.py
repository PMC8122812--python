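"""Desk-scale end-to-end experiments: synthetic recovery and transfer benefit.

These are the study conditions used for the package's own validation:
a 100-subject × 20-segment synthetic corpus (2.4 s segments at 125 Hz,
mild noise and baseline wander), a toy translator (32 hidden units,
15 epochs, batch 64), and a paired comparison of the transferred
(reconstruction-pretrained, frozen) encoder against an identically
initialized encoder that never saw stage 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulse2abp.config import PipelineConfig, validate_config
from pulse2abp.evaluate import EvaluationReport, evaluate_run
from pulse2abp.pipeline import PipelineData, prepare_pipeline_data
from pulse2abp.preprocess import apply_norm
from pulse2abp.translator import (
    ModelConfig,
    build_model,
    freeze_encoder,
    train_reconstruction,
    train_translation,
    translate,
)


def toy_study_config(seed: int = 11) -> PipelineConfig:
    """The desk-scale study conditions (data side)."""
    return validate_config(
        {
            "seed": seed,
            "synth": {
                "n_subjects": 100,
                "segments_per_subject": 20,
                "segment_len": 300,
                "noise_sd": 0.01,
                "baseline_wander_amp": 0.05,
            },
            "model": {
                "hidden_units": 32,
                "max_epochs": 15,
                "batch_size": 64,
                "learning_rate": 0.005,
                "patience": 0,
            },
        }
    )


@dataclass
class SeedOutcome:
    model_seed: int
    evaluation: EvaluationReport
    median_abs_sbp_error: float
    median_abs_dbp_error: float
    transferred_val_loss: float
    baseline_val_loss: float
    encoder_digest_before: str
    encoder_digest_after: str


@dataclass
class TransferStudyResult:
    outcomes: list[SeedOutcome] = field(default_factory=list)

    def median_over_seeds(self, attr: str) -> float:
        return float(np.median([getattr(o, attr) for o in self.outcomes]))

    @property
    def median_sbp_error(self) -> float:
        return self.median_over_seeds("median_abs_sbp_error")

    @property
    def median_r_sbp(self) -> float:
        return float(np.median([o.evaluation.r_sbp for o in self.outcomes]))

    @property
    def median_transfer_gain(self) -> float:
        """Median (baseline − transferred) final validation loss; positive
        means the pretrained encoder helped."""
        return float(
            np.median(
                [o.baseline_val_loss - o.transferred_val_loss for o in self.outcomes]
            )
        )


def run_seed(
    data: PipelineData, config: PipelineConfig, model_seed: int
) -> SeedOutcome:
    """Two-stage training plus the random-encoder baseline for one seed."""
    m = config.model
    mcfg = ModelConfig(
        encoder_layers=m.encoder_layers,
        decoder_layers=m.decoder_layers,
        hidden_units=m.hidden_units,
        dropout_rate=m.dropout_rate,
        learning_rate=m.learning_rate,
        max_epochs=m.max_epochs,
        batch_size=m.batch_size,
        patience=m.patience,
        seed=model_seed,
    )
    y_train = apply_norm(data.train.abp, data.abp_norm)
    y_val = apply_norm(data.val.abp, data.abp_norm)

    model = build_model(mcfg)
    train_reconstruction(model, data.train.stacks, data.val.stacks, mcfg)
    freeze_encoder(model)
    digest_before = model.encoder_digest()
    trans = train_translation(
        model, data.train.stacks, y_train, data.val.stacks, y_val, mcfg
    )
    digest_after = model.encoder_digest()

    # baseline: identical initialization, encoder never pretrained
    baseline = freeze_encoder(build_model(mcfg))
    base_report = train_translation(
        baseline, data.train.stacks, y_train, data.val.stacks, y_val, mcfg
    )

    predicted_waves = translate(model, data.test.stacks, data.abp_norm)
    predicted = dict(zip(data.test.segment_ids, predicted_waves))
    observed = dict(zip(data.test.segment_ids, data.test.abp))
    evaluation = evaluate_run(
        predicted, observed, n_subjects=len(set(data.test.subject_ids))
    )
    return SeedOutcome(
        model_seed=model_seed,
        evaluation=evaluation,
        median_abs_sbp_error=float(
            np.median(np.abs(evaluation.errors.sbp_errors))
        ),
        median_abs_dbp_error=float(
            np.median(np.abs(evaluation.errors.dbp_errors))
        ),
        transferred_val_loss=trans.val_losses[-1],
        baseline_val_loss=base_report.val_losses[-1],
        encoder_digest_before=digest_before,
        encoder_digest_after=digest_after,
    )


def transfer_study(
    config: PipelineConfig | None = None,
    model_seeds: tuple[int, ...] = (101, 102, 103),
    data: PipelineData | None = None,
) -> TransferStudyResult:
    """Run the synthetic-recovery/transfer-benefit study over model seeds."""
    config = config or toy_study_config()
    if data is None:
        data = prepare_pipeline_data(config)
    result = TransferStudyResult()
    for seed in model_seeds:
        result.outcomes.append(run_seed(data, config, seed))
    return result
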