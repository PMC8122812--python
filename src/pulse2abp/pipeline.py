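"""End-to-end orchestration: generate → preprocess → QC → train → evaluate.

Stages mirror the training flow of the two-stage translator: synthetic
(or ingested) paired segments are filtered, normalized, aligned and
stacked; the QC rules eliminate unusable segments (counted per reason);
the autoencoder is trained to reconstruct PPG, its encoder frozen, the
decoder retrained against pressure targets; finally the translated test
segments are evaluated against the observed pressure waveforms.

Subject-level 70/10/20 splitting prevents any subject's segments from
appearing in more than one partition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from pulse2abp import synth
from pulse2abp.config import PipelineConfig
from pulse2abp.evaluate import EvaluationReport, evaluate_run
from pulse2abp.preprocess import (
    GlobalNormParams,
    NormParams,
    aligned_pair,
    apply_norm,
    bandpass_filter,
    fit_global_norm,
    make_feature_stack,
    zscore,
)
from pulse2abp.qc import QCReport, QCThresholds, qc_filter
from pulse2abp.synth import PairedSegment, SynthConfig
from pulse2abp.translator import (
    ModelConfig,
    TrainReport,
    TranslatorModel,
    build_model,
    freeze_encoder,
    train_reconstruction,
    train_translation,
    translate,
)

log = logging.getLogger("pulse2abp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PreparedSet:
    """Aligned, QC-passed, model-ready arrays for one partition."""

    segment_ids: list[str]
    subject_ids: list[str]
    stacks: np.ndarray  # (n, T, 3) normalized PPG feature stacks
    abp: np.ndarray  # (n, T) raw ABP in mmHg
    ppg_params: list[NormParams]
    qc_reports: list[QCReport]
    n_rejected: int


@dataclass
class RunResult:
    config: PipelineConfig
    manifest: dict
    evaluation: EvaluationReport
    recon_report: TrainReport
    trans_report: TrainReport
    model: TranslatorModel
    ppg_norm: GlobalNormParams
    abp_norm: GlobalNormParams


def subject_split(
    segments: list[PairedSegment], fractions: tuple[float, float, float], seed: int
) -> tuple[list[PairedSegment], list[PairedSegment], list[PairedSegment]]:
    """Disjoint train/val/test partition at the subject level."""
    subjects = sorted({s.subject_id for s in segments})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n = len(subjects)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    groups = (
        {subjects[i] for i in order[:n_train]},
        {subjects[i] for i in order[n_train : n_train + n_val]},
        {subjects[i] for i in order[n_train + n_val :]},
    )
    return tuple([s for s in segments if s.subject_id in g] for g in groups)


def funnel_counts(reports: list[QCReport]) -> dict:
    counts = {"sbp_range": 0, "dbp_range": 0, "low_correlation": 0, "no_peak": 0}
    for rep in reports:
        for reason in rep.failure_reasons:
            counts[reason] += 1
    counts["passed"] = sum(r.passed for r in reports)
    counts["total"] = len(reports)
    return counts


def prepare_set(
    segments: list[PairedSegment],
    config: PipelineConfig,
    ppg_norm: GlobalNormParams | None = None,
) -> PreparedSet:
    """Filter, normalize, align, QC-screen and stack one partition.

    Training partitions pass ``ppg_norm=None`` (per-signal z-scoring);
    held-out partitions supply the training-set global parameters.
    Aligned pairs are cropped to the common length
    ``segment_len − max_lag`` so all stacks batch together.
    """
    pp = config.preprocess
    th = QCThresholds(
        sbp_max=config.qc.sbp_max,
        sbp_min=config.qc.sbp_min,
        dbp_max=config.qc.dbp_max,
        dbp_min=config.qc.dbp_min,
        min_r=config.qc.min_r,
    )
    common_len = config.synth.segment_len - pp.max_lag
    ids, subjects, stacks, abps, params, reports = [], [], [], [], [], []
    n_rejected = 0
    for seg in segments:
        try:
            filtered = bandpass_filter(
                seg.ppg, fs=seg.sampling_rate_hz, low=pp.low_hz, high=pp.high_hz,
                order=pp.order,
            )
            if ppg_norm is None:
                normalized, p = zscore(filtered)
            else:
                normalized = apply_norm(filtered, ppg_norm)
                p = NormParams(mu=ppg_norm.mu_bar, sigma=ppg_norm.sigma_bar)
            ppg_al, abp_al, _ = aligned_pair(normalized, seg.abp, pp.max_lag)
        except ValueError:
            # constant or zero-energy signals cannot be normalized or
            # aligned; they are QC eliminations (no usable peak)
            reports.append(
                QCReport(
                    segment_id=seg.segment_id,
                    sbp_mmHg=float(np.max(seg.abp)),
                    dbp_mmHg=float(np.min(seg.abp)),
                    pearson_r=float("nan"),
                    peaks_found=0,
                    passed=False,
                    failure_reasons=["no_peak"],
                )
            )
            n_rejected += 1
            continue
        # QC sees the full aligned pair; cropping to the common batch
        # length happens only after elimination
        report = qc_filter(
            seg.segment_id, ppg_al, abp_al,
            fs=seg.sampling_rate_hz, thresholds=th,
        )
        reports.append(report)
        if not report.passed:
            n_rejected += 1
            continue
        stack = make_feature_stack(
            ppg_al[:common_len], h=1.0 / seg.sampling_rate_hz
        )
        ids.append(seg.segment_id)
        subjects.append(seg.subject_id)
        stacks.append(stack.as_input())
        abps.append(abp_al[:common_len])
        params.append(p)
    return PreparedSet(
        segment_ids=ids,
        subject_ids=subjects,
        stacks=np.array(stacks) if stacks else np.empty((0, common_len, 3)),
        abp=np.array(abps) if abps else np.empty((0, common_len)),
        ppg_params=params,
        qc_reports=reports,
        n_rejected=n_rejected,
    )


def _model_config(config: PipelineConfig) -> ModelConfig:
    m = config.model
    return ModelConfig(
        encoder_layers=m.encoder_layers,
        decoder_layers=m.decoder_layers,
        hidden_units=m.hidden_units,
        dropout_rate=m.dropout_rate,
        learning_rate=m.learning_rate,
        max_epochs=m.max_epochs,
        batch_size=m.batch_size,
        patience=m.patience,
        seed=config.seed,
    )


@dataclass
class PipelineData:
    """Prepared train/val/test partitions plus fitted normalizations."""

    train: PreparedSet
    val: PreparedSet
    test: PreparedSet
    ppg_norm: GlobalNormParams
    abp_norm: GlobalNormParams
    manifest: dict


def prepare_pipeline_data(config: PipelineConfig) -> PipelineData:
    """Generate, split, preprocess and QC-screen a synthetic dataset."""
    base = SynthConfig(
        segment_len=config.synth.segment_len,
        heart_rate_bpm=config.synth.heart_rate_bpm,
        hr_jitter=config.synth.hr_jitter,
        noise_sd=config.synth.noise_sd,
        baseline_wander_amp=config.synth.baseline_wander_amp,
        seed=config.seed,
    )
    segments = synth.generate_dataset(
        base,
        n_subjects=config.synth.n_subjects,
        segments_per_subject=config.synth.segments_per_subject,
        corrupt_frac=config.synth.corrupt_frac,
    )
    manifest: dict = {
        "synth": {
            "n_segments": len(segments),
            "dataset_digest": synth.dataset_digest(segments),
        }
    }
    train_segs, val_segs, test_segs = subject_split(
        segments,
        (config.split.train, config.split.val, config.split.test),
        config.seed + 1,
    )
    train_set = prepare_set(train_segs, config, ppg_norm=None)
    if train_set.stacks.shape[0] == 0:
        raise PipelineError("empty training set after quality control")
    ppg_norm = fit_global_norm(train_set.ppg_params)
    val_set = prepare_set(val_segs, config, ppg_norm=ppg_norm)
    test_set = prepare_set(test_segs, config, ppg_norm=ppg_norm)
    for name, ps in (("train", train_set), ("val", val_set), ("test", test_set)):
        manifest[f"qc_{name}"] = funnel_counts(ps.qc_reports)
    abp_norm = fit_global_norm([zscore(a)[1] for a in train_set.abp])
    manifest["normalization"] = {
        "ppg_mu_bar": ppg_norm.mu_bar,
        "ppg_sigma_bar": ppg_norm.sigma_bar,
        "abp_mu_bar": abp_norm.mu_bar,
        "abp_sigma_bar": abp_norm.sigma_bar,
    }
    return PipelineData(
        train=train_set,
        val=val_set,
        test=test_set,
        ppg_norm=ppg_norm,
        abp_norm=abp_norm,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig, outdir: Path | None = None) -> RunResult:
    """Execute the full pipeline on a synthetic dataset.

    Returns the evaluation of the translated test partition plus a
    manifest (config echo, per-stage counts, digests) sufficient to
    reproduce the run.  Any stage failure raises `PipelineError` naming
    the stage; the partial manifest is persisted when ``outdir`` is set.
    """
    manifest: dict = {"config": config.model_dump(), "stages": {}}
    t_start = time.time()

    def persist() -> None:
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        persist()
        return PipelineError(f"pipeline stage {stage!r} failed: {exc}")

    # -- synth + split + preprocess + qc ---------------------------------
    try:
        data = prepare_pipeline_data(config)
    except PipelineError as exc:
        raise fail("qc", exc) from exc
    except Exception as exc:
        raise fail("preprocess", exc) from exc
    manifest["stages"].update(data.manifest)
    train_set, val_set, test_set = data.train, data.val, data.test
    ppg_norm, abp_norm = data.ppg_norm, data.abp_norm
    for name in ("synth", "qc_train", "qc_val", "qc_test"):
        log.info("%s: %s", name, manifest["stages"][name])

    # -- train -----------------------------------------------------------
    try:
        mcfg = _model_config(config)
        model = build_model(mcfg)
        recon = train_reconstruction(
            model, train_set.stacks, val_set.stacks if len(val_set.stacks) else None,
            mcfg,
        )
        freeze_encoder(model)
        y_train = apply_norm(train_set.abp, abp_norm)
        y_val = apply_norm(val_set.abp, abp_norm) if len(val_set.abp) else None
        trans = train_translation(
            model, train_set.stacks, y_train,
            val_set.stacks if len(val_set.stacks) else None, y_val, mcfg,
        )
    except Exception as exc:
        raise fail("train", exc) from exc
    manifest["stages"]["train"] = {
        "recon_best_epoch": recon.best_epoch,
        "recon_final_val": recon.val_losses[-1] if recon.val_losses else None,
        "trans_best_epoch": trans.best_epoch,
        "trans_final_val": trans.val_losses[-1] if trans.val_losses else None,
        "encoder_digest": model.encoder_digest(),
        "model_digest": model.digest(),
    }

    # -- translate + evaluate -------------------------------------------
    try:
        if test_set.stacks.shape[0] == 0:
            raise PipelineError("empty test set after quality control")
        predicted_waves = translate(model, test_set.stacks, abp_norm)
        predicted = dict(zip(test_set.segment_ids, predicted_waves))
        observed = dict(zip(test_set.segment_ids, test_set.abp))
        n_subjects = len(set(test_set.subject_ids))
        evaluation = evaluate_run(predicted, observed, n_subjects)
    except PipelineError as exc:
        raise fail("evaluate", exc) from exc
    except Exception as exc:
        raise fail("evaluate", exc) from exc
    manifest["stages"]["evaluate"] = {
        "n_test_segments": len(test_set.segment_ids),
        "n_test_subjects": n_subjects,
        "sbp_mae": evaluation.sbp_mae,
        "dbp_mae": evaluation.dbp_mae,
        "sbp_rmse": evaluation.sbp_rmse,
        "dbp_rmse": evaluation.dbp_rmse,
        "bhs_sbp": dataclasses.asdict(evaluation.bhs_sbp),
        "bhs_dbp": dataclasses.asdict(evaluation.bhs_dbp),
        "aami_sbp_pass": evaluation.aami_sbp.passed,
        "aami_dbp_pass": evaluation.aami_dbp.passed,
        "r_sbp": evaluation.r_sbp,
        "r_dbp": evaluation.r_dbp,
    }
    manifest["elapsed_s"] = time.time() - t_start
    persist()
    return RunResult(
        config=config,
        manifest=manifest,
        evaluation=evaluation,
        recon_report=recon,
        trans_report=trans,
        model=model,
        ppg_norm=ppg_norm,
        abp_norm=abp_norm,
    )
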