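"""Evaluation of predicted pressure waveforms: error metrics, BHS and AAMI.

The unit of error is the per-segment systolic/diastolic value: SBP and
DBP are extracted as the maximum/minimum of each predicted and observed
ABP segment, and the signed error is prediction minus observation, in
mmHg.

BHS grading scores the cumulative percentage of absolute errors within
5/10/15 mmHg against the grade rows (A: 60/85/95, B: 50/75/90,
C: 40/65/85; all three thresholds of a row must be met).  The AAMI-style
check follows the convention used for this model family — mean absolute
error below 5 mmHg and error standard deviation below 8 mmHg on more
than 85 subjects — rather than the mean signed error of the formal
standard; boundary comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulse2abp.qc import extract_dbp, extract_sbp, pearson_r

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)
BHS_GRADE_ROWS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
AAMI_MAX_MAE = 5.0
AAMI_MAX_STD = 8.0
AAMI_MIN_SUBJECTS = 85


@dataclass
class ErrorSet:
    """Per-segment signed errors (predicted − observed), in mmHg."""

    sbp_errors: np.ndarray
    dbp_errors: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.sbp_errors = np.asarray(self.sbp_errors, dtype=np.float64)
        self.dbp_errors = np.asarray(self.dbp_errors, dtype=np.float64)
        for e in (self.sbp_errors, self.dbp_errors):
            if e.size == 0:
                raise ValueError("error set must be non-empty")
            if not np.all(np.isfinite(e)):
                raise ValueError("errors must be finite")


@dataclass
class BHSResult:
    pct_le_5: float
    pct_le_10: float
    pct_le_15: float
    grade: str  # "A" | "B" | "C" | "fail"


@dataclass
class AAMIResult:
    mae: float
    std: float
    n_subjects: int
    passed: bool


@dataclass
class EvaluationReport:
    errors: ErrorSet
    sbp_mae: float
    sbp_rmse: float
    sbp_std: float
    dbp_mae: float
    dbp_rmse: float
    dbp_std: float
    bhs_sbp: BHSResult
    bhs_dbp: BHSResult
    aami_sbp: AAMIResult
    aami_dbp: AAMIResult
    r_sbp: float
    r_dbp: float
    abs_error_hist: dict = field(default_factory=dict)


def mae(errors: np.ndarray) -> float:
    """Mean absolute error in mmHg."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        raise ValueError("mae of an empty error set is undefined")
    return float(np.mean(np.abs(errors)))


def rmse(errors: np.ndarray) -> float:
    """Root mean square error in mmHg."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        raise ValueError("rmse of an empty error set is undefined")
    return float(np.sqrt(np.mean(errors**2)))


def error_std(errors: np.ndarray) -> float:
    """Population standard deviation of the signed errors."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        raise ValueError("std of an empty error set is undefined")
    return float(np.std(errors, ddof=0))


def bhs_grade(abs_errors: np.ndarray) -> BHSResult:
    """Cumulative-percentage BHS grading of absolute errors.

    An error exactly on a threshold counts as within it (|e| <= 5 etc.);
    a grade is awarded only if all three of its cumulative percentages
    are met (>=).
    """
    abs_errors = np.abs(np.asarray(abs_errors, dtype=np.float64))
    if abs_errors.size == 0:
        raise ValueError("cannot grade an empty error set")
    pcts = tuple(
        float(100.0 * int(np.count_nonzero(abs_errors <= thr)) / abs_errors.size)
        for thr in BHS_THRESHOLDS_MMHG
    )
    grade = "fail"
    for g, row in BHS_GRADE_ROWS.items():
        if all(p >= req for p, req in zip(pcts, row)):
            grade = g
            break
    return BHSResult(pct_le_5=pcts[0], pct_le_10=pcts[1], pct_le_15=pcts[2],
                     grade=grade)


def aami_check(errors: np.ndarray, n_subjects: int) -> AAMIResult:
    """AAMI-style verdict: MAE < 5 mmHg, error SD < 8 mmHg, > 85 subjects."""
    m = mae(errors)
    s = error_std(errors)
    passed = (m < AAMI_MAX_MAE) and (s < AAMI_MAX_STD) and (n_subjects > AAMI_MIN_SUBJECTS)
    return AAMIResult(mae=m, std=s, n_subjects=n_subjects, passed=passed)


def bp_correlation(
    predicted_sbp: np.ndarray,
    observed_sbp: np.ndarray,
    predicted_dbp: np.ndarray,
    observed_dbp: np.ndarray,
) -> tuple[float, float]:
    """Pearson r between predicted and observed SBP, and likewise DBP."""
    return (
        pearson_r(np.asarray(predicted_sbp), np.asarray(observed_sbp)),
        pearson_r(np.asarray(predicted_dbp), np.asarray(observed_dbp)),
    )


def _hist_summary(abs_errors: np.ndarray) -> dict:
    edges = [0.0, 5.0, 10.0, 15.0, np.inf]
    counts, _ = np.histogram(abs_errors, bins=edges)
    return {
        "le_5": int(counts[0]),
        "5_to_10": int(counts[1]),
        "10_to_15": int(counts[2]),
        "gt_15": int(counts[3]),
    }


def evaluate_run(
    predicted: dict[str, np.ndarray],
    observed: dict[str, np.ndarray],
    n_subjects: int,
) -> EvaluationReport:
    """Full evaluation of matched predicted/observed ABP segments.

    ``predicted`` and ``observed`` map segment ids to ABP waveforms in
    mmHg; the id sets must match exactly.  SBP/DBP are extracted per
    segment (max/min), errors assembled, and MAE/RMSE/STD, BHS grades,
    AAMI verdicts, correlations and an absolute-error histogram
    computed.
    """
    pred_ids = set(predicted)
    obs_ids = set(observed)
    if pred_ids != obs_ids:
        missing = sorted(pred_ids ^ obs_ids)[:5]
        raise ValueError(
            f"predicted and observed segment ids do not match (e.g. {missing})"
        )
    ids = sorted(pred_ids)
    sbp_p = np.array([extract_sbp(predicted[i]) for i in ids])
    sbp_o = np.array([extract_sbp(observed[i]) for i in ids])
    dbp_p = np.array([extract_dbp(predicted[i]) for i in ids])
    dbp_o = np.array([extract_dbp(observed[i]) for i in ids])
    errors = ErrorSet(
        sbp_errors=sbp_p - sbp_o, dbp_errors=dbp_p - dbp_o, n_subjects=n_subjects
    )
    def _safe_r(p: np.ndarray, o: np.ndarray) -> float:
        # a constant value list (e.g. perfect prediction of one subject)
        # has no defined correlation; report 1 for exact agreement
        if np.ptp(p) < 1e-12 or np.ptp(o) < 1e-12:
            return 1.0 if np.allclose(p, o) else float("nan")
        return pearson_r(p, o)

    r_sbp = _safe_r(sbp_p, sbp_o)
    r_dbp = _safe_r(dbp_p, dbp_o)
    return EvaluationReport(
        errors=errors,
        sbp_mae=mae(errors.sbp_errors),
        sbp_rmse=rmse(errors.sbp_errors),
        sbp_std=error_std(errors.sbp_errors),
        dbp_mae=mae(errors.dbp_errors),
        dbp_rmse=rmse(errors.dbp_errors),
        dbp_std=error_std(errors.dbp_errors),
        bhs_sbp=bhs_grade(errors.sbp_errors),
        bhs_dbp=bhs_grade(errors.dbp_errors),
        aami_sbp=aami_check(errors.sbp_errors, n_subjects),
        aami_dbp=aami_check(errors.dbp_errors, n_subjects),
        r_sbp=r_sbp,
        r_dbp=r_dbp,
        abs_error_hist={
            "sbp": _hist_summary(np.abs(errors.sbp_errors)),
            "dbp": _hist_summary(np.abs(errors.dbp_errors)),
        },
    )
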