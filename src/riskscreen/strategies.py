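"""Screening-allocation strategies.

Three deterministic threshold rules turn a risk matrix into a schedule:

* CA   (cumulative): a patient whose summed 5-year risk reaches the
  threshold is screened every year; everyone else not at all.
* CAIR (cumulative with interval-wise reevaluation): risks are accumulated
  year by year; when the running sum reaches the threshold an exam is
  scheduled at the end of that year and the accumulator resets.
* ISA  (interval-specific): an exam after every year whose own annual risk
  reaches the threshold.

Threshold comparisons are inclusive (>=), so threshold 0 is the full
schedule for every rule.

RA (random allocation) is the efficiency reference: patient-year slots are
drawn uniformly at random, one at a time, until the achieved detection
rate reaches the target.  In ``with_replacement`` mode (default) a
repeated slot consumes a draw without adding an exam — the draw count then
measures the examinations an uninformed allocator would waste, and can
exceed the slot budget; in ``without_replacement`` mode draws equal the
distinct exams.  The stopped schedule itself (and hence any saving
computed from its examination count) has the same distribution in both
modes.

A scikit-learn style wrapper (`ThresholdScreeningPolicy`,
`RandomScreeningPolicy`) is provided at the bottom so policies compose
with sklearn pipelines and model selection; the functions above are the
engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InfeasibleTargetError, InvalidParameterError
from .progression import (
    ScreeningSchedule,
    expected_detections,
    max_detections,
)

STRATEGY_NAMES = ("CA", "CAIR", "ISA", "RA", "FULL")
RA_MODES = ("with_replacement", "without_replacement")


@dataclass(frozen=True)
class StrategySpec:
    name: str
    threshold: float | None = None
    ra_mode: str = "with_replacement"

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise InvalidParameterError(f"unknown strategy {self.name!r}")
        if self.threshold is not None and self.threshold < 0:
            raise InvalidParameterError("threshold must be >= 0")
        if self.ra_mode not in RA_MODES:
            raise InvalidParameterError(f"ra_mode must be one of {RA_MODES}")


def _risks_array(risks) -> np.ndarray:
    arr = getattr(risks, "risks", risks)
    return np.asarray(arr, dtype=float)


def _ca_mask(risks: np.ndarray, threshold: float) -> np.ndarray:
    keep = risks.sum(axis=1) >= threshold
    return np.repeat(keep[:, None], risks.shape[1], axis=1)


def _cair_mask(risks: np.ndarray, threshold: float) -> np.ndarray:
    N, n = risks.shape
    out = np.zeros((N, n), dtype=bool)
    running = np.zeros(N)
    for i in range(n):
        running += risks[:, i]
        hit = running >= threshold
        out[:, i] = hit
        running[hit] = 0.0
    return out


def _isa_mask(risks: np.ndarray, threshold: float) -> np.ndarray:
    return risks >= threshold


_RULES = {"CA": _ca_mask, "CAIR": _cair_mask, "ISA": _isa_mask}


def schedule_ca(risks, threshold: float) -> ScreeningSchedule:
    """All-or-nothing screening on the cumulative (5-year) risk."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    return ScreeningSchedule(_ca_mask(_risks_array(risks), threshold))


def schedule_cair(risks, threshold: float) -> ScreeningSchedule:
    """Accumulate annual risks; exam and reset whenever the sum reaches the threshold."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    return ScreeningSchedule(_cair_mask(_risks_array(risks), threshold))


def schedule_isa(risks, threshold: float) -> ScreeningSchedule:
    """Exam after every year whose own annual risk reaches the threshold."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    return ScreeningSchedule(_isa_mask(_risks_array(risks), threshold))


@dataclass(frozen=True)
class RandomAllocationResult:
    schedule: ScreeningSchedule
    draws: int
    exams: int
    tdr_achieved: float


def schedule_ra(
    risks,
    dp: float,
    tdr_target: float,
    ra_mode: str = "with_replacement",
    sensitivity: float = 1.0,
    rng: np.random.Generator | None = None,
    mode: str = "cascade",
) -> RandomAllocationResult:
    """Uniform random slot allocation, stopped at the first draw reaching tdr.

    The stop index is located by bisecting over the prefix length of the
    draw sequence; since adding an exam never decreases the expected
    detections, the first prefix reaching the target is exactly where a
    sequential one-at-a-time allocator would stop.
    """
    arr = _risks_array(risks)
    N, n = arr.shape
    M = N * n
    if rng is None:
        rng = np.random.default_rng()
    if ra_mode not in RA_MODES:
        raise InvalidParameterError(f"ra_mode must be one of {RA_MODES}")
    if not (0.0 < tdr_target <= 1.0):
        raise InvalidParameterError(f"tdr_target must be in (0, 1], got {tdr_target}")

    n_max = max_detections(arr, dp, sensitivity, mode)
    target = tdr_target * n_max

    flat = np.zeros(M, dtype=bool)

    def n_actual_at(seq_prefix: np.ndarray) -> float:
        flat[:] = False
        flat[seq_prefix] = True
        return expected_detections(arr, flat.reshape(N, n), dp, sensitivity, mode)

    if ra_mode == "without_replacement":
        seq = rng.permutation(M)
    else:
        seq = rng.integers(0, M, size=2 * M)
        # extend until the whole sequence reaches the target (or covers all slots)
        while n_actual_at(seq) < target:
            if np.unique(seq).size == M:
                raise InfeasibleTargetError(
                    f"tdr target {tdr_target} unreachable even at full coverage"
                )
            seq = np.concatenate([seq, rng.integers(0, M, size=M)])
    if n_actual_at(seq) < target - 1e-12:
        raise InfeasibleTargetError(
            f"tdr target {tdr_target} unreachable even at full coverage"
        )

    lo, hi = 0, len(seq)  # n_actual_at(hi) >= target, n_actual_at(0) = 0 < target
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if n_actual_at(seq[:mid]) >= target:
            hi = mid
        else:
            lo = mid

    prefix = seq[:hi]
    flat[:] = False
    flat[prefix] = True
    schedule = ScreeningSchedule(flat.reshape(N, n).copy())
    n_act = expected_detections(arr, schedule.screened, dp, sensitivity, mode)
    return RandomAllocationResult(
        schedule=schedule,
        draws=int(hi),
        exams=int(flat.sum()),
        tdr_achieved=n_act / n_max if n_max > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# scikit-learn style policy estimators


class ThresholdScreeningPolicy(BaseEstimator, TransformerMixin):
    """Threshold screening rule calibrated to a target detection rate.

    ``fit`` bisects the rule's threshold on the training risk matrix so the
    achieved detection rate brackets ``tdr_target`` (see
    :func:`riskscreen.calibration.calibrate_threshold`); ``transform`` maps a
    risk matrix to the 0/1 examination schedule at the calibrated threshold.

    Parameters
    ----------
    rule : {"CA", "CAIR", "ISA"}
    tdr_target : fraction of the full-screening curable detections to retain
    dp : curability decay base
    sensitivity : examination sensitivity (1 = perfect)
    sensitivity_mode : {"cascade", "flat"}
    tol : bisection bracket width in risk units

    Attributes
    ----------
    threshold_ : calibrated threshold (lower bracket, tdr >= target)
    exams_at_target_ : interpolated exam count at exactly tdr_target
    calibration_ : the full CalibratedResult
    """

    def __init__(
        self,
        rule: str = "CAIR",
        tdr_target: float = 0.90,
        dp: float = 0.3,
        sensitivity: float = 1.0,
        sensitivity_mode: str = "cascade",
        tol: float = 1e-8,
    ):
        self.rule = rule
        self.tdr_target = tdr_target
        self.dp = dp
        self.sensitivity = sensitivity
        self.sensitivity_mode = sensitivity_mode
        self.tol = tol

    def fit(self, X, y=None):
        from .calibration import calibrate_threshold

        arr = _risks_array(X)
        if arr.ndim != 2:
            raise InvalidParameterError("X must be 2-D (patients x intervals)")
        res = calibrate_threshold(
            self.rule,
            arr,
            dp=self.dp,
            tdr_target=self.tdr_target,
            sensitivity=self.sensitivity,
            tol=self.tol,
            mode=self.sensitivity_mode,
        )
        self.n_features_in_ = arr.shape[1]
        self.calibration_ = res
        self.threshold_ = res.threshold_lo
        self.exams_at_target_ = res.exams_at_target
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        arr = _risks_array(X)
        return _RULES[self.rule](arr, self.threshold_).astype(int)


class RandomScreeningPolicy(BaseEstimator, TransformerMixin):
    """Uninformed random allocation reference, stopped at the target tdr."""

    def __init__(
        self,
        tdr_target: float = 0.90,
        dp: float = 0.3,
        sensitivity: float = 1.0,
        sensitivity_mode: str = "cascade",
        ra_mode: str = "with_replacement",
        random_state: int | None = None,
    ):
        self.tdr_target = tdr_target
        self.dp = dp
        self.sensitivity = sensitivity
        self.sensitivity_mode = sensitivity_mode
        self.ra_mode = ra_mode
        self.random_state = random_state

    def fit(self, X, y=None):
        arr = _risks_array(X)
        res = schedule_ra(
            arr,
            dp=self.dp,
            tdr_target=self.tdr_target,
            ra_mode=self.ra_mode,
            sensitivity=self.sensitivity,
            rng=np.random.default_rng(self.random_state),
            mode=self.sensitivity_mode,
        )
        self.n_features_in_ = arr.shape[1]
        self.result_ = res
        self.draws_ = res.draws
        self.exams_ = res.exams
        self.schedule_ = res.schedule.screened.astype(int)
        return self

    def transform(self, X=None) -> np.ndarray:
        check_is_fitted(self, "schedule_")
        return self.schedule_
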