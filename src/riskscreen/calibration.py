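"""Threshold calibration to a target detection rate, and efficiency metrics.

A discrete schedule can rarely hit the target detection rate exactly, so
the exam count "at" the target is defined by linear interpolation between
the two bracketing thresholds found by bisection: the lower bracket
achieves tdr >= target, the upper bracket tdr <= target.  Both raw
brackets are reported alongside the interpolated count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json

import numpy as np

from .errors import InfeasibleTargetError, InvalidParameterError
from .progression import expected_detections, max_detections
from .strategies import _RULES, _risks_array


@dataclass(frozen=True)
class CalibratedResult:
    strategy: str
    threshold_lo: float
    threshold_hi: float
    tdr_lo: float
    tdr_hi: float
    exams_lo: int
    exams_hi: int
    exams_at_target: float
    tdr_target: float
    n_max: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def calibrate_threshold(
    strategy_name: str,
    risks,
    dp: float,
    tdr_target: float,
    sensitivity: float = 1.0,
    tol: float = 1e-8,
    mode: str = "cascade",
) -> CalibratedResult:
    """Bisect the strategy threshold so the achieved tdr brackets the target.

    Relies on the achieved tdr being non-increasing in the threshold (exact
    for CA and ISA by schedule nesting; empirically true for CAIR).  The
    bisection update only ever moves the lower bracket to a threshold whose
    tdr is >= target, so the bracket invariant tdr_lo >= target > tdr_hi
    holds by construction even under micro non-monotonicity.
    """
    if strategy_name not in _RULES:
        raise InvalidParameterError(
            f"calibratable strategies are {tuple(_RULES)}, got {strategy_name!r}"
        )
    if not (0.0 < tdr_target < 1.0):
        raise InvalidParameterError(f"tdr_target must be in (0, 1), got {tdr_target}")
    arr = _risks_array(risks)
    build = _RULES[strategy_name]
    n_max = max_detections(arr, dp, sensitivity, mode)
    if n_max <= 0.0:
        raise InfeasibleTargetError("population carries no occurrence mass")

    def evaluate(threshold: float) -> tuple[float, int]:
        sched = build(arr, threshold)
        n_act = expected_detections(arr, sched, dp, sensitivity, mode)
        return n_act / n_max, int(sched.sum())

    # domain: threshold 0 is the full schedule (tdr = 1); the upper bound
    # exceeds every relevant risk sum, giving the empty schedule (tdr = 0)
    if strategy_name == "ISA":
        hi = float(arr.max()) + 1e-6
    else:
        hi = float(arr.sum(axis=1).max()) + 1e-6
    lo = 0.0
    tdr_lo, exams_lo = evaluate(lo)
    tdr_hi, exams_hi = evaluate(hi)
    if tdr_lo < tdr_target:
        raise InfeasibleTargetError(
            f"target tdr {tdr_target} exceeds full-schedule tdr {tdr_lo:.6f}"
        )

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        tdr_mid, exams_mid = evaluate(mid)
        if tdr_mid >= tdr_target:
            lo, tdr_lo, exams_lo = mid, tdr_mid, exams_mid
        else:
            hi, tdr_hi, exams_hi = mid, tdr_mid, exams_mid

    if tdr_lo == tdr_hi:
        # degenerate bracket (inside a plateau): the fewer-exams bracket
        exams_at_target = float(min(exams_lo, exams_hi))
    else:
        exams_at_target = exams_hi + (exams_lo - exams_hi) * (
            (tdr_target - tdr_hi) / (tdr_lo - tdr_hi)
        )
    return CalibratedResult(
        strategy=strategy_name,
        threshold_lo=lo,
        threshold_hi=hi,
        tdr_lo=tdr_lo,
        tdr_hi=tdr_hi,
        exams_lo=exams_lo,
        exams_hi=exams_hi,
        exams_at_target=float(exams_at_target),
        tdr_target=tdr_target,
        n_max=n_max,
    )


def saving_percentage(exams_strategy: float, exams_ra: float) -> float:
    """Percent of examinations avoided relative to the random reference.

    May be negative: a risk-based rule can be less efficient than random
    allocation in unfavourable scenarios.
    """
    if exams_ra <= 0.0:
        raise InvalidParameterError("exams_ra must be > 0")
    return 100.0 * (exams_ra - exams_strategy) / exams_ra
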