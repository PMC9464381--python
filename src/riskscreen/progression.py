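"""Curability decay and expected-detection accounting.

Time convention (used everywhere in the package): intervals are 1-based,
interval i spans (i-1, i] years, an examination in interval i happens at
t = i years, and an occurrence in interval i sits at the interval midpoint
t_occ = i - 0.5.  The minimum detection delay is therefore half a year, and
an exam can detect an occurrence of its own interval.

An occurrence detected with delay d is still curable with probability
dp ** d (exponential loss of curability; dp near 1 = slow progression).
Because prediction accuracy is treated as perfect, each annual risk
p_{k,i} is carried as expected occurrence mass rather than sampled as a
binary event: the expected number of curable detections under a schedule
is an exact sum, not a Monte-Carlo estimate.

Imperfect examination sensitivity s is modelled as an independent-miss
cascade: the q-th exam after an occurrence (q = 0, 1, ...) detects it with
probability s * (1-s)**q, discounted by the curability at that exam's
delay.  A "flat" alternative (only the first subsequent exam can detect,
with probability s) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

_MODES = ("cascade", "flat")


def curability(dp: float, delay) -> float | np.ndarray:
    """Probability that an occurrence is still curable after `delay` years."""
    if not (0.0 < dp <= 1.0):
        raise InvalidParameterError(f"dp must be in (0, 1], got {dp}")
    delay = np.asarray(delay, dtype=float)
    if np.any(delay < 0.0):
        raise InvalidParameterError("detection delay cannot be negative")
    out = dp ** delay
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScreeningSchedule:
    """Indicator matrix of examinations: entry (k, i) = exam at t = i+1 years."""

    screened: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.screened)
        if arr.ndim != 2:
            raise InvalidParameterError("schedule must be 2-D (patients x intervals)")
        object.__setattr__(self, "screened", arr.astype(bool))

    @property
    def exam_count(self) -> int:
        return int(self.screened.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.screened.shape[1]
        cols = {f"exam_y{i + 1}": self.screened[:, i].astype(int) for i in range(n)}
        return pd.DataFrame(
            {"patient_id": np.arange(1, self.screened.shape[0] + 1), **cols}
        )


@dataclass(frozen=True)
class DetectionSummary:
    """Expected curable detections of one schedule, and the achieved tdr."""

    n_max: float
    n_actual: float
    tdr_achieved: float
    exams: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _as_indicator(schedule) -> np.ndarray:
    if isinstance(schedule, ScreeningSchedule):
        return schedule.screened
    return np.asarray(schedule).astype(bool)


def _check_mode(sensitivity: float, mode: str) -> None:
    if not (0.0 < sensitivity <= 1.0):
        raise InvalidParameterError(f"sensitivity must be in (0, 1], got {sensitivity}")
    if mode not in _MODES:
        raise InvalidParameterError(f"mode must be one of {_MODES}, got {mode!r}")


def expected_detections(
    risks: np.ndarray,
    screened: np.ndarray,
    dp: float,
    sensitivity: float = 1.0,
    mode: str = "cascade",
) -> float:
    """Expected curable detections of `screened` given occurrence mass `risks`.

    Vectorised over patients; loops only over the (occurrence interval,
    exam interval) pairs, of which there are n*(n+1)/2.
    """
    risks = np.asarray(risks, dtype=float)
    screened = _as_indicator(screened)
    if risks.shape != screened.shape:
        raise InvalidParameterError(
            f"risks {risks.shape} and schedule {screened.shape} dimensions disagree"
        )
    if not (0.0 < dp <= 1.0):
        raise InvalidParameterError(f"dp must be in (0, 1], got {dp}")
    _check_mode(sensitivity, mode)
    n = risks.shape[1]
    dp_tab = dp ** (np.arange(n) + 0.5)  # curability at delay d + 0.5

    if sensitivity == 1.0 or mode == "flat":
        # only the first exam at or after the occurrence interval matters
        scale = sensitivity
        nxt = np.full(risks.shape[0], -1, dtype=np.int64)
        total = 0.0
        for i in range(n - 1, -1, -1):
            nxt = np.where(screened[:, i], i, nxt)
            valid = nxt >= 0
            d = np.clip(nxt - i, 0, n - 1)
            total += float((risks[valid, i] * dp_tab[d[valid]]).sum()) * scale
        return total

    miss = (1.0 - sensitivity) ** np.arange(n)
    cum = np.cumsum(screened, axis=1)
    total = 0.0
    for i in range(n):
        before = cum[:, i] - screened[:, i]  # exams strictly before interval i
        ri = risks[:, i]
        for j in range(i, n):
            has = screened[:, j]
            q = np.clip(cum[:, j] - before - 1, 0, n - 1)
            total += float(
                (ri[has] * miss[q[has]]).sum() * sensitivity * dp_tab[j - i]
            )
    return total


def max_detections(
    risks: np.ndarray, dp: float, sensitivity: float = 1.0, mode: str = "cascade"
) -> float:
    """Expected curable detections under full screening (the tdr denominator).

    Independent of any schedule; with perfect sensitivity it reduces to
    (total occurrence mass) * dp ** 0.5.
    """
    risks = np.asarray(risks, dtype=float)
    _check_mode(sensitivity, mode)
    n = risks.shape[1]
    dp_tab = dp ** (np.arange(n) + 0.5)
    col = risks.sum(axis=0)
    if sensitivity == 1.0 or mode == "flat":
        return float(col.sum() * sensitivity * dp ** 0.5)
    miss = (1.0 - sensitivity) ** np.arange(n)
    # occurrence in interval i (0-based) is covered by exams i..n-1, ranks 0..n-1-i
    f = np.array(
        [sensitivity * (miss[: n - i] * dp_tab[: n - i]).sum() for i in range(n)]
    )
    return float((col * f).sum())


def detection_summary(
    risks,
    schedule,
    dp: float,
    sensitivity: float = 1.0,
    mode: str = "cascade",
) -> DetectionSummary:
    """Full accounting of one schedule: n_max, n_actual, achieved tdr, exams."""
    risks_arr = getattr(risks, "risks", risks)
    screened = _as_indicator(schedule)
    n_actual = expected_detections(risks_arr, screened, dp, sensitivity, mode)
    n_max = max_detections(risks_arr, dp, sensitivity, mode)
    tdr = n_actual / n_max if n_max > 0 else 0.0
    return DetectionSummary(
        n_max=n_max,
        n_actual=n_actual,
        tdr_achieved=tdr,
        exams=int(screened.sum()),
    )


def full_schedule(n_patients: int, n_intervals: int) -> ScreeningSchedule:
    return ScreeningSchedule(np.ones((n_patients, n_intervals), dtype=bool))


def empty_schedule(n_patients: int, n_intervals: int) -> ScreeningSchedule:
    return ScreeningSchedule(np.zeros((n_patients, n_intervals), dtype=bool))
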