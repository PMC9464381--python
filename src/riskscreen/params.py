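"""Scenario parameterisation.

A simulated screening scenario is fully described by three disease /
population parameters (``dp``, ``cvmr``, ``r``), a target detection rate,
and bookkeeping (population size, number of annual intervals, repetitions,
seed).  ``dp`` is the base of the exponential curability decay (0.6 slow,
0.3 intermediate, 0.1 fast progression).  ``cvmr`` is the coefficient of
variation of the five population mean annual risks; ``r`` the common
pairwise correlation between an individual's annual risks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError


@dataclass(frozen=True)
class ScenarioParams:
    dp: float
    cvmr: float
    r: float
    tdr_target: float = 0.90
    n_patients: int = 5000
    mean_5y_risk: float = 0.10
    n_intervals: int = 5
    reps: int = 100
    seed: int = 0
    #: scale of the individual per-year spread sigma_i = sigma_scale / |log10(m_i)|
    sigma_scale: float = 0.01

    def __post_init__(self) -> None:
        errs = []
        if not (0.0 < self.dp <= 1.0):
            errs.append(f"dp must be in (0, 1], got {self.dp}")
        if self.cvmr < 0.0:
            errs.append(f"cvmr must be >= 0, got {self.cvmr}")
        if not (0.0 <= self.r < 1.0):
            errs.append(f"r must be in [0, 1), got {self.r}")
        if not (0.0 < self.tdr_target <= 1.0):
            errs.append(f"tdr_target must be in (0, 1], got {self.tdr_target}")
        if self.n_patients < 1:
            errs.append(f"n_patients must be >= 1, got {self.n_patients}")
        if not (0.0 < self.mean_5y_risk < 1.0):
            errs.append(f"mean_5y_risk must be in (0, 1), got {self.mean_5y_risk}")
        if self.n_intervals < 1:
            errs.append(f"n_intervals must be >= 1, got {self.n_intervals}")
        if self.reps < 1:
            errs.append(f"reps must be >= 1, got {self.reps}")
        if self.sigma_scale < 0.0:
            errs.append(f"sigma_scale must be >= 0, got {self.sigma_scale}")
        if errs:
            raise InvalidParameterError("; ".join(errs))

    @property
    def mean_annual_risk(self) -> float:
        """Population mean annual risk, mean_5y_risk / n_intervals."""
        return self.mean_5y_risk / self.n_intervals

    @property
    def sdmr(self) -> float:
        """Standard deviation of the mean annual risks, cvmr * mean annual risk."""
        return self.cvmr * self.mean_annual_risk

    def with_(self, **kwargs) -> "ScenarioParams":
        return replace(self, **kwargs)
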