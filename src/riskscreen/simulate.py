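"""Population risk-trajectory and individual risk-matrix generation.

The generator works in two stages.  First a population mean annual risk
trajectory m_1..m_n is drawn whose sample mean and sample standard
deviation are standardised to exactly (mean_5y_risk / n, sdmr); the
trajectory therefore sums to the 5-year population risk exactly and its
between-year variation is controlled exactly by ``cvmr``.  Second, each
patient's annual risks are drawn jointly normal around that trajectory
with equicorrelation ``r`` between all year pairs, truncated at zero and
multiplicatively recentred per year so that each column mean equals the
trajectory value (conserving the population occurrence mass that the
target-detection-rate denominator depends on).

Each annual risk is interpreted as expected occurrence mass for that
patient-year (conditional on no earlier event), not sampled as a binary
event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .params import ScenarioParams

_MIN_MEAN = 1e-4
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class MeanRiskTrajectory:
    """Population mean annual risks m_1..m_n (fractions, sum = mean_5y_risk)."""

    means: np.ndarray
    mean_5y_risk: float
    sdmr: float

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))


@dataclass(frozen=True)
class RiskMatrix:
    """n_patients x n_intervals annual conditional risks p_{k,i}."""

    risks: np.ndarray
    trajectory: MeanRiskTrajectory

    @property
    def n_patients(self) -> int:
        return self.risks.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.risks.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Cumulative (e.g. 5-year) risk per patient."""
        return self.risks.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_intervals
        cols = {f"risk_y{i + 1}": self.risks[:, i] for i in range(n)}
        df = pd.DataFrame({"patient_id": np.arange(1, self.n_patients + 1), **cols})
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskMatrix":
        cols = [c for c in df.columns if c.startswith("risk_y")]
        cols.sort(key=lambda c: int(c.removeprefix("risk_y")))
        if not cols:
            raise InvalidParameterError("no risk_y* columns found")
        risks = df[cols].to_numpy(dtype=float)
        means = risks.mean(axis=0)
        traj = MeanRiskTrajectory(
            means=means,
            mean_5y_risk=float(means.sum()),
            sdmr=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        )
        return cls(risks=risks, trajectory=traj)

    @classmethod
    def from_csv(cls, path) -> "RiskMatrix":
        return cls.from_frame(pd.read_csv(path))


def make_mean_trajectory(
    params: ScenarioParams, rng: np.random.Generator
) -> MeanRiskTrajectory:
    """Draw population mean annual risks with exact first two sample moments.

    Standard-normal deviates are affinely standardised so the sample mean is
    exactly mean_5y_risk / n_intervals and the sample SD (ddof=1) exactly
    sdmr = cvmr * mean annual risk.  Redraws (up to 100) if any mean falls
    at or below 1e-4; raises InvalidParameterError if that never succeeds
    (possible for extreme cvmr).
    """
    n = params.n_intervals
    mu = params.mean_annual_risk
    sdmr = params.sdmr
    if params.cvmr == 0.0 or n == 1:
        means = np.full(n, mu)
        return MeanRiskTrajectory(means, params.mean_5y_risk, sdmr)
    for _ in range(_MAX_REDRAWS):
        z = rng.standard_normal(n)
        zc = z - z.mean()
        s = zc.std(ddof=1)
        if s == 0.0:
            continue
        means = mu + sdmr * zc / s
        if np.all(means > _MIN_MEAN):
            return MeanRiskTrajectory(means, params.mean_5y_risk, sdmr)
    raise InvalidParameterError(
        f"could not draw a positive mean trajectory for cvmr={params.cvmr} "
        f"(sdmr={sdmr:.4g}, mean annual risk={mu:.4g})"
    )


def interval_sigmas(trajectory: MeanRiskTrajectory, sigma_scale: float) -> np.ndarray:
    """Per-year individual spread, inversely proportional to |log10(m_i)|.

    Lower mean annual risks (larger |log10|) get tighter individual spreads,
    so rare years stay rare for everyone while common years differentiate
    patients more.
    """
    m = trajectory.means
    if np.any(m >= 1.0):
        raise InvalidParameterError("mean annual risks must be < 1 for the log-spread rule")
    return sigma_scale / np.abs(np.log10(m))


def sample_risk_matrix(
    trajectory: MeanRiskTrajectory,
    params: ScenarioParams,
    rng: np.random.Generator,
    return_untruncated: bool = False,
):
    """Draw the N x n individual annual risk matrix around a trajectory.

    A one-factor construction gives exact equicorrelation r between all year
    pairs of the untruncated draws: X_ki = m_i + sigma_i * (sqrt(r) * g_k +
    sqrt(1-r) * e_ki).  Draws are then truncated at zero and each column is
    multiplicatively rescaled to restore its mean, so the population
    occurrence mass per year equals the trajectory exactly.
    """
    r = params.r
    if not (0.0 <= r < 1.0):
        raise InvalidParameterError(f"r must be in [0, 1), got {r}")
    n = params.n_intervals
    N = params.n_patients
    m = trajectory.means
    sig = interval_sigmas(trajectory, params.sigma_scale)

    shared = rng.standard_normal((N, 1))
    idio = rng.standard_normal((N, n))
    latent = np.sqrt(r) * shared + np.sqrt(1.0 - r) * idio
    raw = m[None, :] + sig[None, :] * latent

    risks = np.clip(raw, 0.0, None)
    col_means = risks.mean(axis=0)
    if np.any(col_means <= 0.0):
        raise InvalidParameterError("a risk column collapsed to zero after truncation")
    risks *= m[None, :] / col_means[None, :]

    matrix = RiskMatrix(risks=risks, trajectory=trajectory)
    if return_untruncated:
        return matrix, raw
    return matrix


def simulate_population(
    params: ScenarioParams,
    rng_trajectory: np.random.Generator,
    rng_matrix: np.random.Generator,
) -> RiskMatrix:
    """Convenience: trajectory draw followed by the matrix draw."""
    traj = make_mean_trajectory(params, rng_trajectory)
    return sample_risk_matrix(traj, params, rng_matrix)
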