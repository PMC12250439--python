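"""Catastrophic health expenditure (CHE) under the budget-share method.

An out-of-pocket (OOP) payment is catastrophic for a household when it
exceeds a stated share of the household's total annual expenditure —
10% or 25%, with 25% the base case.  The boundary is strict (">"), so a
payment exactly at the threshold share is not catastrophic; this makes
results bit-reproducible.

The household-expenditure distribution may be empirical (a list of
positive annual totals) or parametric (lognormal, specified on the log
scale).  Either way the proportion facing CHE at OOP price ``p`` and
threshold ``τ`` is the distribution mass strictly below ``p/τ``.

The normative and partial-normative CHE variants (which deduct a
subsistence basket before computing capacity to pay) are recognised
extension points; see :data:`UNIMPLEMENTED_METHODS`.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

#: CHE estimation variants that the budget-share implementation does not
#: cover; requesting one raises ``NotImplementedError``.
UNIMPLEMENTED_METHODS = ("normative", "partial_normative")

#: Budget-share thresholds conventionally reported; 0.25 is the base case.
DEFAULT_THRESHOLDS = (0.10, 0.25)
BASE_CASE_THRESHOLD = 0.25


@dataclass(frozen=True)
class EmpiricalExpenditure:
    """Empirical household annual total expenditures (currency units)."""

    values: tuple[float, ...]

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.size == 0:
            raise ValueError("empirical expenditure distribution must be non-empty")
        if np.any(arr <= 0):
            raise ValueError("household expenditures must be positive")

    def fraction_below(self, cutoff: float) -> float:
        """Exact fraction of households with expenditure strictly below cutoff."""
        arr = np.asarray(self.values, dtype=float)
        return float(np.count_nonzero(arr < cutoff)) / arr.size

    @classmethod
    def from_file(cls, path: Union[str, pathlib.Path]) -> "EmpiricalExpenditure":
        """Read one positive expenditure per line (blank lines ignored)."""
        lines = pathlib.Path(path).read_text().split()
        return cls(tuple(float(x) for x in lines))


@dataclass(frozen=True)
class LognormalExpenditure:
    """Lognormal household-expenditure distribution (log-scale parameters)."""

    log_mean: float
    log_sd: float

    def __post_init__(self):
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    def fraction_below(self, cutoff: float) -> float:
        if cutoff <= 0:
            return 0.0
        return float(
            stats.lognorm.cdf(cutoff, s=self.log_sd, scale=np.exp(self.log_mean))
        )

    @property
    def mean(self) -> float:
        """Analytic mean ``exp(μ + σ²/2)`` on the natural scale."""
        return float(np.exp(self.log_mean + 0.5 * self.log_sd**2))


ExpenditureDistribution = Union[EmpiricalExpenditure, LognormalExpenditure]


def is_catastrophic(oop: float, household_expenditure: float, threshold: float) -> bool:
    """Whether an OOP payment exceeds ``threshold`` of one household's budget.

    Strict inequality: a payment of exactly the threshold share is not
    catastrophic.
    """
    if household_expenditure <= 0:
        raise ValueError("household_expenditure must be positive")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return oop > threshold * household_expenditure


@dataclass(frozen=True)
class CheResult:
    """Proportion of households for which an OOP price is catastrophic."""

    threshold: float
    proportion_catastrophic: float

    @property
    def affordable_proportion(self) -> float:
        """Complement: households that could pay without crossing the threshold."""
        return 1.0 - self.proportion_catastrophic


def proportion_catastrophic(
    oop: float, dist: ExpenditureDistribution, threshold: float = BASE_CASE_THRESHOLD
) -> CheResult:
    """Population CHE proportion at one OOP price and budget-share threshold.

    ``oop > τ·e`` iff ``e < oop/τ``, so the proportion is the distribution
    mass strictly below ``oop/τ`` (exact count for empirical data, CDF for
    the lognormal form).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if oop < 0:
        raise ValueError("oop must be non-negative")
    if oop == 0:
        return CheResult(threshold=threshold, proportion_catastrophic=0.0)
    cutoff = oop / threshold
    if not isinstance(dist, (EmpiricalExpenditure, LognormalExpenditure)):
        raise TypeError(f"unsupported expenditure distribution: {type(dist).__name__}")
    return CheResult(threshold=threshold, proportion_catastrophic=dist.fraction_below(cutoff))


def che_table(
    oop_by_intervention: dict[str, float],
    dist: ExpenditureDistribution,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[dict]:
    """One row per intervention × threshold, for the CHE report."""
    rows = []
    for name, oop in oop_by_intervention.items():
        for tau in thresholds:
            res = proportion_catastrophic(oop, dist, tau)
            rows.append(
                {
                    "intervention": name,
                    "oop": oop,
                    "threshold": tau,
                    "proportion_catastrophic": res.proportion_catastrophic,
                    "affordable_proportion": res.affordable_proportion,
                }
            )
    return rows
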