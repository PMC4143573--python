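"""Phenotype-expression regression across strains.

Each strain contributes one point: its heat/control expression ratio for a
candidate gene (y) against its doubling-time ratio T_d(30°C)/T_d(high) (x).
A simple ordinary-least-squares line summarises how tightly heat induction of
the gene tracks thermotolerance; the headline statistic is the coefficient of
determination R².  Both axes stay on their natural linear scales by default; a
log-log mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, UndefinedFitError

__all__ = [
    "StrainObservation",
    "CorrelationResult",
    "fit_phenotype_regression",
    "compare_temperatures",
    "TemperatureComparison",
]


@dataclass(frozen=True)
class StrainObservation:
    """One strain's paired (expression ratio, T_d ratio) at one temperature."""

    strain: str
    expression_ratio: float
    td_ratio: float
    temperature: str = ""

    def __post_init__(self) -> None:
        if self.expression_ratio <= 0 or self.td_ratio <= 0:
            raise InvalidInputError("ratios must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    temperature: str
    slope: float
    intercept: float
    r2: float
    n: int
    p_value: float
    low_n: bool  # flagged when n == 3, the minimum for a meaningful R²


def fit_phenotype_regression(
    observations: Sequence[StrainObservation],
    gene: str = "",
    temperature: str = "",
    log_scale: bool = False,
) -> CorrelationResult:
    """OLS of expression ratio on T_d ratio across strains.

    With ``log_scale=True`` both variables are log2-transformed first.
    Requires at least 3 distinct strains and variation in the T_d ratio.
    """
    if len(observations) < 3:
        raise InvalidInputError("regression needs at least 3 strains")
    labels = [o.strain for o in observations]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate strains in observations")
    x = np.array([o.td_ratio for o in observations], dtype=float)
    y = np.array([o.expression_ratio for o in observations], dtype=float)
    if log_scale:
        x, y = np.log2(x), np.log2(y)
    if np.allclose(x, x[0]):
        raise UndefinedFitError("T_d ratio has zero variance across strains")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    if not temperature:
        temps = {o.temperature for o in observations if o.temperature}
        temperature = temps.pop() if len(temps) == 1 else temperature
    return CorrelationResult(
        gene=gene,
        temperature=temperature,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        n=len(observations),
        p_value=float(fit.pvalue),
        low_n=len(observations) == 3,
    )


@dataclass(frozen=True)
class TemperatureComparison:
    """R² per temperature with the stronger association flagged."""

    r2_by_temperature: dict[str, float]
    strongest: tuple[str, ...]  # >1 entry on an exact tie
    warnings: tuple[str, ...] = ()


def compare_temperatures(
    results: Mapping[str, CorrelationResult]
) -> TemperatureComparison:
    """Tabulate R² across heat-treatment temperatures; no inferential claim."""
    if not results:
        raise InvalidInputError("no results to compare")
    warnings: tuple[str, ...] = ()
    if len(results) == 1:
        warnings = ("only one temperature supplied; nothing to compare",)
    r2s = {t: r.r2 for t, r in results.items()}
    best = max(r2s.values())
    strongest = tuple(t for t, v in r2s.items() if v == best)
    return TemperatureComparison(
        r2_by_temperature=r2s, strongest=strongest, warnings=warnings
    )
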