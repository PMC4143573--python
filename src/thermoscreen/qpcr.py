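"""Relative quantification from qPCR Cq values via external standard curves.

A serial dilution of a known template gives, for each gene, a standard curve

    Cq = intercept + slope * log10(concentration),    slope < 0,

whose slope yields the amplification efficiency E = 10^(-1/slope) - 1 (E = 1
is perfect doubling each cycle, slope = -1/log10(2) ~ -3.32).  Unknown samples
are read off the inverted curve, normalized to a reference transcript (ACT1
here), and the heat/control ratio of these normalized rates is the expression
ratio compared against the thermotolerance phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidAssayError, InvalidInputError

__all__ = [
    "StandardSeries",
    "StandardCurve",
    "ExpressionRate",
    "ExpressionRatio",
    "fit_standard_curve",
    "quantify",
    "delta_delta_cq_ratio",
    "normalized_rate",
    "expression_ratio",
    "reference_stability",
    "StabilityReport",
]


@dataclass(frozen=True)
class StandardSeries:
    """Dilution series for one gene: (relative concentration, Cq) pairs."""

    gene: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise InvalidInputError("standard series needs at least 3 points")
        concs = [c for c, _ in self.points]
        if any(c <= 0 for c in concs):
            raise InvalidInputError("concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise InvalidInputError("concentrations must be distinct")
        if any(not np.isfinite(cq) for _, cq in self.points):
            raise InvalidInputError("Cq values must be finite")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line Cq vs log10(concentration) with derived efficiency."""

    gene: str
    slope: float  # cycles per log10(concentration), < 0 for a valid assay
    intercept: float  # Cq at concentration 1
    efficiency: float  # 10^(-1/slope) - 1
    r2: float


@dataclass(frozen=True)
class ExpressionRate:
    """Target quantity divided by reference-gene quantity in one sample."""

    gene: str
    sample: str
    rate: float


@dataclass(frozen=True)
class ExpressionRatio:
    """Heat-treated expression rate over non-treated control rate."""

    gene: str
    strain: str
    temperature: str
    ratio: float


def fit_standard_curve(series: StandardSeries) -> StandardCurve:
    """Least-squares line of Cq against log10(concentration).

    Raises :class:`InvalidAssayError` when the slope is non-negative (more
    template must not need more cycles).
    """
    conc = np.array([c for c, _ in series.points])
    cq = np.array([q for _, q in series.points])
    fit = stats.linregress(np.log10(conc), cq)
    if fit.slope >= 0:
        raise InvalidAssayError(
            f"standard curve for {series.gene!r} has slope {fit.slope:.3g} >= 0"
        )
    r = fit.rvalue
    return StandardCurve(
        gene=series.gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(10.0 ** (-1.0 / fit.slope) - 1.0),
        r2=float(r * r) if np.isfinite(r) else 0.0,
    )


def quantify(cq: float | Sequence[float], curve: StandardCurve) -> float:
    """Relative concentration from a Cq reading via the inverted curve.

    A sequence of Cq values (technical replicates) is averaged before
    inversion.  Strictly decreasing in Cq.
    """
    if curve.slope >= 0:
        raise InvalidAssayError("cannot quantify against a non-negative slope")
    if not np.isscalar(cq):
        cq = fmean(cq)
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def delta_delta_cq_ratio(
    target_heat_cq: float,
    target_control_cq: float,
    reference_heat_cq: float,
    reference_control_cq: float,
    efficiency: float = 1.0,
) -> float:
    """Expression ratio by the comparative-Cq shortcut, for cross-checks.

    (1+E)^(-ddCq) with ddCq = (Cq_t,heat - Cq_t,ctrl) - (Cq_r,heat - Cq_r,ctrl).
    Assumes the target and reference assays share efficiency ``efficiency``.
    """
    if not 0 < efficiency <= 1:
        raise InvalidInputError("efficiency must be in (0, 1]")
    ddcq = (target_heat_cq - target_control_cq) - (
        reference_heat_cq - reference_control_cq
    )
    return float((1.0 + efficiency) ** (-ddcq))


def normalized_rate(
    target_conc: float, reference_conc: float, gene: str = "", sample: str = ""
) -> ExpressionRate:
    """Reference-gene normalization: target / reference concentration."""
    if target_conc <= 0 or reference_conc <= 0:
        raise InvalidInputError("concentrations must be positive")
    return ExpressionRate(gene=gene, sample=sample, rate=target_conc / reference_conc)


def expression_ratio(
    heat: ExpressionRate,
    control: ExpressionRate,
    strain: str = "",
    temperature: str = "",
) -> ExpressionRatio:
    """Heat / control ratio of normalized expression rates."""
    if heat.rate <= 0 or control.rate <= 0:
        raise InvalidInputError("expression rates must be positive")
    if heat.gene != control.gene:
        raise InvalidInputError("ratio mixes genes")
    return ExpressionRatio(
        gene=heat.gene,
        strain=strain,
        temperature=temperature,
        ratio=heat.rate / control.rate,
    )


@dataclass(frozen=True)
class StabilityReport:
    """Is the primary reference gene as stable as a second reference?

    ``log2_deviations`` maps condition -> log2(primary ratio / secondary
    ratio); a perfectly co-stable pair sits at 0 everywhere.
    """

    log2_deviations: dict[str, float]
    mean_log2: float
    sd_log2: float
    tolerance: float
    stable: bool


def reference_stability(
    primary_ratios: Mapping[str, float],
    secondary_ratios: Mapping[str, float],
    tolerance: float = 0.5,
) -> StabilityReport:
    """Compare heat/control ratios of two reference genes across conditions.

    Both mappings are condition -> expression ratio and must cover the same
    conditions.  The pair passes when every per-condition |log2| deviation is
    within ``tolerance`` (default 0.5, i.e. within ~1.4-fold).
    """
    if set(primary_ratios) != set(secondary_ratios):
        raise InvalidInputError("reference ratio mappings cover different conditions")
    if not primary_ratios:
        raise InvalidInputError("no conditions to compare")
    devs = {
        cond: float(np.log2(primary_ratios[cond] / secondary_ratios[cond]))
        for cond in sorted(primary_ratios)
    }
    vals = np.array(list(devs.values()))
    return StabilityReport(
        log2_deviations=devs,
        mean_log2=float(vals.mean()),
        sd_log2=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        tolerance=tolerance,
        stable=bool(np.all(np.abs(vals) <= tolerance)),
    )
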