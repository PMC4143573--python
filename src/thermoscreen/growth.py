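"""Doubling-time estimation from OD600 growth curves and thermotolerance ranking.

The growth phenotype used throughout the package is the doubling time

    T_d = (t2 - t1) / log2(OD2 / OD1)

evaluated either from two points of the curve or, more robustly, as the inverse
slope of a least-squares fit of log2(OD) against time over the linear
(exponential) growth phase.  The two formulations coincide exactly for a
two-point window.  Thermotolerance of a strain is summarised as the ratio
T_d(low temperature) / T_d(high temperature): heat slows growth, so the ratio is
below 1, and larger values mean better relative growth under heat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, NoGrowthError

__all__ = [
    "GrowthCurve",
    "DoublingTimeResult",
    "TdRatio",
    "select_linear_phase",
    "doubling_time",
    "td_ratio",
    "rank_thermotolerance",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one strain at one temperature.

    Parameters
    ----------
    strain, temperature : str
        Labels carried through to downstream results.
    times : array-like of float
        Sampling times in hours, strictly increasing.
    od : array-like of float
        OD600 readings, strictly positive, same length as ``times``.
    """

    strain: str
    temperature: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if times.size != od.size:
            raise InvalidInputError("times and od must have equal length")
        if times.size < 2:
            raise InvalidInputError("a growth curve needs at least 2 points")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(od <= 0) or not np.all(np.isfinite(od)):
            raise InvalidInputError("OD values must be positive and finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class DoublingTimeResult:
    """Doubling time in hours plus the window and fit quality behind it."""

    strain: str
    temperature: str
    td: float
    window: tuple[int, int]
    fit_quality: float


@dataclass(frozen=True)
class TdRatio:
    """Doubling-time ratio T_d(low temp) / T_d(high temp) for one strain."""

    strain: str
    high_temperature: str
    ratio: float


def _log2_r2(times: np.ndarray, log2_od: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of log2(OD) vs time; R^2 is 0 when OD is constant."""
    slope, _, r, _, _ = stats.linregress(times, log2_od)
    if not np.isfinite(r):  # zero variance in log2(od)
        return float(slope), 0.0
    return float(slope), float(r * r)


def select_linear_phase(curve: GrowthCurve, min_points: int = 3) -> tuple[int, int]:
    """Find the contiguous window best described by exponential growth.

    Scans every contiguous window of at least ``min_points`` points and returns
    the (start, end) index pair (inclusive) maximising the coefficient of
    determination of log2(OD) against time.  Ties are broken toward the longer
    window, then toward the earlier one, so a fully exponential curve selects
    its whole range.

    Raises
    ------
    NoGrowthError
        If the curve is flat (no OD variation anywhere).
    InvalidInputError
        If the curve has fewer than ``min_points`` points or ``min_points < 3``.
    """
    if min_points < 3:
        raise InvalidInputError("min_points must be at least 3")
    n = len(curve)
    if n < min_points:
        raise InvalidInputError(f"curve has {n} points, needs at least {min_points}")
    log2_od = np.log2(curve.od)
    if np.allclose(log2_od, log2_od[0]):
        raise NoGrowthError(f"curve for {curve.strain!r} is flat; no growth phase")

    best_key: tuple[float, int, int] | None = None
    best_window = (0, n - 1)
    for start in range(0, n - min_points + 1):
        for end in range(start + min_points - 1, n):
            _, r2 = _log2_r2(curve.times[start : end + 1], log2_od[start : end + 1])
            # maximise r2; ties -> longer window, then earlier start
            key = (round(r2, 12), end - start, -start)
            if best_key is None or key > best_key:
                best_key = key
                best_window = (start, end)
    return best_window


def doubling_time(
    curve: GrowthCurve,
    window: tuple[int, int] | None = None,
    mode: str = "regression",
) -> DoublingTimeResult:
    """Doubling time over a window of the curve.

    ``mode="regression"`` (default) fits log2(OD) against time by least squares
    over the window and returns the inverse slope; ``mode="two-point"`` applies
    T_d = (t2 - t1)/log2(OD2/OD1) to the window endpoints only.  Both reduce to
    the same number for a two-point window.

    ``window`` is an inclusive (start, end) index pair; ``None`` means the whole
    curve.

    Raises
    ------
    NoGrowthError
        If OD does not increase over the window (slope <= 0).
    InvalidInputError
        If the window lies outside the curve or ``mode`` is unknown.
    """
    if mode not in ("regression", "two-point"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    n = len(curve)
    if window is None:
        window = (0, n - 1)
    start, end = window
    if not (0 <= start < end < n):
        raise InvalidInputError(f"window {window} outside curve of length {n}")

    t = curve.times[start : end + 1]
    y = np.log2(curve.od[start : end + 1])

    if mode == "two-point" or end - start == 1:
        if curve.od[end] <= curve.od[start]:
            raise NoGrowthError("OD2 <= OD1 on the window; culture not growing")
        td = (t[-1] - t[0]) / (y[-1] - y[0])
        _, r2 = _log2_r2(t, y) if t.size > 2 else (0.0, 1.0)
    else:
        slope, r2 = _log2_r2(t, y)
        if slope <= 0:
            raise NoGrowthError("non-positive log2(OD) slope; culture not growing")
        td = 1.0 / slope
    return DoublingTimeResult(
        strain=curve.strain,
        temperature=curve.temperature,
        td=float(td),
        window=(start, end),
        fit_quality=float(r2),
    )


def td_ratio(
    td_low_temp: DoublingTimeResult, td_high_temp: DoublingTimeResult
) -> TdRatio:
    """Thermotolerance phenotype: T_d(low temp) / T_d(high temp).

    Heat stress lengthens the doubling time, so the ratio is usually < 1;
    larger values indicate better relative growth under heat.
    """
    if td_low_temp.td <= 0 or td_high_temp.td <= 0:
        raise InvalidInputError("doubling times must be positive")
    if td_low_temp.strain != td_high_temp.strain:
        raise InvalidInputError(
            "T_d ratio mixes strains "
            f"{td_low_temp.strain!r} and {td_high_temp.strain!r}"
        )
    return TdRatio(
        strain=td_low_temp.strain,
        high_temperature=td_high_temp.temperature,
        ratio=td_low_temp.td / td_high_temp.td,
    )


@dataclass(frozen=True)
class ThermotoleranceRanking:
    """Strains ordered most- to least-thermotolerant, with any exact ties."""

    order: tuple[str, ...]
    ratios: dict[str, float] = field(repr=False)
    ties: tuple[tuple[str, str], ...] = ()


def rank_thermotolerance(ratios: Sequence[TdRatio]) -> ThermotoleranceRanking:
    """Sort strains by T_d ratio, descending (most tolerant first).

    Exact ties are reported and the stable input order is kept within a tie.
    """
    if len(ratios) < 2:
        raise InvalidInputError("ranking needs at least 2 strains")
    labels = [r.strain for r in ratios]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate strain labels in ranking input")
    ordered = sorted(ratios, key=lambda r: -r.ratio)
    ties = tuple(
        (a.strain, b.strain)
        for a, b in zip(ordered, ordered[1:])
        if a.ratio == b.ratio
    )
    return ThermotoleranceRanking(
        order=tuple(r.strain for r in ordered),
        ratios={r.strain: r.ratio for r in ordered},
        ties=ties,
    )
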