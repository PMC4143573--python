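"""Synthetic strains, growth curves, expression matrices and qPCR reads.

Every generator here produces data with exactly the statistical structure the
downstream analysis assumes, plus a ground-truth record, so the whole pipeline
can be exercised against planted answers:

* growth: logistic OD600 trajectories with a temperature-dependent specific
  growth rate (the exponential limit is reached by making ``od_max`` large);
* expression: duplicate control/heat arrays per strain, log-normal
  multiplicative noise, background genes with expected fold change 1 and one
  planted gene whose heat induction increases with strain thermotolerance;
* qPCR: Cq values from the exponential amplification model
  Cq(c) = cq0 - log(c)/log(1 + efficiency) with Gaussian cycle noise.

All generators take a single integer seed; independent substreams are derived
per generator so one pipeline seed fixes everything and results are bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import StrainObservation
from .errors import InvalidInputError
from .growth import GrowthCurve
from .qpcr import StandardSeries
from .screen import ExpressionMatrix

__all__ = [
    "StrainSpec",
    "SyntheticTruth",
    "default_strain_trio",
    "simulate_growth_curve",
    "simulate_expression_matrix",
    "simulate_qpcr",
    "simulate_phenotype_cohort",
]

# substream tags keep the per-generator RNGs independent under one pipeline seed
_STREAM_GROWTH = 1
_STREAM_EXPRESSION = 2
_STREAM_QPCR = 3
_STREAM_PHENOTYPE = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class StrainSpec:
    """Parameters of one synthetic yeast strain.

    Parameters
    ----------
    name : str
    tolerance : float
        Dimensionless thermotolerance coefficient in [0, 1]; orders strains
        and (by convention of the callers) scales planted heat induction.
    mu_30 : float
        Specific growth rate at the permissive temperature, per hour.
    mu_hot : float
        Specific growth rate at the elevated temperature, per hour;
        0 < mu_hot <= mu_30 (heat never speeds growth here).
    od_init, od_max : float
        Inoculum OD600 and carrying capacity.
    """

    name: str
    tolerance: float
    mu_30: float
    mu_hot: float
    od_init: float = 0.1
    od_max: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance <= 1:
            raise InvalidInputError("tolerance must be in [0, 1]")
        if self.mu_30 <= 0:
            raise InvalidInputError("mu_30 must be positive")
        if not 0 < self.mu_hot <= self.mu_30:
            raise InvalidInputError("need 0 < mu_hot <= mu_30")
        if not 0 < self.od_init < self.od_max:
            raise InvalidInputError("need 0 < od_init < od_max")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a simulated expression matrix."""

    planted_gene: str
    induction_per_strain: dict[str, float]
    strain_order: tuple[str, ...]  # most- to least-thermotolerant
    noise_sd: float


def default_strain_trio() -> list[StrainSpec]:
    """A tolerant / reference / sensitive trio with realistic growth rates.

    Permissive-temperature doubling times sit near 1.2-1.3 h and the
    heat-stressed rates are scaled so the tolerant strain slows least —
    the regime the screen is designed for.
    """
    return [
        StrainSpec("tolerant", tolerance=0.9, mu_30=np.log(2) / 1.15,
                   mu_hot=np.log(2) / 1.75),
        StrainSpec("reference", tolerance=0.6, mu_30=np.log(2) / 1.34,
                   mu_hot=np.log(2) / 2.11),
        StrainSpec("sensitive", tolerance=0.2, mu_30=np.log(2) / 1.28,
                   mu_hot=np.log(2) / 2.90),
    ]


def simulate_growth_curve(
    strain: StrainSpec,
    temperature: str,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Logistic OD600 trajectory for one strain at one temperature.

    OD(t) = od_max * od_init * e^{mu t} / (od_max + od_init * (e^{mu t} - 1))
    with mu = mu_30 for ``temperature="low"`` and mu = mu_hot for ``"high"``,
    plus additive Gaussian noise truncated so all OD values stay positive.
    """
    if temperature not in ("low", "high"):
        raise InvalidInputError("temperature must be 'low' or 'high'")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise InvalidInputError("times must be non-empty")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be non-negative and strictly increasing")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    mu = strain.mu_30 if temperature == "low" else strain.mu_hot
    growth = np.exp(mu * t)
    od = strain.od_max * strain.od_init * growth / (
        strain.od_max + strain.od_init * (growth - 1.0)
    )
    if noise_sd > 0:
        od = od + _rng(seed, _STREAM_GROWTH).normal(0.0, noise_sd, size=od.shape)
        od = np.maximum(od, 1e-6)  # truncate: OD600 readings cannot go negative
    return GrowthCurve(strain=strain.name, temperature=temperature, times=t, od=od)


def simulate_expression_matrix(
    strains: Sequence[StrainSpec],
    n_genes: int = 1000,
    n_replicates: int = 2,
    planted_induction: Mapping[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    absent_flag_fraction: float = 0.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Control/heat intensity matrix with one planted concordant gene.

    Background genes have expected heat/control fold change 1; the planted
    gene's expected fold in each strain equals ``planted_induction[strain]``
    (default: induction 1.5 + 3 * tolerance, strictly increasing with the
    strain's thermotolerance coefficient).  Noise is i.i.d. Gaussian on the
    log2 scale (log-normal multiplicative on the linear scale), emulating
    duplicate arrays from independently grown cultures.

    The planted gene is assigned the median baseline intensity so intensity
    filters act on it the way they would on a typical detected transcript.
    ``absent_flag_fraction`` marks that fraction of the dimmest background
    genes "absent" in every sample; everything else is "present".

    Returns the matrix (linear scale) and the ground-truth record.
    """
    if len(strains) < 2:
        raise InvalidInputError("screen needs cross-strain ratios: >=2 strains")
    if n_genes < 2:
        raise InvalidInputError("n_genes must be >= 2")
    if n_replicates < 2:
        raise InvalidInputError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    names = [s.name for s in strains]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate strain names")
    if planted_induction is None:
        planted_induction = {s.name: 1.5 + 3.0 * s.tolerance for s in strains}
    missing = [n for n in names if n not in planted_induction]
    if missing:
        raise InvalidInputError(f"planted_induction lacks strains: {missing}")

    rng = _rng(seed, _STREAM_EXPRESSION)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    baselines = rng.uniform(4.0, 12.0, size=n_genes)  # log2 intensity units
    planted_idx = int(np.argsort(baselines)[n_genes // 2])  # median baseline
    planted_gene = genes[planted_idx]

    columns, meta_rows = [], []
    log2_cols = []
    for strain in strains:
        for condition in ("control", "heat"):
            for rep in range(1, n_replicates + 1):
                sample = f"{strain.name}_{condition}_r{rep}"
                col = baselines.copy()
                if condition == "heat":
                    col[planted_idx] += np.log2(planted_induction[strain.name])
                if noise_sd > 0:
                    col = col + rng.normal(0.0, noise_sd, size=n_genes)
                columns.append(sample)
                log2_cols.append(col)
                meta_rows.append((sample, strain.name, condition, rep))

    values = pd.DataFrame(
        2.0 ** np.column_stack(log2_cols), index=genes, columns=columns
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample", "strain", "condition", "replicate"]
    ).set_index("sample")

    flags = pd.DataFrame("present", index=genes, columns=columns)
    if absent_flag_fraction > 0:
        n_absent = int(np.floor(absent_flag_fraction * n_genes))
        dim = np.argsort(baselines)[:n_absent]
        dim = dim[dim != planted_idx]
        flags.iloc[dim, :] = "absent"

    order = tuple(
        s.name for s in sorted(strains, key=lambda s: -s.tolerance)
    )
    truth = SyntheticTruth(
        planted_gene=planted_gene,
        induction_per_strain=dict(planted_induction),
        strain_order=order,
        noise_sd=noise_sd,
    )
    matrix = ExpressionMatrix(values=values, metadata=metadata, flags=flags)
    return matrix, truth


def simulate_qpcr(
    true_conc: float,
    efficiency: float = 1.0,
    cq0: float = 20.0,
    dilution_factors: Sequence[float] = (0.1, 0.01, 0.001, 0.0001),
    cq_noise_sd: float = 0.0,
    seed: int = 0,
    gene: str = "target",
    n_technical: int = 2,
) -> tuple[StandardSeries, float]:
    """Standard dilution series plus one unknown-sample Cq measurement.

    Cq(c) = cq0 - log(c)/log(1 + efficiency): at perfect efficiency each
    halving of template costs one extra cycle and a 10-fold dilution costs
    log2(10) ~ 3.32 cycles.  Every reported Cq is the mean of ``n_technical``
    independent reads (default 2, the usual technical-duplicate practice),
    each carrying Gaussian noise of SD ``cq_noise_sd`` cycles.  The default
    dilutions span 1/10 to 1/10000.
    """
    if not 0 < efficiency <= 1:
        raise InvalidInputError("efficiency must be in (0, 1]")
    if true_conc <= 0:
        raise InvalidInputError("true_conc must be positive")
    dil = np.asarray(dilution_factors, dtype=float)
    if dil.size < 3:
        raise InvalidInputError("need at least 3 dilution points")
    if np.any(dil <= 0):
        raise InvalidInputError("dilution factors must be positive")
    if cq_noise_sd < 0:
        raise InvalidInputError("cq_noise_sd must be non-negative")
    if n_technical < 1:
        raise InvalidInputError("n_technical must be >= 1")

    rng = _rng(seed, _STREAM_QPCR)
    base = np.log(1.0 + efficiency)

    def cq_model(c: np.ndarray | float) -> np.ndarray | float:
        return cq0 - np.log(c) / base

    series_cq = np.asarray(cq_model(dil), dtype=float)
    measured = float(cq_model(true_conc))
    if cq_noise_sd > 0:
        # each reported Cq is the mean over technical replicates
        series_cq = series_cq + rng.normal(
            0.0, cq_noise_sd, size=(n_technical, dil.size)
        ).mean(axis=0)
        measured += float(rng.normal(0.0, cq_noise_sd, size=n_technical).mean())
    series = StandardSeries(
        gene=gene, points=tuple(zip(dil.tolist(), series_cq.tolist()))
    )
    return series, measured


def simulate_phenotype_cohort(
    n_strains: int = 8,
    slope: float = 10.0,
    intercept: float = 1.0,
    population_r2: float = 0.8,
    td_ratio_range: tuple[float, float] = (0.3, 0.9),
    temperature: str = "37C",
    seed: int = 0,
) -> tuple[list[StrainObservation], float]:
    """Cohort of strains with a planted linear phenotype-expression relation.

    T_d ratios are drawn uniformly on ``td_ratio_range``; expression ratios
    follow intercept + slope * x plus Gaussian noise whose variance is set
    from the realized x sample variance so the population R² (fraction of
    response variance explained by the line) equals ``population_r2``.

    Returns the observations and the noise SD actually used.
    """
    if n_strains < 3:
        raise InvalidInputError("cohort needs >= 3 strains")
    if not 0 < population_r2 < 1:
        raise InvalidInputError("population_r2 must be in (0, 1)")
    rng = _rng(seed, _STREAM_PHENOTYPE)
    lo, hi = td_ratio_range
    x = rng.uniform(lo, hi, size=n_strains)
    var_signal = slope**2 * x.var(ddof=1)
    noise_sd = float(np.sqrt(var_signal * (1.0 - population_r2) / population_r2))
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n_strains)
    y = np.maximum(y, 1e-6)  # expression ratios are positive
    obs = [
        StrainObservation(
            strain=f"strain_{i:02d}",
            expression_ratio=float(y[i]),
            td_ratio=float(x[i]),
            temperature=temperature,
        )
        for i in range(n_strains)
    ]
    return obs, noise_sd
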