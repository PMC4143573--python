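"""Preprocessing and three-stage cross-strain screen for heat-induced genes.

The screen compares heat/control expression fold changes across three strains
with known relative thermotolerance — a tolerant strain, a reference strain and
a sensitive strain — and keeps genes whose heat induction tracks that ranking:

* stage 1: fold change > threshold (default 1.5) in BOTH the tolerant and the
  reference strain (heat induction in the strains that grow under heat);
* stage 2: ratio of fold changes tolerant/reference > threshold OR
  reference/sensitive > threshold (induction scales with tolerance somewhere);
* stage 3: fold changes strictly decreasing along the full tolerance order
  (perfect rank concordance).

Upstream of the screen the expression matrix is preprocessed the way array
intensity data usually is: per-sample 75th-percentile shift on the log2 scale,
removal of probes in the lowest 20% of every sample, removal of probes not
called present/marginal, and optionally a per-strain two-sample t-test between
heat and control replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "ExpressionMatrix",
    "FoldChangeTable",
    "ScreenConfig",
    "ScreenResult",
    "percentile_shift_normalize",
    "low_intensity_filter",
    "flag_filter",
    "fold_change",
    "fold_change_table",
    "differential_filter",
    "screen_stage1",
    "screen_stage2",
    "screen_stage3",
    "run_screen",
]

VALID_FLAGS = frozenset({"present", "marginal", "absent"})
META_COLUMNS = ("strain", "condition", "replicate")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples intensity matrix with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (unique index), samples in columns.  Strictly positive
        when ``scale == "linear"``; unconstrained on the log2 scale.
    metadata : pandas.DataFrame
        Indexed by sample name, with columns ``strain``, ``condition``
        (``control``/``heat``) and ``replicate``.
    flags : pandas.DataFrame, optional
        Detection calls (``present``/``marginal``/``absent``), same shape and
        labels as ``values``.  ``None`` means no calls available.
    scale : {"linear", "log2"}
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    flags: pd.DataFrame | None = None
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise InvalidInputError("duplicate gene ids in expression matrix")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise InvalidInputError(f"samples without metadata: {sorted(missing)}")
        for col in META_COLUMNS:
            if col not in self.metadata.columns:
                raise InvalidInputError(f"metadata lacks column {col!r}")
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            raise InvalidInputError("linear-scale intensities must be positive")
        if self.flags is not None:
            bad = set(np.unique(self.flags.to_numpy())) - VALID_FLAGS
            if bad:
                raise InvalidInputError(f"unknown detection flags: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.metadata.loc[self.samples, "strain"]))

    def samples_for(self, strain: str, condition: str) -> list[str]:
        meta = self.metadata.loc[self.samples]
        mask = (meta["strain"] == strain) & (meta["condition"] == condition)
        return list(meta.index[mask])

    def log2_values(self) -> pd.DataFrame:
        return np.log2(self.values) if self.scale == "linear" else self.values

    def subset_genes(self, keep: pd.Series | Iterable[str]) -> "ExpressionMatrix":
        if isinstance(keep, pd.Series):
            keep = keep.index[keep]
        flags = self.flags.loc[keep] if self.flags is not None else None
        return replace(self, values=self.values.loc[keep], flags=flags)


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-gene, per-strain heat/control fold changes on the linear scale."""

    folds: pd.DataFrame  # genes x strains
    p_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.folds.to_numpy() <= 0).any():
            raise InvalidInputError("fold changes must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.folds.index

    @property
    def strains(self) -> list[str]:
        return list(self.folds.columns)


# ---------------------------------------------------------------------------
# preprocessing


def percentile_shift_normalize(
    matrix: ExpressionMatrix, percentile: float = 75.0
) -> ExpressionMatrix:
    """Per-sample percentile shift on the log2 scale.

    Each sample is log2-transformed and shifted so that its ``percentile``-th
    percentile equals exactly 0, removing per-sample global intensity
    differences.  Returns a log2-scale matrix.
    """
    if not 0 <= percentile <= 100:
        raise InvalidInputError("percentile must be in [0, 100]")
    if matrix.scale == "linear" and (matrix.values.to_numpy() <= 0).any():
        raise InvalidInputError("non-positive intensities cannot be log-transformed")
    log2 = matrix.log2_values()
    shifts = log2.quantile(percentile / 100.0, axis=0)
    return replace(matrix, values=log2 - shifts, scale="log2")


def low_intensity_filter(
    matrix: ExpressionMatrix, fraction: float = 0.2
) -> pd.Series:
    """Keep-mask removing genes that sit in the lowest ``fraction`` of EVERY sample.

    This is the permissive reading of low-intensity filtering: a gene expressed
    above the cutoff in even one sample (e.g. induced under heat but silent in
    controls) is kept.  Returns a boolean Series indexed by gene (True = keep).
    """
    if not 0 <= fraction < 1:
        raise InvalidInputError("fraction must be in [0, 1)")
    n_low = int(np.floor(fraction * len(matrix.genes)))
    if n_low == 0:
        return pd.Series(True, index=matrix.genes)
    # rank 0 = dimmest; a gene is "low" in a sample if its rank < n_low
    # (min-rank so exact ties resolve independently of row order)
    ranks = matrix.values.rank(axis=0, method="min") - 1
    low_everywhere = (ranks < n_low).all(axis=1)
    return ~low_everywhere


def flag_filter(
    matrix: ExpressionMatrix,
    allowed: frozenset[str] | set[str] = frozenset({"present", "marginal"}),
) -> pd.Series:
    """Keep-mask from detection calls: kept iff called in ``allowed`` in at
    least half of the samples.  Matrices without flags keep every gene."""
    bad = set(allowed) - VALID_FLAGS
    if bad:
        raise InvalidInputError(f"unknown flag labels: {sorted(bad)}")
    if matrix.flags is None:
        return pd.Series(True, index=matrix.genes)
    ok = matrix.flags.isin(allowed)
    return ok.sum(axis=1) >= ok.shape[1] / 2.0


def differential_filter(
    matrix: ExpressionMatrix, strain: str, alpha: float = 0.05
) -> pd.Series:
    """Keep-mask from a per-gene two-sample t-test, heat vs control replicates.

    The test is run on log2 values, unpaired, equal-variance, with no
    multiple-testing correction.  Genes with p < ``alpha`` are kept.  Genes
    whose test is degenerate (zero variance in both groups with equal means)
    get p = 1 and are removed.
    """
    heat = matrix.samples_for(strain, "heat")
    ctrl = matrix.samples_for(strain, "control")
    if len(heat) < 2 or len(ctrl) < 2:
        raise InvalidInputError(
            f"t-test needs >=2 replicates per condition for strain {strain!r}"
        )
    log2 = matrix.log2_values()
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(log2[heat], log2[ctrl], axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p < alpha, index=matrix.genes)


# ---------------------------------------------------------------------------
# fold changes


def fold_change(
    matrix: ExpressionMatrix, strain: str, mode: str = "geometric"
) -> pd.Series:
    """Per-gene heat/control fold change for one strain, on the linear scale.

    ``mode="geometric"`` (default) back-transforms the difference of mean log2
    values — the geometric mean over replicates, the usual choice for array
    intensities; ``mode="arithmetic"`` uses plain means of linear intensities.
    """
    if mode not in ("geometric", "arithmetic"):
        raise InvalidInputError(f"unknown fold-change mode {mode!r}")
    heat = matrix.samples_for(strain, "heat")
    ctrl = matrix.samples_for(strain, "control")
    if not heat or not ctrl:
        raise InvalidInputError(
            f"strain {strain!r} lacks heat or control samples"
        )
    if mode == "geometric":
        log2 = matrix.log2_values()
        fold = 2.0 ** (log2[heat].mean(axis=1) - log2[ctrl].mean(axis=1))
    else:
        if matrix.scale != "linear":
            raise InvalidInputError("arithmetic fold change needs linear scale")
        fold = matrix.values[heat].mean(axis=1) / matrix.values[ctrl].mean(axis=1)
    fold.name = strain
    return fold


def fold_change_table(
    matrix: ExpressionMatrix,
    strains: Iterable[str] | None = None,
    mode: str = "geometric",
) -> FoldChangeTable:
    """Fold changes for several strains, as genes x strains."""
    strains = list(strains) if strains is not None else matrix.strains
    folds = pd.concat([fold_change(matrix, s, mode=mode) for s in strains], axis=1)
    return FoldChangeTable(folds=folds)


# ---------------------------------------------------------------------------
# screen stages


def _require_strains(fc: FoldChangeTable, strains: Iterable[str]) -> None:
    missing = [s for s in strains if s not in fc.folds.columns]
    if missing:
        raise InvalidInputError(f"strains absent from fold-change table: {missing}")


def screen_stage1(
    fc: FoldChangeTable,
    tolerant: str,
    reference: str,
    threshold: float = 1.5,
    absolute: bool = False,
) -> set[str]:
    """Genes heat-induced above ``threshold``-fold in both the tolerant and the
    reference strain (strict inequality; boundary values fail).

    With ``absolute=True`` a fold below 1/threshold also qualifies (two-sided
    change); the default keeps up-regulated genes only.
    """
    _require_strains(fc, [tolerant, reference])
    f = fc.folds
    if absolute:
        hit = (f > threshold) | (f < 1.0 / threshold)
    else:
        hit = f > threshold
    mask = hit[tolerant] & hit[reference]
    return set(f.index[mask])


def screen_stage2(
    fc: FoldChangeTable,
    tolerant: str,
    reference: str,
    sensitive: str,
    threshold: float = 1.5,
) -> set[str]:
    """Genes whose fold-change ratio tolerant/reference OR reference/sensitive
    exceeds ``threshold`` (inclusive or, strict inequality)."""
    if len({tolerant, reference, sensitive}) != 3:
        raise InvalidInputError("stage 2 needs three distinct strains")
    _require_strains(fc, [tolerant, reference, sensitive])
    f = fc.folds
    ratio_tr = f[tolerant] / f[reference]
    ratio_rs = f[reference] / f[sensitive]
    mask = (ratio_tr > threshold) | (ratio_rs > threshold)
    return set(f.index[mask])


def screen_stage3(
    fc: FoldChangeTable, tolerance_order: tuple[str, ...] | list[str]
) -> set[str]:
    """Genes whose fold changes strictly decrease along the tolerance order.

    ``tolerance_order`` lists strains most- to least-thermotolerant.  Perfect
    rank concordance is required: any tie or inversion fails the gene.  For
    more than three strains this is equivalent to Spearman correlation 1 with
    the order.
    """
    order = list(tolerance_order)
    _require_strains(fc, order)
    if len(order) < 2:
        raise InvalidInputError("tolerance order needs at least 2 strains")
    f = fc.folds[order].to_numpy()
    monotone = (np.diff(f, axis=1) < 0).all(axis=1)
    return set(fc.folds.index[monotone])


# ---------------------------------------------------------------------------
# the full screen


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the preprocessing + screen chain.

    fc_threshold applies to stage 1 (fold change) and stage 2 (fold-change
    ratio).  ``differential`` switches the per-strain t-test filter on; it is
    off by default because with duplicate arrays the test has almost no power
    and its position in the chain is a judgement call (when on, it runs after
    the intensity/flag filters, and a gene must be significant in every
    screened strain).
    """

    percentile: float = 75.0
    low_fraction: float = 0.2
    flags_allowed: frozenset[str] = frozenset({"present", "marginal"})
    fc_threshold: float = 1.5
    fc_mode: str = "geometric"
    stage1_absolute: bool = False
    differential: bool = False
    alpha: float = 0.05


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the three-stage screen with a per-gene audit trail.

    ``audit`` has one row per gene that survived preprocessing: its fold
    change per strain and a boolean per stage.  ``stage3_genes`` is the final
    candidate set; the subset chain stage3 <= stage2 <= stage1 always holds.
    """

    stage1_genes: frozenset[str]
    stage2_genes: frozenset[str]
    stage3_genes: frozenset[str]
    audit: pd.DataFrame
    fold_changes: FoldChangeTable
    config: ScreenConfig
    tolerance_order: tuple[str, ...]
    n_input_genes: int
    n_filtered_genes: int
    warnings: tuple[str, ...] = ()


def run_screen(
    matrix: ExpressionMatrix,
    roles: Mapping[str, str],
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Run normalization, filtering and the three-stage screen.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Linear-scale intensities (or already log2 with ``scale="log2"``, in
        which case the percentile shift still applies).
    roles : mapping
        Keys ``tolerant``, ``reference``, ``sensitive`` naming the strains.
    config : ScreenConfig, optional

    Returns
    -------
    ScreenResult
        Candidate sets per stage plus the per-gene audit.
    """
    config = config or ScreenConfig()
    for role in ("tolerant", "reference", "sensitive"):
        if role not in roles:
            raise InvalidInputError(f"roles mapping lacks {role!r}")
    tol, ref, sen = roles["tolerant"], roles["reference"], roles["sensitive"]
    order = (tol, ref, sen)
    warnings: list[str] = []

    norm = percentile_shift_normalize(matrix, percentile=config.percentile)
    keep = flag_filter(norm, allowed=config.flags_allowed)
    keep &= low_intensity_filter(norm, fraction=config.low_fraction)
    filtered = norm.subset_genes(keep)
    if config.differential:
        for strain in order:
            filtered = filtered.subset_genes(
                differential_filter(filtered, strain, alpha=config.alpha)
            )

    if len(filtered.genes) == 0:
        warnings.append("no genes survived preprocessing filters")
        empty = pd.DataFrame(
            columns=[*order, "stage1", "stage2", "stage3"]
        )
        return ScreenResult(
            stage1_genes=frozenset(),
            stage2_genes=frozenset(),
            stage3_genes=frozenset(),
            audit=empty,
            fold_changes=FoldChangeTable(
                folds=pd.DataFrame(
                    np.empty((0, 3)), columns=list(order), dtype=float
                )
            ),
            config=config,
            tolerance_order=order,
            n_input_genes=len(matrix.genes),
            n_filtered_genes=0,
            warnings=tuple(warnings),
        )

    fc = fold_change_table(filtered, strains=order, mode=config.fc_mode)
    return screen_fold_changes(
        fc, roles, config=config, n_input_genes=len(matrix.genes),
        warnings=tuple(warnings),
    )


def screen_fold_changes(
    fc: FoldChangeTable,
    roles: Mapping[str, str],
    config: ScreenConfig | None = None,
    n_input_genes: int | None = None,
    warnings: tuple[str, ...] = (),
) -> ScreenResult:
    """Run only stages 1-3 on an existing fold-change table.

    Entry point for pre-computed fold changes (e.g. a published table) where
    raw intensities are unavailable and preprocessing is bypassed.
    """
    config = config or ScreenConfig()
    tol, ref, sen = roles["tolerant"], roles["reference"], roles["sensitive"]
    order = (tol, ref, sen)
    s1 = screen_stage1(
        fc, tol, ref, threshold=config.fc_threshold, absolute=config.stage1_absolute
    )
    s2 = s1 & screen_stage2(fc, tol, ref, sen, threshold=config.fc_threshold)
    s3 = s2 & screen_stage3(fc, order)
    audit = fc.folds[list(order)].copy()
    audit["stage1"] = audit.index.isin(s1)
    audit["stage2"] = audit.index.isin(s2)
    audit["stage3"] = audit.index.isin(s3)
    return ScreenResult(
        stage1_genes=frozenset(s1),
        stage2_genes=frozenset(s2),
        stage3_genes=frozenset(s3),
        audit=audit,
        fold_changes=fc,
        config=config,
        tolerance_order=order,
        n_input_genes=n_input_genes if n_input_genes is not None else len(fc.genes),
        n_filtered_genes=len(fc.genes),
        warnings=warnings,
    )
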