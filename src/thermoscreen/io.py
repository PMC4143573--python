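"""TSV/JSON readers and writers for the pipeline's on-disk formats.

Formats:

* growth curve — TSV with columns ``time_h``, ``od600``; strain and
  temperature live in the file name or a manifest, so the reader takes them
  as arguments;
* expression matrix — TSV with gene ids in the first column and one column
  per sample, plus a sample-metadata TSV (``sample``, ``strain``,
  ``condition``, ``replicate``, optional ``flag``; a per-sample ``flag``
  column applies one call to every gene of that sample — per-gene calls use
  a separate flags TSV shaped like the matrix);
* Cq table — TSV with ``gene``, ``sample``, ``cq``, ``role``
  (``standard``/``unknown``) and ``dilution`` for standards;
* observations — TSV with ``strain``, ``temperature``, ``expression_ratio``,
  ``td_ratio``;
* screen result — TSV audit plus a JSON summary; synthetic ground truth —
  JSON or YAML sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .correlation import StrainObservation
from .errors import InvalidInputError
from .growth import GrowthCurve
from .qpcr import StandardSeries
from .screen import ExpressionMatrix, ScreenResult
from .synthetic import SyntheticTruth

__all__ = [
    "read_growth_curve",
    "write_growth_curve",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_cq_table",
    "write_cq_table",
    "standard_series_from_cq_table",
    "read_observations",
    "write_observations",
    "write_screen_result",
    "write_truth",
    "read_truth",
]


def read_growth_curve(path: str | Path, strain: str, temperature: str) -> GrowthCurve:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("time_h", "od600"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    return GrowthCurve(
        strain=strain,
        temperature=temperature,
        times=df["time_h"].to_numpy(float),
        od=df["od600"].to_numpy(float),
    )


def write_growth_curve(curve: GrowthCurve, path: str | Path) -> None:
    pd.DataFrame({"time_h": curve.times, "od600": curve.od}).to_csv(
        path, sep="\t", index=False
    )


def read_expression_matrix(
    matrix_path: str | Path,
    metadata_path: str | Path,
    flags_path: str | Path | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0)
    elif "flag" in meta.columns and meta["flag"].notna().any():
        # broadcast per-sample calls to every gene of that sample
        flags = pd.DataFrame(
            {s: meta.loc[s, "flag"] for s in values.columns}, index=values.index
        )
    return ExpressionMatrix(
        values=values,
        metadata=meta.drop(columns=["flag"], errors="ignore"),
        flags=flags,
        scale=scale,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    metadata_path: str | Path,
    flags_path: str | Path | None = None,
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene")
    matrix.metadata.to_csv(metadata_path, sep="\t", index_label="sample")
    if flags_path is not None and matrix.flags is not None:
        matrix.flags.to_csv(flags_path, sep="\t", index_label="gene")


def read_cq_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("gene", "sample", "cq"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    return df


def write_cq_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def standard_series_from_cq_table(df: pd.DataFrame, gene: str) -> StandardSeries:
    """Assemble one gene's dilution series from a long-format Cq table."""
    if "role" not in df.columns or "dilution" not in df.columns:
        raise InvalidInputError("Cq table lacks 'role'/'dilution' columns")
    std = df[(df["gene"] == gene) & (df["role"] == "standard")]
    if std.empty:
        raise InvalidInputError(f"no standard rows for gene {gene!r}")
    points = tuple(zip(std["dilution"].astype(float), std["cq"].astype(float)))
    return StandardSeries(gene=gene, points=points)


def read_observations(path: str | Path) -> list[StrainObservation]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        StrainObservation(
            strain=row["strain"],
            expression_ratio=float(row["expression_ratio"]),
            td_ratio=float(row["td_ratio"]),
            temperature=str(row.get("temperature", "")),
        )
        for _, row in df.iterrows()
    ]


def write_observations(obs: list[StrainObservation], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(o) for o in obs]).to_csv(
        path, sep="\t", index=False
    )


def write_screen_result(
    result: ScreenResult, audit_path: str | Path, summary_path: str | Path
) -> None:
    """Audit table as TSV, stage sets and parameters as JSON."""
    result.audit.to_csv(audit_path, sep="\t", index_label="gene")
    summary: dict[str, Any] = {
        "stage1_genes": sorted(result.stage1_genes),
        "stage2_genes": sorted(result.stage2_genes),
        "stage3_genes": sorted(result.stage3_genes),
        "tolerance_order": list(result.tolerance_order),
        "n_input_genes": result.n_input_genes,
        "n_filtered_genes": result.n_filtered_genes,
        "config": dataclasses.asdict(result.config),
        "warnings": list(result.warnings),
    }
    summary["config"]["flags_allowed"] = sorted(summary["config"]["flags_allowed"])
    Path(summary_path).write_text(json.dumps(summary, indent=2))


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Ground-truth sidecar as YAML (or JSON if the path ends in .json)."""
    payload = {
        "planted_gene": truth.planted_gene,
        "induction_per_strain": dict(truth.induction_per_strain),
        "strain_order": list(truth.strain_order),
        "noise_sd": truth.noise_sd,
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_truth(path: str | Path) -> SyntheticTruth:
    path = Path(path)
    raw = path.read_text()
    payload = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    return SyntheticTruth(
        planted_gene=payload["planted_gene"],
        induction_per_strain=dict(payload["induction_per_strain"]),
        strain_order=tuple(payload["strain_order"]),
        noise_sd=float(payload["noise_sd"]),
    )
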