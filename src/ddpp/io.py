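"""Readers and writers for expression, clinical, panel, model, and report files.

Formats are deliberately plain: comma-separated UTF-8 with a header row (TSV
accepted by extension), and JSON for panels, fitted models, and reports.

Expression tables are accepted in two dialects, auto-detected from the header:

* long  — ``patient_id,gene,tumor_intensity,normal_intensity``
* wide  — a ``gene`` column plus ``<patient>_tumor`` / ``<patient>_normal``
  column pairs, one pair per patient
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datamodel import (
    Channel,
    Cohort,
    DDPPModel,
    FeatureMode,
    FoldResult,
    GenePanel,
    NullScanResult,
    PairedExpression,
    PatientRecord,
    SummationMethod,
    ValidationError,
    ValidationReport,
)

__all__ = [
    "ParseError",
    "read_expression_table",
    "write_expression_table",
    "read_clinical_table",
    "write_clinical_table",
    "attach_expression",
    "read_panel",
    "write_panel",
    "read_model",
    "write_model",
    "write_report",
    "write_null_scan",
]

LONG_COLUMNS = ("patient_id", "gene", "tumor_intensity", "normal_intensity")


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _separator(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep=_separator(path), dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise ParseError(f"cannot read {path}: {exc}") from exc


def _positive_float(raw: str, *, gene: str, patient: str, label: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric {label} {raw!r} for gene {gene!r}, patient {patient!r}"
        ) from None
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(
            f"{label} must be > 0 for gene {gene!r}, patient {patient!r}; "
            f"got {value!r}"
        )
    return value


def read_expression_table(path: str | Path) -> dict[str, dict[str, PairedExpression]]:
    """Parse an expression CSV/TSV into per-patient gene maps.

    Both long and wide dialects are accepted; the dialect is chosen from the
    header names alone.
    """
    df = _read_table(path)
    cols = list(df.columns)
    if all(c in cols for c in LONG_COLUMNS):
        return _parse_long(df)
    if "gene" in cols:
        return _parse_wide(df)
    raise ParseError(
        f"unrecognized expression header {cols}: expected long columns "
        f"{list(LONG_COLUMNS)} or a 'gene' column with <patient>_tumor/"
        f"<patient>_normal pairs"
    )


def _parse_long(df: pd.DataFrame) -> dict[str, dict[str, PairedExpression]]:
    out: dict[str, dict[str, PairedExpression]] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        gene = str(row.gene)
        per_patient = out.setdefault(pid, {})
        if gene in per_patient:
            raise ParseError(f"duplicate gene {gene!r} for patient {pid!r}")
        per_patient[gene] = PairedExpression(
            gene=gene,
            tumor_intensity=_positive_float(
                row.tumor_intensity, gene=gene, patient=pid, label="tumor_intensity"
            ),
            normal_intensity=_positive_float(
                row.normal_intensity, gene=gene, patient=pid, label="normal_intensity"
            ),
        )
    return out


def _parse_wide(df: pd.DataFrame) -> dict[str, dict[str, PairedExpression]]:
    tumor_cols = {c[: -len("_tumor")]: c for c in df.columns if c.endswith("_tumor")}
    normal_cols = {c[: -len("_normal")]: c for c in df.columns if c.endswith("_normal")}
    patients = sorted(tumor_cols)
    if not patients or sorted(normal_cols) != patients:
        raise ParseError(
            "wide expression table must contain matching <patient>_tumor and "
            f"<patient>_normal column pairs; got tumor={sorted(tumor_cols)}, "
            f"normal={sorted(normal_cols)}"
        )
    out: dict[str, dict[str, PairedExpression]] = {p: {} for p in patients}
    for row in df.itertuples(index=False):
        gene = str(getattr(row, "gene"))
        for pid in patients:
            if gene in out[pid]:
                raise ParseError(f"duplicate gene {gene!r} for patient {pid!r}")
            out[pid][gene] = PairedExpression(
                gene=gene,
                tumor_intensity=_positive_float(
                    getattr(row, tumor_cols[pid]),
                    gene=gene,
                    patient=pid,
                    label="tumor_intensity",
                ),
                normal_intensity=_positive_float(
                    getattr(row, normal_cols[pid]),
                    gene=gene,
                    patient=pid,
                    label="normal_intensity",
                ),
            )
    return out


def write_expression_table(
    expression: dict[str, dict[str, PairedExpression]], path: str | Path
) -> None:
    """Write per-patient expression maps in the long dialect."""
    path = Path(path)
    sep = _separator(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(LONG_COLUMNS)
        for pid in expression:
            for pe in expression[pid].values():
                writer.writerow(
                    [pid, pe.gene, repr(pe.tumor_intensity), repr(pe.normal_intensity)]
                )


def _parse_pfs(raw: str, *, patient: str) -> tuple[float, bool]:
    """Parse a PFS cell; a trailing ``+`` marks a censored observation."""
    text = str(raw).strip()
    censored = text.endswith("+")
    if censored:
        text = text[:-1].strip()
    try:
        value = float(text)
    except ValueError:
        raise ParseError(f"non-numeric PFS {raw!r} for patient {patient!r}") from None
    return value, censored


def read_clinical_table(path: str | Path) -> dict[str, Cohort]:
    """Parse a clinical CSV into cohorts keyed by drug.

    Required columns: ``patient_id, drug, pfs_months``; an optional
    ``censored`` column (true/false) is OR-ed with a ``+`` suffix on PFS.
    """
    df = _read_table(path)
    required = {"patient_id", "drug", "pfs_months"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"clinical table must contain columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    has_flag = "censored" in df.columns
    cohorts: dict[str, list[PatientRecord]] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        drug = str(row.drug)
        pfs, censored = _parse_pfs(row.pfs_months, patient=pid)
        if has_flag:
            flag = str(row.censored).strip().lower()
            censored = censored or flag in {"1", "true", "yes", "+"}
        cohorts.setdefault(drug, []).append(
            PatientRecord(patient_id=pid, pfs_months=pfs, censored=censored)
        )
    return {drug: Cohort(drug=drug, patients=pats) for drug, pats in cohorts.items()}


def write_clinical_table(cohorts: Iterable[Cohort], path: str | Path) -> None:
    path = Path(path)
    sep = _separator(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["patient_id", "drug", "pfs_months", "censored"])
        for cohort in cohorts:
            for p in cohort.patients:
                writer.writerow(
                    [p.patient_id, cohort.drug, repr(p.pfs_months),
                     "true" if p.censored else "false"]
                )


def attach_expression(
    cohort: Cohort, expression: dict[str, dict[str, PairedExpression]]
) -> Cohort:
    """Join per-patient expression maps onto a cohort's patients, in place."""
    missing = [p.patient_id for p in cohort.patients if p.patient_id not in expression]
    if missing:
        raise ValidationError(
            f"no expression data for patients {missing} of cohort {cohort.drug!r}"
        )
    for p in cohort.patients:
        p.expression = dict(expression[p.patient_id])
    return cohort


def read_panel(path: str | Path) -> GenePanel:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return GenePanel(
            drug=raw["drug"],
            genes=list(raw["genes"]),
            source=raw.get("source", ""),
            aliases=dict(raw.get("aliases", {})),
        )
    except KeyError as exc:
        raise ParseError(f"panel file {path} missing key {exc}") from exc


def write_panel(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(panel), fh, indent=2)
        fh.write("\n")


def read_model(path: str | Path) -> DDPPModel:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return DDPPModel(
            drug=raw["drug"],
            channel=Channel(raw["channel"]),
            feature_mode=FeatureMode(raw["feature_mode"]),
            genes=list(raw["genes"]),
            method=SummationMethod(raw["method"]),
            slope=float(raw["slope"]),
            intercept=float(raw["intercept"]),
            train_r=float(raw["train_r"]),
            train_p=float(raw["train_p"]),
            n_train=int(raw["n_train"]),
        )
    except KeyError as exc:
        raise ParseError(f"model file {path} missing key {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, (Channel, FeatureMode, SummationMethod)):
        return obj.value
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_model(model: DDPPModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(asdict(model)), fh, indent=2)
        fh.write("\n")


def write_report(report: ValidationReport, path: str | Path) -> None:
    payload = {
        "concordance_r": report.concordance_r,
        "concordance_p": report.concordance_p,
        "rmse": report.rmse,
        "mae": report.mae,
        "rmse_insample": report.rmse_insample,
        "mae_insample": report.mae_insample,
        "n_degenerate": report.n_degenerate,
        "folds": [
            {
                "left_out": f.left_out_id,
                "predicted_pfs": f.predicted_pfs,
                "observed_pfs": f.observed_pfs,
                "degenerate": f.degenerate,
                "model": None if f.model is None else _jsonable(asdict(f.model)),
            }
            for f in report.folds
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(payload), fh, indent=2)
        fh.write("\n")


def write_fold_table(report: ValidationReport, path: str | Path) -> None:
    """Per-fold CSV: left_out,predicted,observed,channel,K,method,slope,intercept."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["left_out", "predicted", "observed", "channel", "K", "method",
             "slope", "intercept"]
        )
        for f in report.folds:
            m = f.model
            writer.writerow(
                [
                    f.left_out_id,
                    "" if f.predicted_pfs is None else repr(f.predicted_pfs),
                    repr(f.observed_pfs),
                    "" if m is None else m.channel.value,
                    "" if m is None else len(m.genes),
                    "" if m is None else m.method.value,
                    "" if m is None else repr(m.slope),
                    "" if m is None else repr(m.intercept),
                ]
            )


def write_null_scan(result: NullScanResult, path: str | Path) -> None:
    payload = {
        "panel_size": result.panel_size,
        "iterations": result.iterations,
        "seed": result.seed,
        "method": result.method.value,
        "threshold": {"min_abs_r": result.min_abs_r, "max_p": result.max_p},
        "n_significant": result.n_significant,
        "n_degenerate": result.n_degenerate,
        "proportion": result.proportion_significant,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
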