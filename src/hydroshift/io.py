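"""Readers and writers for the pipeline's text formats.

Beta and detection-p matrices are TSV with a probe_id first column and one
column per sample; missing values are written as ``NA``. The sample sheet
and probe manifest are CSV; chromatin states are BED4 (0-based half-open).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ParseError,
    SampleRecord,
    check_beta_matrix,
    check_chrom_states,
    check_detection_p,
    check_manifest,
    validate_sheet,
)

_NA = "NA"
_SHEET_COLUMNS = ["sample_id", "group", "sex", "age_years", "pmi_hours", "glial_proportion"]


def _read_matrix(path: str | Path, dialect: str) -> pd.DataFrame:
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ParseError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=[_NA], keep_default_na=False)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.name is None or df.shape[1] == 0:
        raise ParseError(f"{path}: expected a probe_id column plus >= 1 sample column")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from exc
    return df


def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a probes x samples beta matrix; values outside [0, 1] are rejected."""
    return check_beta_matrix(_read_matrix(path, dialect), name=str(path))


def read_detection_p(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a detection p-value matrix (same layout as a beta matrix)."""
    return check_detection_p(_read_matrix(path, dialect), name=str(path))


def write_matrix(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    """Write a matrix in the reader's format; NaN becomes ``NA``."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = df.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(path, sep=sep, na_rep=_NA)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read and validate the sample sheet CSV.

    Required columns: sample_id, group, sex, age_years, pmi_hours,
    glial_proportion. Unknown group/sex labels and out-of-range covariates
    are rejected with the offending sample named.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        missing = set(_SHEET_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    SampleRecord(
                        sample_id=row["sample_id"],
                        group=row["group"],
                        sex=row["sex"],
                        age_years=float(row["age_years"]),
                        pmi_hours=float(row["pmi_hours"]),
                        glial_proportion=float(row["glial_proportion"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return validate_sheet(records)


def write_sample_sheet(records: list[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SHEET_COLUMNS)
        for r in records:
            writer.writerow(
                [r.sample_id, r.group, r.sex, r.age_years, r.pmi_hours, r.glial_proportion]
            )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the probe manifest CSV (probe_id, chrom, pos, gene_symbols, feature, masked)."""
    df = pd.read_csv(path, index_col="probe_id", na_values=[_NA], keep_default_na=False)
    df.index = df.index.astype(str)
    df["gene_symbols"] = df["gene_symbols"].fillna("").astype(str)
    if df["masked"].dtype == object:
        df["masked"] = df["masked"].map(
            {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
        )
    df["masked"] = df["masked"].astype(bool)
    df["pos"] = df["pos"].astype(int)
    return check_manifest(df)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path)


def read_chrom_states(path: str | Path) -> pd.DataFrame:
    """Read a BED4 chromatin-state file (chrom, start, end, state)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": str},
        comment="#",
    )
    return check_chrom_states(df)


def write_chrom_states(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "state"]].to_csv(path, sep="\t", header=False, index=False)
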