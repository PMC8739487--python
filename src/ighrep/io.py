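"""Flat-file I/O: AIRR-dialect rearrangement TSV and the sample manifest."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import REARRANGEMENT_COLUMNS

MANIFEST_COLUMNS = ["fastq1", "fastq2", "subject_id", "sample_id"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def write_rearrangements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_rearrangements(path: str | Path) -> pd.DataFrame:
    """Read an AIRR-dialect rearrangement TSV, validating required columns.

    This is also the pre-annotated entry point of the pipeline, bypassing
    read QC and annotation.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"cdr3": str, "cdr3_aa": str, "sequence": str},
        float_precision="round_trip",
    )
    missing = [c for c in REARRANGEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if not df.empty:
        if df["productive"].dtype == object:
            mapped = df["productive"].map(
                {"True": True, "False": False, "T": True, "F": False}
            )
            if mapped.isna().any():
                bad = df.index[mapped.isna()][0]
                raise FormatError(
                    f"{path}: line {bad + 2}: productive must be True/False"
                )
            df["productive"] = mapped
        else:
            df["productive"] = df["productive"].astype(bool)
        if (df["duplicate_count"] < 1).any():
            bad = df.index[df["duplicate_count"] < 1][0]
            raise FormatError(f"{path}: line {bad + 2}: duplicate_count < 1")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the TSV mapping FASTQ pairs to subject and sample labels."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    return df
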