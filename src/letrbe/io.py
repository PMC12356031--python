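"""CSV schemas, validated readers/writers and record-to-analysis conversion.

Two tabular formats are exchanged:

* clonogenic records - one row per cell line x quality x dose x replicate
  with raw colony counts;
* focus records - one row per cell line x quality x timepoint with the
  population mean 53BP1 focus count and its SEM.

Readers validate the header, types and key uniqueness and report malformed
rows with line numbers. ``clonogenic_to_dose_response`` performs the
standard clonogenic normalisation: per-replicate surviving fraction
relative to that replicate's 0 Gy plating efficiency, then averaged.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .foci import FociTimeCourse
from .survival import DoseResponse

__all__ = [
    "CLONOGENIC_COLUMNS",
    "FOCI_COLUMNS",
    "SchemaError",
    "read_clonogenic_csv",
    "write_clonogenic_csv",
    "read_foci_csv",
    "write_foci_csv",
    "clonogenic_to_dose_response",
    "foci_records_to_timecourse",
]

CLONOGENIC_COLUMNS = (
    "cell_line", "quality", "let", "dose", "replicate",
    "cells_seeded", "colonies", "surface",
)
FOCI_COLUMNS = (
    "cell_line", "quality", "let", "dose", "time", "mean_foci", "sem", "n_cells",
)

_CLONO_NUMERIC = ("let", "dose", "cells_seeded", "colonies")
_FOCI_NUMERIC = ("let", "dose", "time", "mean_foci", "sem", "n_cells")


class SchemaError(ValueError):
    """A CSV file does not conform to the expected schema."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(
                f"{path}: non-numeric value(s) in column {col!r} at line(s) {lines}"
            )
        if coerced.isna().any():
            lines = [int(i) + 2 for i in df.index[coerced.isna()][:5]]
            raise SchemaError(f"{path}: empty value(s) in column {col!r} at line(s) {lines}")
        df[col] = coerced
    return df


def read_clonogenic_csv(path) -> pd.DataFrame:
    """Read and validate a clonogenic record table."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, CLONOGENIC_COLUMNS, path)
    df = _check_numeric(df, _CLONO_NUMERIC + ("replicate",), path)
    df["replicate"] = df["replicate"].astype(int)
    df["cells_seeded"] = df["cells_seeded"].astype(int)
    df["colonies"] = df["colonies"].astype(int)
    if (df["colonies"] > df["cells_seeded"]).any():
        bad = df.index[df["colonies"] > df["cells_seeded"]][0]
        raise SchemaError(f"{path}: colonies exceed cells_seeded at line {int(bad) + 2}")
    if (df["dose"] < 0).any():
        raise SchemaError(f"{path}: negative dose")
    key = ["cell_line", "quality", "dose", "replicate"]
    dups = df.duplicated(subset=key)
    if dups.any():
        raise SchemaError(
            f"{path}: duplicate (cell_line, quality, dose, replicate) key "
            f"at line {int(df.index[dups][0]) + 2}"
        )
    bad_surface = ~df["surface"].isin(["plate", "mylar"])
    if bad_surface.any():
        raise SchemaError(
            f"{path}: surface must be 'plate' or 'mylar' "
            f"(line {int(df.index[bad_surface][0]) + 2})"
        )
    return df[list(CLONOGENIC_COLUMNS)]


def write_clonogenic_csv(df: pd.DataFrame, path) -> None:
    _check_columns(df, CLONOGENIC_COLUMNS, path)
    df[list(CLONOGENIC_COLUMNS)].to_csv(path, index=False)


def read_foci_csv(path) -> pd.DataFrame:
    """Read and validate a focus time-course record table."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, FOCI_COLUMNS, path)
    df = _check_numeric(df, _FOCI_NUMERIC, path)
    if (df["mean_foci"] < 0).any():
        raise SchemaError(f"{path}: negative mean_foci")
    if (df["n_cells"] < 1).any():
        raise SchemaError(f"{path}: n_cells must be >= 1")
    key = ["cell_line", "quality", "time"]
    dups = df.duplicated(subset=key)
    if dups.any():
        raise SchemaError(
            f"{path}: duplicate (cell_line, quality, time) key "
            f"at line {int(df.index[dups][0]) + 2}"
        )
    return df[list(FOCI_COLUMNS)]


def write_foci_csv(df: pd.DataFrame, path) -> None:
    _check_columns(df, FOCI_COLUMNS, path)
    df[list(FOCI_COLUMNS)].to_csv(path, index=False)


def clonogenic_to_dose_response(
    records: pd.DataFrame, dropped_log: list | None = None
) -> DoseResponse:
    """Collapse one cell's clonogenic records into a :class:`DoseResponse`.

    ``records`` must contain a single (cell_line, quality) combination.
    Surviving fraction is computed per replicate relative to that
    replicate's 0 Gy plating efficiency, then averaged across replicates.
    Trailing doses whose pooled colony count is zero carry no survival
    information on a log scale and are dropped; each drop is recorded in
    ``dropped_log`` (and warned about) so no row disappears silently.
    """
    keys = records[["cell_line", "quality"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("records must contain exactly one cell line x quality")
    line, quality = keys.iloc[0]

    pe = {}
    zero = records[records["dose"] == 0]
    if zero.empty:
        raise ValueError(f"{line}/{quality}: no 0 Gy reference records")
    for _, row in zero.iterrows():
        if row["colonies"] == 0:
            raise ValueError(f"{line}/{quality}: zero colonies at 0 Gy")
        pe[row["replicate"]] = row["colonies"] / row["cells_seeded"]

    doses = np.sort(records["dose"].unique())
    sf_mean, sf_err, reps_per_dose, counts_per_dose, kept = [], [], [], [], []
    for dose in doses:
        sub = records[records["dose"] == dose].sort_values("replicate")
        if sub["colonies"].sum() == 0:
            msg = f"{line}/{quality}: dropping dose {dose:g} Gy (no colonies in any replicate)"
            if dropped_log is not None:
                dropped_log.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        sf, counts = [], []
        for _, row in sub.iterrows():
            if row["replicate"] not in pe or row["colonies"] == 0:
                continue
            sf.append(row["colonies"] / row["cells_seeded"] / pe[row["replicate"]])
            counts.append(row["colonies"])
        sf = np.asarray(sf)
        kept.append(dose)
        sf_mean.append(sf.mean())
        sf_err.append(sf.std(ddof=1) / np.sqrt(len(sf)) if len(sf) > 1 else 0.0)
        reps_per_dose.append(sf)
        counts_per_dose.append(np.asarray(counts))

    sf_mean = np.asarray(sf_mean)
    sf_mean[0] = 1.0  # exact by the per-replicate normalisation
    return DoseResponse(
        doses=np.asarray(kept), sf_mean=sf_mean,
        sf_err=np.asarray(sf_err), replicates=reps_per_dose,
        colony_counts=counts_per_dose,
    )


def foci_records_to_timecourse(records: pd.DataFrame) -> FociTimeCourse:
    """Collapse one cell's focus records into a :class:`FociTimeCourse`."""
    keys = records[["cell_line", "quality"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("records must contain exactly one cell line x quality")
    line, quality = keys.iloc[0]
    records = records.sort_values("time")
    return FociTimeCourse(
        times=records["time"].to_numpy(dtype=float),
        mean_foci=records["mean_foci"].to_numpy(dtype=float),
        sem=records["sem"].to_numpy(dtype=float),
        dose=float(records["dose"].iloc[0]),
        quality_label=str(quality),
        cell_line=str(line),
    )
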