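"""Tabular I/O for the dialects exchanged between pipeline stages.

All tables are TSV, UTF-8, LF line endings. Reading is gzip-transparent
(by file extension, via pandas). The differential table follows the
Cuffdiff ``gene_exp.diff`` dialect restricted to the columns the pipeline
consumes; unknown extra columns are ignored on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIFF_COLUMNS = [
    "gene_id",
    "sample_1",
    "sample_2",
    "value_1",
    "value_2",
    "log2_fc",
    "p_value",
    "q_value",
    "status",
]

EXPRESSION_COLUMNS = ["gene_id", "genotype", "timepoint_min", "replicate", "fpkm"]

GENE_CALL_COLUMNS = [
    "gene_id",
    "timepoint_min",
    "responsive",
    "direction",
    "category",
    "mkp1_dependent",
    "mkp1_shift",
    "baseline_genotype_diff",
]

STATUS_VALUES = ("OK", "NOTEST", "LOWDATA")


class TableFormatError(ValueError):
    """Raised for malformed or inconsistent input tables.

    Row numbers in messages are 1-based and count the header as row 1.
    """


@dataclass(frozen=True)
class DiffRecord:
    """One pairwise contrast result for one gene."""

    gene_id: str
    sample_1: str
    sample_2: str
    value_1: float
    value_2: float
    log2_fc: float
    p_value: float
    q_value: float
    status: str = "OK"


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def write_table(df: pd.DataFrame, path) -> None:
    """Write any stage table as TSV (UTF-8, LF)."""
    _write_tsv(df, path)


def read_diff_table(path) -> pd.DataFrame:
    """Read a differential table, validating numeric fields row by row.

    Returns a DataFrame with exactly :data:`DIFF_COLUMNS`. Malformed
    numeric fields and out-of-bounds p/q values are fatal with a 1-based
    row number (header is row 1).
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file") from None
    _require_columns(raw, DIFF_COLUMNS, path)
    if len(raw) == 0:
        raise TableFormatError(f"{path}: no data rows")
    df = raw[DIFF_COLUMNS].copy()
    numeric = ["value_1", "value_2", "log2_fc", "p_value", "q_value"]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip().str.lower() != "nan")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise TableFormatError(f"{path}: row {row}: malformed numeric field {col!r}: {df[col].iloc[row - 2]!r}")
        df[col] = parsed.astype(float)
    for col in ("p_value", "q_value"):
        vals = df[col].to_numpy()
        bad = np.isfinite(vals) & ((vals < 0.0) | (vals > 1.0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2
            raise TableFormatError(f"{path}: row {row}: {col}={vals[row - 2]} outside [0, 1]")
    bad_status = ~df["status"].isin(STATUS_VALUES)
    if bad_status.any():
        row = int(np.flatnonzero(bad_status.to_numpy())[0]) + 2
        raise TableFormatError(f"{path}: row {row}: unknown status {df['status'].iloc[row - 2]!r}")
    # sign consistency of log2_fc with the two means, where both are positive
    v1 = df["value_1"].to_numpy()
    v2 = df["value_2"].to_numpy()
    lfc = df["log2_fc"].to_numpy()
    both_pos = (v1 > 0) & (v2 > 0) & np.isfinite(lfc)
    inconsistent = both_pos & (np.sign(lfc) != 0) & (np.sign(lfc) != np.sign(v2 - v1))
    if inconsistent.any():
        row = int(np.flatnonzero(inconsistent)[0]) + 2
        raise TableFormatError(
            f"{path}: row {row}: log2_fc sign inconsistent with value_1/value_2"
        )
    return df


def write_diff_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, DIFF_COLUMNS, path)
    _write_tsv(df[DIFF_COLUMNS], path)


def iter_diff_records(df: pd.DataFrame) -> Iterator[DiffRecord]:
    """Yield :class:`DiffRecord` objects from a validated differential frame."""
    for row in df.itertuples(index=False):
        yield DiffRecord(
            gene_id=row.gene_id,
            sample_1=row.sample_1,
            sample_2=row.sample_2,
            value_1=float(row.value_1),
            value_2=float(row.value_2),
            log2_fc=float(row.log2_fc),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
            status=row.status,
        )


def diff_frame(records: Iterable[DiffRecord]) -> pd.DataFrame:
    rows = [
        (r.gene_id, r.sample_1, r.sample_2, r.value_1, r.value_2, r.log2_fc, r.p_value, r.q_value, r.status)
        for r in records
    ]
    return pd.DataFrame(rows, columns=DIFF_COLUMNS)


def read_expression_long(path) -> pd.DataFrame:
    """Read a long-format expression table; duplicate sample keys are fatal."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file") from None
    _require_columns(df, EXPRESSION_COLUMNS, path)
    df = df[EXPRESSION_COLUMNS].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    df["genotype"] = df["genotype"].astype(str)
    df["timepoint_min"] = df["timepoint_min"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["fpkm"] = df["fpkm"].astype(float)
    key = ["gene_id", "genotype", "timepoint_min", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise TableFormatError(f"{path}: row {row}: duplicate (gene, genotype, timepoint, replicate)")
    if (df["fpkm"] < 0).any():
        row = int(np.flatnonzero((df["fpkm"] < 0).to_numpy())[0]) + 2
        raise TableFormatError(f"{path}: row {row}: negative expression value")
    return df


def write_expression_long(df: pd.DataFrame, path) -> None:
    _require_columns(df, EXPRESSION_COLUMNS, path)
    _write_tsv(df[EXPRESSION_COLUMNS], path)


def read_annotation_map(path) -> pd.DataFrame:
    """Read a two-column gene->term map; duplicated pairs are dropped with a warning.

    The number of dropped duplicates is recorded in ``df.attrs['n_duplicates']``.
    An empty map (header only, or empty file) yields an empty frame.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return _empty_annotation_frame()
    if len(df.columns) < 2:
        raise TableFormatError(f"{path}: annotation map needs two columns (gene_id, term_id)")
    df = df.iloc[:, :2].copy()
    df.columns = ["gene_id", "term_id"]
    n_before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    n_dup = n_before - len(df)
    if n_dup:
        log.warning("%s: dropped %d duplicated gene/term pair(s)", path, n_dup)
    df.attrs["n_duplicates"] = n_dup
    return df


def _empty_annotation_frame() -> pd.DataFrame:
    df = pd.DataFrame({"gene_id": pd.Series(dtype=str), "term_id": pd.Series(dtype=str)})
    df.attrs["n_duplicates"] = 0
    return df


def write_annotation_map(df: pd.DataFrame, path) -> None:
    _require_columns(df, ["gene_id", "term_id"], path)
    _write_tsv(df[["gene_id", "term_id"]], path)


def write_gene_calls(df: pd.DataFrame, path) -> None:
    _require_columns(df, GENE_CALL_COLUMNS, path)
    _write_tsv(df[GENE_CALL_COLUMNS], path)


def read_gene_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, GENE_CALL_COLUMNS, path)
    df["gene_id"] = df["gene_id"].astype(str)
    return df[GENE_CALL_COLUMNS]


def read_qpcr_curves(path) -> pd.DataFrame:
    """Read amplification curves: reaction_id, cycle, fluorescence."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["reaction_id", "cycle", "fluorescence"], path)
    df["reaction_id"] = df["reaction_id"].astype(str)
    df["cycle"] = df["cycle"].astype(int)
    df["fluorescence"] = df["fluorescence"].astype(float)
    return df


def write_qpcr_curves(df: pd.DataFrame, path) -> None:
    _require_columns(df, ["reaction_id", "cycle", "fluorescence"], path)
    _write_tsv(df[["reaction_id", "cycle", "fluorescence"]], path)


def condition_label(genotype: str, timepoint_min: int) -> str:
    """Encode a sample condition as ``<genotype>_<minutes>``."""
    return f"{genotype}_{int(timepoint_min)}"


def split_condition_label(label: str) -> tuple[str, int]:
    genotype, _, minutes = label.rpartition("_")
    if not genotype:
        raise TableFormatError(f"malformed condition label {label!r} (expected <genotype>_<minutes>)")
    try:
        t = int(minutes)
    except ValueError:
        raise TableFormatError(f"malformed condition label {label!r} (expected <genotype>_<minutes>)") from None
    return genotype, t


def is_finite_prob(x: float) -> bool:
    return math.isfinite(x) and 0.0 <= x <= 1.0
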