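"""Readers and writers for the standard files the pipeline touches.

Supported formats: Bismark cytosine reports (7-column
``coverage2cytosine`` layout, with a 6-column coverage dialect), BED3/BED6
feature annotations, TSV expression-count tables and per-cell QC tables.
Genomes are read through :mod:`pyfaidx`.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .types import FEATURE_COLUMNS, SITE_COLUMNS, VALID_STRANDS, sites_frame


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path, dialect: str = "report") -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a sites frame.

    Parameters
    ----------
    path
        Tab-separated file with columns chrom, 1-based position, strand,
        methylated count, unmethylated count, context, trinucleotide.
    dialect
        ``"report"`` expects the 7-column coverage2cytosine layout;
        ``"coverage"`` tolerates the 6-column coverage layout (no
        trinucleotide; the context column is kept, trinucleotide left
        empty for downstream genome-based classification).

    Zero-coverage lines are retained: in NOMe data an uncovered site is
    missing information, not closed chromatin, and downstream operations
    filter on total count explicitly.
    """
    if dialect not in ("report", "coverage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncol = 7 if dialect == "report" else 6
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return sites_frame()

    if raw.shape[1] != ncol:
        raise ParseError(
            f"{path}: expected {ncol} tab-separated columns, found {raw.shape[1]}"
        )
    raw.columns = SITE_COLUMNS[:ncol]

    def _bad_line(mask: np.ndarray, what: str) -> None:
        line = int(np.flatnonzero(mask)[0]) + 1
        raise ParseError(f"{path}: line {line}: {what}")

    ragged = raw.isna().any(axis=1)
    if ragged.any():
        _bad_line(ragged.to_numpy(), f"wrong number of columns (expected {ncol})")

    for col in ("pos", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            _bad_line(bad.to_numpy(), f"non-integer value in column {col!r}")
        raw[col] = vals.astype(np.int64)
    bad = ~raw["strand"].isin(VALID_STRANDS)
    if bad.any():
        _bad_line(bad.to_numpy(), "unknown strand symbol")
    bad = (raw["pos"] < 1) | (raw["n_meth"] < 0) | (raw["n_unmeth"] < 0)
    if bad.any():
        _bad_line(bad.to_numpy(), "negative count or non-positive position")

    if dialect == "coverage":
        raw["trinucleotide"] = ""
    return raw[SITE_COLUMNS].copy()


def write_cytosine_report(sites: pd.DataFrame, path) -> None:
    """Write a sites frame as a 7-column cytosine report.

    Records are sorted by (chrom, pos, strand) on output regardless of
    input order, so the round trip through :func:`read_cytosine_report`
    is an identity on the sorted table.
    """
    cols = [c for c in SITE_COLUMNS if c in sites.columns]
    missing = set(SITE_COLUMNS) - set(cols)
    if missing:
        raise ValueError(f"sites frame missing columns: {sorted(missing)}")
    out = sites[SITE_COLUMNS].sort_values(
        ["chrom", "pos", "strand"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Features (BED)
# ---------------------------------------------------------------------------

def read_features_bed(
    path,
    context_class: str = "feature",
    gene_ids: bool = False,
) -> pd.DataFrame:
    """Read a BED3+ file into a 1-based inclusive feature frame.

    BED is 0-based half-open; internally start becomes ``start + 1`` and
    end is unchanged, an exact bijection.  Column 4 (name), if present,
    becomes ``feature_id``; otherwise ids ``feat_1..feat_k`` are
    assigned.  Column 6 is the strand.  With ``gene_ids=True`` the name
    column is also used as the associated gene id.

    Records with ``start >= end`` are rejected with a single warning
    reporting the reject count.  Unsorted input is accepted.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    if raw.shape[1] < 3:
        raise ParseError(f"{path}: BED needs at least 3 columns")

    start = pd.to_numeric(raw[1], errors="coerce")
    end = pd.to_numeric(raw[2], errors="coerce")
    if start.isna().any() or end.isna().any():
        line = int((start.isna() | end.isna()).to_numpy().argmax()) + 1
        raise ParseError(f"{path}: line {line}: non-numeric BED coordinate")

    bad = (start >= end) | (start < 0)
    if bad.any():
        warnings.warn(
            f"{path}: rejected {int(bad.sum())} BED records with start >= end",
            stacklevel=2,
        )
    keep = raw.loc[~bad].reset_index(drop=True)
    start = start[~bad.to_numpy()].reset_index(drop=True)
    end = end[~bad.to_numpy()].reset_index(drop=True)

    n = len(keep)
    feat = pd.DataFrame(
        {
            "chrom": keep[0].astype(str),
            "start": start.astype(np.int64) + 1,
            "end": end.astype(np.int64),
            "strand": keep[5].astype(str) if keep.shape[1] >= 6 else "+",
            "feature_id": (
                keep[3].astype(str)
                if keep.shape[1] >= 4
                else [f"feat_{i + 1}" for i in range(n)]
            ),
            "context_class": context_class,
        }
    )
    feat.loc[~feat["strand"].isin(VALID_STRANDS), "strand"] = "+"
    feat["gene_id"] = feat["feature_id"] if gene_ids else None
    return feat[FEATURE_COLUMNS]


def write_features_bed(features: pd.DataFrame, path) -> None:
    """Write a feature frame back to BED6 (0-based half-open)."""
    out = pd.DataFrame(
        {
            0: features["chrom"],
            1: features["start"].astype(np.int64) - 1,
            2: features["end"].astype(np.int64),
            3: features["feature_id"],
            4: 0,
            5: features["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Expression counts and QC tables
# ---------------------------------------------------------------------------

def read_expression_counts(path) -> pd.DataFrame:
    """Read a genes x cells TSV of non-negative integer counts.

    The header row carries cell ids, the first column gene ids.
    Duplicate gene or cell ids, ragged rows and negative or non-integer
    entries are format errors.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated gene id {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated cell id {dup!r}")
    arr = counts.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{path}: non-numeric entries in count table")
    if np.isnan(arr.astype(float)).any():
        raise ParseError(f"{path}: missing entries (ragged rows?) in count table")
    if (arr < 0).any():
        raise ParseError(f"{path}: negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ParseError(f"{path}: non-integer counts")
    counts = counts.astype(np.int64)
    counts.index = counts.index.astype(str)
    counts.index.name = "gene_id"
    return counts


def write_expression_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_qc_table(path) -> pd.DataFrame:
    """Read a per-cell QC statistics TSV indexed by cell_id."""
    qc = pd.read_csv(path, sep="\t", index_col=0)
    qc.index = qc.index.astype(str)
    qc.index.name = "cell_id"
    return qc


def write_qc_table(qc: pd.DataFrame, path) -> None:
    qc.to_csv(path, sep="\t", index_label="cell_id")


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    """Write {name: sequence} to FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    """Read a FASTA into {name: uppercase sequence} via pyfaidx."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Validation (CLI support)
# ---------------------------------------------------------------------------

def validate_file(path) -> Tuple[str, str]:
    """Best-effort format diagnosis of ``path``.

    Returns ``(format, message)`` where format is one of
    ``cytosine_report``, ``coverage``, ``bed``, ``counts``, ``fasta`` or
    ``unknown``.
    """
    path = str(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith(">"):
        return "fasta", "FASTA sequence file"
    for dialect, name in (("report", "cytosine_report"), ("coverage", "coverage")):
        try:
            df = read_cytosine_report(path, dialect=dialect)
            return name, f"{len(df)} site records"
        except (ParseError, ValueError):
            pass
    try:
        feat = read_features_bed(path)
        return "bed", f"{len(feat)} features"
    except (ParseError, ValueError):
        pass
    try:
        counts = read_expression_counts(path)
        return "counts", f"{counts.shape[0]} genes x {counts.shape[1]} cells"
    except (ParseError, ValueError):
        pass
    return "unknown", "no known format matched"
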