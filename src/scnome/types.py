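"""Shared record types and tabular conventions.

Bulk data travels as :class:`pandas.DataFrame` objects with the column
layouts declared here; the dataclasses are the per-record views used at
API boundaries and in round-trip tests.

Coordinate convention: 1-based, inclusive on both ends, matching Bismark
cytosine reports.  BED input/output is converted at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Column order of a cytosine-report table (Bismark coverage2cytosine layout).
SITE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]

#: Column order of a genomic-feature table.
FEATURE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "feature_id",
    "context_class",
    "gene_id",
]

#: Column order of a per-feature rate table.
RATE_COLUMNS = ["cell_id", "feature_id", "rate", "se", "n_sites", "layer"]

VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class SiteCall:
    """One cytosine observation in one cell.

    ``pos`` is the 1-based position of the cytosine on its own strand's
    coordinate (reported in plus-strand coordinates, as Bismark does).
    ``trinucleotide`` is read 5'->3' on the cytosine's strand, so its
    middle letter is always C.
    """

    chrom: str
    pos: int
    strand: str
    trinucleotide: str
    n_meth: int
    n_unmeth: int
    context: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if len(self.trinucleotide) == 3 and self.trinucleotide[1] not in "CN":
            raise ValueError(
                f"trinucleotide middle letter must be C, got {self.trinucleotide!r}"
            )

    @property
    def n_total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def covered(self) -> bool:
        return self.n_total > 0


@dataclass(frozen=True)
class GenomicFeature:
    """A genomic interval (1-based, inclusive) with a context label."""

    chrom: str
    start: int
    end: int
    feature_id: str
    context_class: str = "feature"
    strand: str = "+"
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("1-based start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class QCThresholds:
    """Per-layer cell quality thresholds; ``None`` disables a check.

    RNA layer: ``min_mapped_reads``, ``max_mito_frac``, ``min_genes``.
    Bisulfite layer: ``min_mapping_efficiency``, ``min_cpg_sites``,
    ``min_gpc_sites``.
    """

    min_mapped_reads: Optional[float] = None
    max_mito_frac: Optional[float] = None
    min_genes: Optional[float] = None
    min_mapping_efficiency: Optional[float] = None
    min_cpg_sites: Optional[float] = None
    min_gpc_sites: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "min_mapped_reads",
            "max_mito_frac",
            "min_genes",
            "min_mapping_efficiency",
            "min_cpg_sites",
            "min_gpc_sites",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


# QC presets for serum-grown ES cells and embryoid-body cells.  The EB
# preset relaxes the read-depth cutoffs for shallower sequencing and does
# not threshold GpC coverage.
QC_PRESETS = {
    "es": QCThresholds(
        min_mapped_reads=300_000,
        max_mito_frac=0.15,
        min_genes=2000,
        min_mapping_efficiency=0.10,
        min_cpg_sites=500_000,
        min_gpc_sites=5_000_000,
    ),
    "eb": QCThresholds(
        min_mapped_reads=100_000,
        max_mito_frac=0.15,
        min_genes=2000,
        min_mapping_efficiency=0.10,
        min_cpg_sites=300_000,
        min_gpc_sites=None,
    ),
}


@dataclass
class RateMatrix:
    """Features x cells rate container for one molecular layer.

    Three aligned frames: posterior-mean ``rates`` in [0, 1], their
    standard errors and the per-entry covered-site counts.  ``NaN``
    encodes a genuinely missing entry (no covered site); ``n_sites`` is
    the coverage weight the correlation scans use.
    """

    rates: pd.DataFrame
    se: pd.DataFrame
    n_sites: pd.DataFrame
    layer: str = "met"

    def __post_init__(self) -> None:
        for other in (self.se, self.n_sites):
            if not (
                other.index.equals(self.rates.index)
                and other.columns.equals(self.rates.columns)
            ):
                raise ValueError("rates/se/n_sites frames must be aligned")
        obs = self.rates.notna()
        if not (self.n_sites.where(obs).fillna(1) >= 1).all().all():
            raise ValueError("observed entries must have n_sites >= 1")

    @property
    def features(self) -> pd.Index:
        return self.rates.index

    @property
    def cells(self) -> pd.Index:
        return self.rates.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where a rate was observed."""
        return self.rates.notna()

    def to_long(self) -> pd.DataFrame:
        long = (
            self.rates.stack().rename("rate").reset_index()
        )
        long.columns = ["feature_id", "cell_id", "rate"]
        long["se"] = self.se.stack().to_numpy()
        long["n_sites"] = self.n_sites.stack().to_numpy()
        long["layer"] = self.layer
        return long[RATE_COLUMNS]


def sites_frame(records=None) -> pd.DataFrame:
    """Build an empty or populated cytosine-report frame."""
    if not records:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "n_meth": pd.Series(dtype=np.int64),
                "n_unmeth": pd.Series(dtype=np.int64),
                "context": pd.Series(dtype=str),
                "trinucleotide": pd.Series(dtype=str),
            }
        )
    rows = [
        (r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context, r.trinucleotide)
        for r in records
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)
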