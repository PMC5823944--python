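"""NOMe trinucleotide context classification.

In NOMe data the exogenous GpC methyltransferase writes the accessibility
signal while endogenous methylation lives on CpG.  A cytosine whose
trinucleotide (read 5'->3' on its own strand) is G-C-G is intrinsically
ambiguous — it is both a GpC and a CpG — and is discarded from both
channels; C-C-G is discarded from the CpG channel against enzyme
off-target risk.  What survives: A-C-G and T-C-G carry methylation,
G-C-A / G-C-C / G-C-T carry accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

# Context labels.
CG_KEPT = "CG_KEPT"
CG_EXCLUDED_GCG = "CG_EXCLUDED_GCG"
CG_EXCLUDED_CCG = "CG_EXCLUDED_CCG"
GC_KEPT = "GC_KEPT"
NONE = "NONE"

LABELS = (CG_KEPT, CG_EXCLUDED_GCG, CG_EXCLUDED_CCG, GC_KEPT, NONE)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# uint8 base codes for vectorised classification
_A, _C, _G, _T = (ord(b) for b in "ACGT")
_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _c in _COMP.items():
    _COMP_TABLE[ord(_b)] = ord(_c)

# integer label codes used internally (index into LABELS)
_LCODE = {name: i for i, name in enumerate(LABELS)}


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def classify_trinucleotide(tri: str) -> str:
    """Label a 3-mer whose middle base is the cytosine under test."""
    tri = tri.upper()
    if len(tri) != 3 or tri[1] != "C" or any(b not in "ACGT" for b in tri):
        return NONE
    up, _, down = tri
    if down == "G":
        if up == "G":
            return CG_EXCLUDED_GCG
        if up == "C":
            return CG_EXCLUDED_CCG
        return CG_KEPT
    if up == "G":
        return GC_KEPT
    return NONE


def _classify_codes(up: np.ndarray, down: np.ndarray) -> np.ndarray:
    """Vectorised label codes for cytosines given flanking base codes."""
    out = np.full(up.shape, _LCODE[NONE], dtype=np.int8)
    valid = np.isin(up, (_A, _C, _G, _T)) & np.isin(down, (_A, _C, _G, _T))
    cg = valid & (down == _G)
    out[cg & (up == _G)] = _LCODE[CG_EXCLUDED_GCG]
    out[cg & (up == _C)] = _LCODE[CG_EXCLUDED_CCG]
    out[cg & ((up == _A) | (up == _T))] = _LCODE[CG_KEPT]
    out[valid & ~cg & (up == _G)] = _LCODE[GC_KEPT]
    return out


def _genome_arrays(genome: Dict[str, str]) -> Dict[str, np.ndarray]:
    return {
        chrom: np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        for chrom, seq in genome.items()
    }


def classify_cytosine(genome: Dict[str, str], chrom: str, pos: int, strand: str) -> str:
    """Context label of the cytosine at 1-based ``pos`` on ``strand``.

    The base at the position must actually be a cytosine on the given
    strand (C on plus, G on plus-strand sequence for minus).  Edge
    cytosines, lacking an upstream or downstream base, are ``NONE``.
    """
    seq = genome[chrom].upper()
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside {chrom} (length {len(seq)})")
    base = seq[pos - 1]
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {base}, not C")
        if pos == 1 or pos == len(seq):
            return NONE
        return classify_trinucleotide(seq[pos - 2 : pos + 1])
    if strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {_COMP.get(base, 'N')}, not C")
        if pos == 1 or pos == len(seq):
            return NONE
        return classify_trinucleotide(revcomp(seq[pos - 2 : pos + 1]))
    raise ValueError(f"strand must be + or -, got {strand!r}")


def classify_sites(sites: pd.DataFrame, genome: Dict[str, str]) -> pd.Series:
    """Vectorised context labels for every row of a sites frame."""
    labels = np.full(len(sites), _LCODE[NONE], dtype=np.int8)
    arrays = _genome_arrays(genome)
    pos0 = sites["pos"].to_numpy(dtype=np.int64) - 1
    strand = sites["strand"].to_numpy()
    for chrom, arr in arrays.items():
        in_chrom = (sites["chrom"] == chrom).to_numpy()
        if not in_chrom.any():
            continue
        p = pos0[in_chrom]
        if (p < 0).any() or (p >= arr.size).any():
            bad = p[(p < 0) | (p >= arr.size)][0] + 1
            raise ValueError(f"position {bad} outside {chrom}")
        s = strand[in_chrom]
        interior = (p > 0) & (p < arr.size - 1)
        here = arr[p]
        plus = s == "+"
        bad_base = (plus & (here != _C)) | (~plus & (here != _G))
        if bad_base.any():
            badp = p[bad_base][0] + 1
            raise ValueError(f"no cytosine at {chrom}:{badp} on stated strand")
        sub = np.full(p.shape, _LCODE[NONE], dtype=np.int8)
        pi = interior & plus
        sub[pi] = _classify_codes(arr[p[pi] - 1], arr[p[pi] + 1])
        mi = interior & ~plus
        sub[mi] = _classify_codes(
            _COMP_TABLE[arr[p[mi] + 1]], _COMP_TABLE[arr[p[mi] - 1]]
        )
        labels[in_chrom] = sub
    return pd.Series([LABELS[c] for c in labels], index=sites.index, name="label")


def partition_report(
    sites: pd.DataFrame,
    genome: Dict[str, str],
    on_mismatch: str = "warn",
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Split a cytosine report into CpG and GpC channels.

    Returns ``(cpg_sites, gpc_sites, census)`` where the census maps each
    excluded/kept label to its count in the input.  The genome sequence
    is authoritative: a stored trinucleotide disagreeing with the
    genome-derived one triggers a warning (``on_mismatch="warn"``) or an
    error (``"error"``); ``"trust"`` skips the genome lookup entirely and
    classifies the stored trinucleotide.
    """
    if on_mismatch not in ("warn", "error", "trust"):
        raise ValueError(f"unknown on_mismatch policy {on_mismatch!r}")
    if len(sites) == 0:
        empty = sites.copy()
        return empty, empty.copy(), {lab: 0 for lab in LABELS}

    if on_mismatch == "trust":
        labels = sites["trinucleotide"].map(classify_trinucleotide)
        labels.name = "label"
    else:
        labels = classify_sites(sites, genome)
        stored = sites["trinucleotide"].astype(str).str.upper()
        has_stored = stored.str.len() == 3
        if has_stored.any():
            derived = labels[has_stored]
            stored_lab = stored[has_stored].map(classify_trinucleotide)
            mism = derived != stored_lab
            if mism.any():
                msg = (
                    f"{int(mism.sum())} stored trinucleotides disagree with the "
                    "genome; genome-derived context used"
                )
                if on_mismatch == "error":
                    raise ValueError(msg)
                import warnings

                warnings.warn(msg, stacklevel=2)

    census = {lab: int((labels == lab).sum()) for lab in LABELS}
    cpg = sites.loc[labels == CG_KEPT].copy()
    gpc = sites.loc[labels == GC_KEPT].copy()
    return cpg, gpc, census


@dataclass
class ContextCensus:
    """Exhaustive per-strand context counts for a genome.

    ``counts[(label, strand)]`` counts cytosines; ``n_cpg_dinucleotides``
    and ``n_gpc_dinucleotides`` count plus-strand dinucleotide
    occurrences (each CpG contributes one cytosine per strand).
    ``mean_gpc_spacing`` is the mean distance in bp between consecutive
    GpC dinucleotide start positions, per chromosome.
    """

    counts: Dict[Tuple[str, str], int]
    n_cytosines: int
    n_cpg_dinucleotides: int
    n_gpc_dinucleotides: int
    mean_gpc_spacing: Dict[str, float]
    n_with_n: int = 0

    @property
    def n_cpg_cytosines(self) -> int:
        """CpG-context cytosines over both strands (kept or excluded)."""
        return sum(
            self.counts[(lab, s)]
            for lab in (CG_KEPT, CG_EXCLUDED_GCG, CG_EXCLUDED_CCG)
            for s in "+-"
        )

    def fraction_of_cpg(self, label: str) -> float:
        """Share of CpG-context cytosines carrying ``label``."""
        tot = self.n_cpg_cytosines
        if tot == 0:
            return float("nan")
        return (self.counts[(label, "+")] + self.counts[(label, "-")]) / tot

    def to_dict(self) -> dict:
        return {
            "counts": {f"{lab}:{s}": v for (lab, s), v in self.counts.items()},
            "n_cytosines": self.n_cytosines,
            "n_cpg_dinucleotides": self.n_cpg_dinucleotides,
            "n_gpc_dinucleotides": self.n_gpc_dinucleotides,
            "mean_gpc_spacing": self.mean_gpc_spacing,
            "n_with_n": self.n_with_n,
        }


def context_census(genome: Dict[str, str]) -> ContextCensus:
    """Scan both strands of a genome and tabulate context labels."""
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    counts = {(lab, s): 0 for lab in LABELS for s in "+-"}
    n_cyt = 0
    n_cpg = 0
    n_gpc = 0
    n_with_n = 0
    spacing: Dict[str, float] = {}
    for chrom, arr in _genome_arrays(genome).items():
        if arr.size == 0:
            continue
        # plus strand cytosines
        isC = arr == _C
        isG = arr == _G
        n_cyt += int(isC.sum() + isG.sum())  # G on plus = C on minus
        interior = np.zeros(arr.size, dtype=bool)
        interior[1:-1] = True

        pc = isC & interior
        codes = _classify_codes(arr[np.flatnonzero(pc) - 1], arr[np.flatnonzero(pc) + 1])
        for i, lab in enumerate(LABELS):
            counts[(lab, "+")] += int((codes == i).sum())
        counts[(NONE, "+")] += int((isC & ~interior).sum())

        mc = isG & interior  # minus-strand cytosines
        idx = np.flatnonzero(mc)
        codes = _classify_codes(_COMP_TABLE[arr[idx + 1]], _COMP_TABLE[arr[idx - 1]])
        for i, lab in enumerate(LABELS):
            counts[(lab, "-")] += int((codes == i).sum())
        counts[(NONE, "-")] += int((isG & ~interior).sum())

        nmask = ~np.isin(arr, (_A, _C, _G, _T))
        n_with_n += int(
            nmask.sum()
        )  # positions with N themselves (flank Ns already fall into NONE)

        # dinucleotide totals and GpC spacing on the plus strand
        di_cg = isC[:-1] & isG[1:]
        di_gc = isG[:-1] & isC[1:]
        n_cpg += int(di_cg.sum())
        n_gpc += int(di_gc.sum())
        gpc_pos = np.flatnonzero(di_gc)
        if gpc_pos.size >= 2:
            spacing[chrom] = float(np.diff(gpc_pos).mean())
        else:
            spacing[chrom] = float("nan")
    return ContextCensus(
        counts=counts,
        n_cytosines=n_cyt,
        n_cpg_dinucleotides=n_cpg,
        n_gpc_dinucleotides=n_gpc,
        mean_gpc_spacing=spacing,
        n_with_n=n_with_n,
    )
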