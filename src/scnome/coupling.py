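"""Weighted-correlation machinery and the two association scans.

Two complementary designs probe coupling between molecular layers:

* across genes, one test per cell — each cell contributes a single
  weighted Pearson correlation computed over all qualifying loci of one
  genomic context (a quality-control-style global summary);
* across cells, one test per locus — each locus contributes a weighted
  Pearson correlation over the cells covering it, yielding a genome-wide
  scan for loci with coordinated heterogeneity, Benjamini–Hochberg
  adjusted within each context.

Weights are sequencing coverage (covered-site counts) of the epigenetic
layer; whenever methylation participates, CpG coverage is the weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import RateMatrix

RECORD_COLUMNS = [
    "unit_id", "layer_pair", "context_class", "r", "t", "p", "q", "n", "mean_weight",
]


def weighted_pearson(x, y, w=None) -> float:
    """Weighted Pearson correlation of ``x`` and ``y``.

    Weights (all positive) are normalised to sum to n, so the equal-weight
    case reduces exactly to the textbook Pearson correlation.  Returns
    NaN when either vector has zero weighted variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if w is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match x in length")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    w = w * (x.size / w.sum())
    mx = np.sum(w * x) / x.size
    my = np.sum(w * y) / x.size
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def pearson_t_test(r: float, n: int) -> Tuple[float, float]:
    """Two-tailed t-test for a nonzero Pearson correlation.

    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom; |r| = 1
    gives an infinite t and p = 0.  Degrees of freedom use the unweighted
    observation count, which keeps p-values conservative when weights
    concentrate on few observations.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"invalid correlation {r}")
    if abs(r) == 1.0:
        return float("inf") if r > 0 else float("-inf"), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(min(p, 1.0))


def bh_adjust(pvalues, groups=None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, optionally within groups.

    NaN p-values are excluded from the adjustment and returned as NaN.
    ``groups``, when given, partitions the tests (e.g. by genomic
    context) and the adjustment is applied separately per group.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    if groups is None:
        groups = np.zeros(p.shape, dtype=int)
    else:
        groups = np.asarray(groups)
        if groups.shape != p.shape:
            raise ValueError("groups must match pvalues in length")
    for g in pd.unique(groups):
        sel = (groups == g) & np.isfinite(p)
        if not sel.any():
            continue
        if (p[sel] < 0).any() or (p[sel] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return q


@dataclass
class ScanParams:
    """Filters and thresholds shared by the association scans."""

    min_sites: int = 3          # covered sites per feature per cell
    min_cells: int = 20         # jointly observed cells per locus test
    min_loci: int = 10          # qualifying loci per cell test
    top_variable_frac: float = 0.5   # per-context variance filter on loci
    expression_variance_filter: bool = True  # drop genes below median variance
    fdr: float = 0.1
    gene_window: int = 10_000   # bp for feature-gene association (upstream use)


def _apply_min_sites(layer: RateMatrix, min_sites: int) -> pd.DataFrame:
    """Rates with entries under the coverage floor masked to NaN."""
    return layer.rates.where(layer.n_sites >= min_sites)


def _variance_filter(rates: pd.DataFrame, frac: float) -> pd.Index:
    """Indices of the top ``frac`` most variable rows (ties kept)."""
    v = rates.var(axis=1, skipna=True)
    v = v[v.notna() & (v > 0)]
    if v.empty or frac >= 1.0:
        return rates.index
    cutoff = v.quantile(1.0 - frac)
    return v.index[v >= cutoff]


def _prepare_b(
    layer_b,
    features: pd.DataFrame,
    params: ScanParams,
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame], pd.Series, bool]:
    """Resolve layer B to a per-feature value frame.

    Returns ``(values, n_sites_or_None, feature->unit map, is_expression)``.
    An expression matrix (genes x cells of log-normalised values) is
    mapped onto features through their ``gene_id``; features without an
    associated gene are dropped.
    """
    if isinstance(layer_b, RateMatrix):
        return _apply_min_sites(layer_b, params.min_sites), layer_b.n_sites, None, False
    expr = layer_b
    fmap = features.set_index("feature_id")["gene_id"]
    fmap = fmap[fmap.notna() & fmap.isin(expr.index)]
    if params.expression_variance_filter and expr.shape[0] >= 4:
        v = expr.var(axis=1)
        keep_genes = v.index[v >= v.median()]
        fmap = fmap[fmap.isin(keep_genes)]
    vals = expr.loc[fmap.to_numpy()]
    vals.index = fmap.index
    return vals, None, fmap, True


def across_cells_scan(
    layer_a: RateMatrix,
    layer_b,
    features: pd.DataFrame,
    params: Optional[ScanParams] = None,
    layer_pair: Optional[str] = None,
) -> pd.DataFrame:
    """One weighted association test per locus, across cells.

    ``layer_a`` is the epigenetic layer whose coverage provides the
    weights (CpG methylation coverage whenever methylation participates).
    ``layer_b`` is a second :class:`RateMatrix` on the same features or a
    log-normalised expression matrix (genes x cells); expression is
    matched to features through ``features.gene_id``.

    Filters: entries need >= ``min_sites`` covered sites; a locus needs
    >= ``min_cells`` jointly observed cells; only the top
    ``top_variable_frac`` most variable loci per context (by layer-A rate
    variance, ties kept) are tested; for expression, genes below the
    median variance are removed first.  p-values are BH-adjusted within
    each context; ``significant`` marks q < fdr.
    """
    params = params or ScanParams()
    if layer_pair is None:
        layer_pair = f"{layer_a.layer}-" + (
            layer_b.layer if isinstance(layer_b, RateMatrix) else "expr"
        )
    a_vals = _apply_min_sites(layer_a, params.min_sites)
    b_vals, b_sites, _, _ = _prepare_b(layer_b, features, params)
    common_cells = a_vals.columns.intersection(b_vals.columns)
    if len(common_cells) == 0:
        raise ValueError("layers share no cells")
    a_vals = a_vals[common_cells]
    b_vals = b_vals[common_cells]
    ctx = features.set_index("feature_id")["context_class"]

    rows = []
    for context in ctx.unique():
        fids = ctx.index[ctx == context]
        fids = fids.intersection(a_vals.index).intersection(b_vals.index)
        if len(fids) == 0:
            continue
        keep = _variance_filter(a_vals.loc[fids], params.top_variable_frac)
        for fid in fids.intersection(keep):
            x = a_vals.loc[fid]
            y = b_vals.loc[fid]
            obs = x.notna() & y.notna()
            if b_sites is not None:
                obs &= b_sites.loc[fid, common_cells].notna()
            n = int(obs.sum())
            if n < params.min_cells:
                continue
            w = layer_a.n_sites.loc[fid, common_cells][obs].to_numpy(dtype=float)
            r = weighted_pearson(x[obs].to_numpy(), y[obs].to_numpy(), w)
            if not np.isfinite(r):
                continue
            t, p = pearson_t_test(r, n)
            rows.append((fid, layer_pair, context, r, t, p, np.nan, n, w.mean()))
    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if out.empty:
        warnings.warn("no locus passed the scan filters", stacklevel=2)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = bh_adjust(out["p"].to_numpy(), out["context_class"].to_numpy())
    out["significant"] = out["q"] < params.fdr
    return out


def across_genes_scan(
    layer_a: RateMatrix,
    layer_b,
    features: pd.DataFrame,
    params: Optional[ScanParams] = None,
    layer_pair: Optional[str] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One weighted association test per cell, across loci.

    For each cell and context, correlates the two layers over all loci
    the cell covers in both (>= ``min_sites`` sites each, >= ``min_loci``
    loci).  Also returns the pseudo-bulk correlation per context,
    computed with :func:`weighted_pearson` on the cell-averaged locus
    values with cell-summed coverage weights.

    Returns ``(per_cell_records, pseudobulk_records)``.
    """
    params = params or ScanParams()
    if layer_pair is None:
        layer_pair = f"{layer_a.layer}-" + (
            layer_b.layer if isinstance(layer_b, RateMatrix) else "expr"
        )
    a_vals = _apply_min_sites(layer_a, params.min_sites)
    b_vals, b_sites, _, _ = _prepare_b(layer_b, features, params)
    common_cells = a_vals.columns.intersection(b_vals.columns)
    if len(common_cells) == 0:
        raise ValueError("layers share no cells")
    a_vals = a_vals[common_cells]
    b_vals = b_vals[common_cells]
    ctx = features.set_index("feature_id")["context_class"]

    per_cell = []
    bulk = []
    for context in ctx.unique():
        fids = ctx.index[ctx == context]
        fids = fids.intersection(a_vals.index).intersection(b_vals.index)
        if len(fids) == 0:
            continue
        A = a_vals.loc[fids]
        B = b_vals.loc[fids]
        W = layer_a.n_sites.loc[fids, common_cells]
        if b_sites is not None:
            B = B.where(b_sites.loc[fids, common_cells].notna())
        for cell in common_cells:
            obs = A[cell].notna() & B[cell].notna()
            n = int(obs.sum())
            if n < max(params.min_loci, 3):
                continue
            w = W.loc[obs, cell].to_numpy(dtype=float)
            r = weighted_pearson(
                A.loc[obs, cell].to_numpy(), B.loc[obs, cell].to_numpy(), w
            )
            if not np.isfinite(r):
                continue
            t, p = pearson_t_test(r, n)
            per_cell.append((cell, layer_pair, context, r, t, p, np.nan, n, w.mean()))
        # pseudo-bulk: cell-averaged values per locus
        am = A.mean(axis=1, skipna=True)
        bm = B.mean(axis=1, skipna=True)
        wsum = W.sum(axis=1, skipna=True)
        obs = am.notna() & bm.notna() & (wsum > 0)
        if int(obs.sum()) >= 3:
            r = weighted_pearson(
                am[obs].to_numpy(), bm[obs].to_numpy(), wsum[obs].to_numpy()
            )
            if np.isfinite(r):
                t, p = pearson_t_test(r, int(obs.sum()))
                bulk.append(
                    ("pseudobulk", layer_pair, context, r, t, p, np.nan,
                     int(obs.sum()), float(wsum[obs].mean()))
                )
    cells_df = pd.DataFrame(per_cell, columns=RECORD_COLUMNS)
    if not cells_df.empty:
        cells_df["q"] = bh_adjust(
            cells_df["p"].to_numpy(), cells_df["context_class"].to_numpy()
        )
    bulk_df = pd.DataFrame(bulk, columns=RECORD_COLUMNS)
    return cells_df, bulk_df
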