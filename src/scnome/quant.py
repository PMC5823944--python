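"""Per-site and per-feature methylation/accessibility rates, QC and
expression normalisation.

Site rates follow a binomial model for the reads supporting methylation
at one cytosine in one cell, with a beta prior: the point estimate is the
posterior mode (MAP) and its uncertainty the posterior standard
deviation.  Feature rates combine the sites overlapping a genomic
interval by inverse-variance weighting, so noisier sites count less.
Across cells a feature's rate is summarised under a normal model with a
method-of-moments between-cell variance component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .types import QCThresholds, QC_PRESETS, RateMatrix


# ---------------------------------------------------------------------------
# Beta prior estimation
# ---------------------------------------------------------------------------

def estimate_prior(sites: pd.DataFrame, method: str = "mom") -> Tuple[float, float]:
    """Estimate beta prior hyperparameters from raw site proportions.

    ``method="mom"`` fits a beta by moments to the latent per-site rates,
    subtracting the binomial sampling variance from the spread of the raw
    proportions (so read depth does not inflate the prior variance).
    ``method="flat"`` returns the uniform prior (1, 1).  Estimates are
    clipped to >= 1 so the posterior mode stays interior.

    Degenerate inputs — no latent spread, or maximal spread as with
    all-0/1 proportions — fall back to (1, 1) with a warning.
    """
    if method == "flat":
        return 1.0, 1.0
    if method != "mom":
        raise ValueError(f"unknown prior method {method!r}")
    n = (sites["n_meth"] + sites["n_unmeth"]).to_numpy(dtype=float)
    keep = n >= 1
    if keep.sum() < 10:
        raise ValueError("need at least 10 covered sites to estimate a prior")
    n = n[keep]
    p = sites["n_meth"].to_numpy(dtype=float)[keep] / n

    m = p.mean()
    # unbiased estimate of E[r(1-r)]: E[p(1-p)] = (1 - 1/n) E[r(1-r)]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(n > 1, p * (1 - p) * n / (n - 1), np.nan)
    u = np.nanmean(u) if np.isfinite(u).any() else np.nan
    if not np.isfinite(u):
        u = float(np.mean(p * (1 - p)))
    var_latent = m - u - m * m
    denom = m * (1 - m)
    if not (0 < var_latent < denom):
        warnings.warn(
            "degenerate site proportions; falling back to flat Beta(1,1) prior",
            stacklevel=2,
        )
        return 1.0, 1.0
    c = denom / var_latent - 1.0
    alpha = max(1.0, m * c)
    beta = max(1.0, (1 - m) * c)
    return float(alpha), float(beta)


# ---------------------------------------------------------------------------
# Site rates
# ---------------------------------------------------------------------------

def site_rate(n_meth, n_total, alpha: float = 1.0, beta: float = 1.0):
    """MAP rate and posterior sd for one or many sites.

    rate = (m + a - 1) / (n + a + b - 2), clipped to [0, 1];
    se = sd of the posterior Beta(m + a, n - m + b).
    Sites with ``n_total == 0`` yield NaN (missing), not an error.
    Accepts scalars or arrays; returns ``(rate, se)`` of matching shape.
    """
    if alpha < 1 or beta < 1:
        raise ValueError("alpha and beta must be >= 1")
    m = np.asarray(n_meth, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if (m < 0).any() or (m > n).any():
        raise ValueError("need 0 <= n_meth <= n_total")
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n + alpha + beta - 2.0
        rate = np.where(denom > 0, (m + alpha - 1.0) / np.maximum(denom, 1e-300), 0.5)
        rate = np.clip(rate, 0.0, 1.0)
        a = m + alpha
        b = n - m + beta
        se = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
    rate = np.where(n >= 1, rate, np.nan)
    se = np.where(n >= 1, se, np.nan)
    if np.isscalar(n_meth) and np.isscalar(n_total):
        return float(rate), float(se)
    return rate, se


# ---------------------------------------------------------------------------
# Feature-level aggregation
# ---------------------------------------------------------------------------

def feature_rate(rates, ses) -> Tuple[float, float, int]:
    """Inverse-variance weighted mean of the site rates in one feature.

    Returns ``(rate, se, n_sites)`` with ``se = sqrt(1 / sum(1/se_i^2))``.
    """
    r = np.asarray(rates, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(r) & np.isfinite(s) & (s > 0)
    r, s = r[ok], s[ok]
    if r.size == 0:
        return float("nan"), float("nan"), 0
    w = 1.0 / s**2
    return float(np.sum(w * r) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w))), int(r.size)


def _assign_sites_to_features(
    sites: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Long overlap table (feature_id x site row index).

    1-based inclusive intervals on both sides; boundary positions are
    inside.  Sites match features on chrom only (both strands of a
    feature's span contribute).
    """
    out = []
    for chrom, fgrp in features.groupby("chrom", sort=False):
        sub = sites[sites["chrom"] == chrom]
        if sub.empty:
            continue
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        pos = sub["pos"].to_numpy()[order]
        idx = sub.index.to_numpy()[order]
        lo = np.searchsorted(pos, fgrp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, fgrp["end"].to_numpy(), side="right")
        for fid, a, b in zip(fgrp["feature_id"], lo, hi):
            if b > a:
                out.append(pd.DataFrame({"feature_id": fid, "site_index": idx[a:b]}))
    if not out:
        return pd.DataFrame(columns=["feature_id", "site_index"])
    return pd.concat(out, ignore_index=True)


def rate_matrix(
    sites_by_cell: Mapping[str, pd.DataFrame],
    features: pd.DataFrame,
    prior: str = "mom",
    min_sites: int = 1,
    layer: str = "met",
) -> RateMatrix:
    """Build the features x cells :class:`RateMatrix` for one layer.

    For each cell, a beta prior is estimated from that cell's covered
    sites (``prior="mom"``; ``"flat"`` for Beta(1,1)), site MAP rates are
    computed, and every feature with at least ``min_sites`` covered sites
    receives the inverse-variance weighted rate.  Entries without
    coverage are NaN.
    """
    cells = list(sites_by_cell)
    feature_ids = features["feature_id"].tolist()
    rates = pd.DataFrame(np.nan, index=feature_ids, columns=cells)
    ses = pd.DataFrame(np.nan, index=feature_ids, columns=cells)
    nsites = pd.DataFrame(np.nan, index=feature_ids, columns=cells)

    for cell, sites in sites_by_cell.items():
        total = sites["n_meth"] + sites["n_unmeth"]
        cov = sites.loc[total > 0]
        if cov.empty:
            continue
        if prior == "flat":
            a, b = 1.0, 1.0
        else:
            try:
                a, b = estimate_prior(cov, method=prior)
            except ValueError:
                a, b = 1.0, 1.0
        r, s = site_rate(
            cov["n_meth"].to_numpy(), total[cov.index].to_numpy(), a, b
        )
        cov = cov.assign(_rate=r, _se=s)
        overlap = _assign_sites_to_features(cov, features)
        if overlap.empty:
            continue
        merged = overlap.merge(
            cov[["_rate", "_se"]], left_on="site_index", right_index=True
        )
        w = 1.0 / merged["_se"] ** 2
        grp = merged.assign(_w=w, _wr=w * merged["_rate"]).groupby("feature_id")
        agg = grp.agg(wsum=("_w", "sum"), wrsum=("_wr", "sum"), n=("_rate", "size"))
        agg = agg[agg["n"] >= min_sites]
        rates.loc[agg.index, cell] = agg["wrsum"] / agg["wsum"]
        ses.loc[agg.index, cell] = np.sqrt(1.0 / agg["wsum"])
        nsites.loc[agg.index, cell] = agg["n"].astype(float)

    return RateMatrix(rates=rates, se=ses, n_sites=nsites, layer=layer)


def aggregate_across_cells(rates, ses) -> Tuple[float, float, int]:
    """Summarise one feature across cells under a normal model.

    Method-of-moments (DerSimonian–Laird) between-cell variance tau^2 is
    added to each cell's squared standard error; the mean is the
    precision-weighted mean with weights 1/(se^2 + tau^2).  Returns
    ``(mean, between_cell_sd, n_cells)``; with fewer than two cells the
    sd is NaN.
    """
    r = np.asarray(rates, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(r) & np.isfinite(s) & (s > 0)
    r, s = r[ok], s[ok]
    k = r.size
    if k == 0:
        return float("nan"), float("nan"), 0
    if k == 1:
        return float(r[0]), float("nan"), 1
    w = 1.0 / s**2
    mu_fe = np.sum(w * r) / np.sum(w)
    q = np.sum(w * (r - mu_fe) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w2 = 1.0 / (s**2 + tau2)
    mu = np.sum(w2 * r) / np.sum(w2)
    return float(mu), float(np.sqrt(tau2)), int(k)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

#: QC statistic column expected per active threshold.
_QC_FIELDS = {
    "min_mapped_reads": ("mapped_reads", "rna", "low_mapped_reads", False),
    "max_mito_frac": ("mito_frac", "rna", "high_mito_fraction", True),
    "min_genes": ("n_genes", "rna", "few_genes_expressed", False),
    "min_mapping_efficiency": ("mapping_efficiency", "bs", "low_mapping_efficiency", False),
    "min_cpg_sites": ("cpg_sites", "bs", "few_cpg_sites", False),
    "min_gpc_sites": ("gpc_sites", "bs", "few_gpc_sites", False),
}


def qc_filter(
    cell_records: pd.DataFrame,
    thresholds: QCThresholds | str,
) -> pd.DataFrame:
    """Apply per-layer QC thresholds to a per-cell statistics table.

    ``thresholds`` may be a :class:`QCThresholds` or a preset name
    (``"es"``/``"eb"``).  Returns a frame indexed like the input with
    boolean ``pass_rna``, ``pass_bs``, ``pass`` columns and a
    semicolon-joined ``fail_reasons`` string; attaches the per-reason
    failure counts as ``result.attrs["failure_counts"]``.
    """
    if isinstance(thresholds, str):
        thresholds = QC_PRESETS[thresholds]
    reasons = {c: [] for c in cell_records.index}
    pass_layer = {"rna": pd.Series(True, index=cell_records.index),
                  "bs": pd.Series(True, index=cell_records.index)}
    counts: Dict[str, int] = {}
    for name, (col, layer, reason, is_max) in _QC_FIELDS.items():
        thr = getattr(thresholds, name)
        if thr is None:
            continue
        if col not in cell_records.columns:
            raise ValueError(f"QC table lacks column {col!r} needed by {name}")
        vals = cell_records[col]
        if vals.isna().any():
            cell = vals.index[vals.isna()][0]
            raise ValueError(f"cell {cell!r}: missing QC statistic {col!r}")
        fail = vals > thr if is_max else vals < thr
        counts[reason] = int(fail.sum())
        pass_layer[layer] &= ~fail
        for cell in cell_records.index[fail]:
            reasons[cell].append(reason)
    out = pd.DataFrame(
        {
            "pass_rna": pass_layer["rna"],
            "pass_bs": pass_layer["bs"],
            "pass": pass_layer["rna"] & pass_layer["bs"],
            "fail_reasons": [";".join(reasons[c]) for c in cell_records.index],
        },
        index=cell_records.index,
    )
    out.attrs["failure_counts"] = counts
    return out


# ---------------------------------------------------------------------------
# Expression normalisation
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per cell, library-size fallback.

    The reference is the geometric mean expression of genes detected in
    every cell; cells without enough reference genes (sparse cells) fall
    back to a library-size factor.  Factors are rescaled to mean 1.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        dead = counts.columns[arr.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero cells: {dead}")
    universal = (arr > 0).all(axis=1)
    factors = np.full(arr.shape[1], np.nan)
    if universal.sum() >= 10:
        logref = np.log(arr[universal]).mean(axis=1)
        ratios = np.log(arr[universal]) - logref[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    bad = ~np.isfinite(factors) | (factors <= 0)
    if bad.any():
        lib = arr.sum(axis=0)
        factors[bad] = lib[bad] / lib.mean()
    factors = factors / factors.mean()
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor adjust and log2(x+1)-transform a count matrix."""
    sf = size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)
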