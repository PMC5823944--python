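"""Pseudotemporal ordering and along-trajectory epigenome dynamics.

Cells are ordered from the transcriptome alone: the most biologically
overdispersed genes feed a diffusion map, and pseudotime is the rank of
each cell along the first nontrivial diffusion component, oriented by a
marker gene of known direction.  Two trajectory analyses then couple the
epigenome to the ordering: a permutation test for coordinated change of
accessibility profiles with pseudotime, and the trend of per-cell
methylation–accessibility coupling along pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .coupling import bh_adjust, pearson_t_test, weighted_pearson


def overdispersed_genes(log_counts: pd.DataFrame, n_top: int = 500) -> pd.Index:
    """Genes ranked by variance in excess of the mean–variance trend.

    A rolling median of variance against mean expression estimates the
    technical trend; genes are ranked by their positive residual from it
    and the top ``n_top`` returned.  Constant genes are never selected.
    """
    mean = log_counts.mean(axis=1)
    var = log_counts.var(axis=1)
    informative = var > 0
    if informative.sum() == 0:
        raise ValueError("no gene with nonzero variance")
    m = mean[informative]
    v = var[informative]
    order = m.sort_values(kind="mergesort").index
    window = max(5, min(101, len(order) // 10 | 1))
    trend = v[order].rolling(window, center=True, min_periods=1).median()
    resid = (v[order] - trend).sort_values(ascending=False, kind="mergesort")
    if n_top > len(resid):
        import warnings

        warnings.warn(
            f"only {len(resid)} informative genes for n_top={n_top}", stacklevel=2
        )
        n_top = len(resid)
    return resid.index[:n_top]


@dataclass
class PseudotimeResult:
    """Per-cell pseudotime in [0, 1] with diffusion-component scores."""

    tau: pd.Series
    components: pd.DataFrame
    eigenvalues: np.ndarray
    genes: list
    marker: Optional[str] = None
    flipped: bool = False


def diffusion_pseudotime(
    log_counts: pd.DataFrame,
    marker: Optional[str] = None,
    orientation: str = "decreasing",
    n_components: int = 10,
    k_bandwidth: int = 5,
) -> PseudotimeResult:
    """Diffusion-map pseudotime from a genes x cells expression matrix.

    A Gaussian kernel on cell–cell Euclidean distances, with bandwidth
    set to the median distance to each cell's ``k_bandwidth``-th
    neighbour, is symmetrically normalised and eigendecomposed;
    pseudotime is the min–max-scaled rank of each cell along the first
    nontrivial diffusion component.  ``marker`` names a gene whose
    expression is expected to fall (``orientation="decreasing"``) or
    rise along pseudotime; the ordering is reversed to honour it.
    """
    if log_counts.shape[1] < 10:
        raise ValueError("need at least 10 cells")
    if orientation not in ("decreasing", "increasing"):
        raise ValueError(f"orientation must be de/increasing, got {orientation!r}")
    X = log_counts.T.to_numpy(dtype=float)  # cells x genes
    cells = log_counts.columns
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    d = np.sqrt(d2)
    kth = np.sort(d, axis=1)[:, min(k_bandwidth, d.shape[0] - 1)]
    sigma = float(np.median(kth))
    if sigma <= 0:
        sigma = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
    K = np.exp(-d2 / (2.0 * sigma**2))

    n_comp_graph, _ = connected_components(K > np.exp(-18.0), directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            "kernel graph is disconnected; increase the bandwidth (k_bandwidth)"
        )
    deg = K.sum(axis=1)
    A = K / np.sqrt(np.outer(deg, deg))
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # map back to the random-walk eigenvectors
    phi = evecs / np.sqrt(deg)[:, None]
    ncomp = min(n_components, len(cells) - 1)
    comps = pd.DataFrame(
        phi[:, 1 : ncomp + 1],
        index=cells,
        columns=[f"DC{i + 1}" for i in range(ncomp)],
    )
    dc1 = comps["DC1"]
    ranks = dc1.rank(method="average") - 1.0
    tau = ranks / ranks.max() if ranks.max() > 0 else ranks
    flipped = False
    if marker is not None:
        if marker not in log_counts.index:
            raise ValueError(f"marker gene {marker!r} not in the matrix")
        corr = np.corrcoef(log_counts.loc[marker].to_numpy(), tau.to_numpy())[0, 1]
        want_negative = orientation == "decreasing"
        if np.isfinite(corr) and ((corr > 0) == want_negative):
            tau = 1.0 - tau
            flipped = True
    tau.name = "tau"
    return PseudotimeResult(
        tau=tau,
        components=comps,
        eigenvalues=evals[1 : ncomp + 1],
        genes=list(log_counts.index),
        marker=marker,
        flipped=flipped,
    )


def profile_trajectory_association(
    profile_weights: Mapping[str, pd.DataFrame],
    tau: pd.Series,
    n_perm: int = 1000,
    min_cells: int = 20,
    seed: int = 0,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Test each gene's accessibility profile for change along pseudotime.

    For one gene, the fitted per-cell basis-weight vectors are projected
    onto their first principal axis; the statistic is the Spearman
    correlation of that projection with pseudotime, with a two-sided
    permutation p-value (``n_perm`` permutations of tau; ``n_perm=0``
    returns statistics without p-values) and BH adjustment across genes.
    """
    from sklearn.decomposition import PCA

    rng = np.random.default_rng(seed)
    rows = []
    for gene, W in profile_weights.items():
        cells = W.index.intersection(tau.index)
        if len(cells) < min_cells:
            continue
        X = W.loc[cells].to_numpy(dtype=float)
        if np.allclose(X.var(axis=0), 0):
            continue
        proj = PCA(n_components=1, random_state=0).fit_transform(X)[:, 0]
        if np.std(proj) == 0:
            continue
        t = tau[cells].to_numpy(dtype=float)
        rp = stats.rankdata(proj)
        rt = stats.rankdata(t)
        rp_c = rp - rp.mean()
        rt_c = rt - rt.mean()
        denom = np.sqrt(np.sum(rp_c**2) * np.sum(rt_c**2))
        if denom == 0:
            continue
        rho = float(np.sum(rp_c * rt_c) / denom)
        if n_perm > 0:
            perms = rng.permuted(np.tile(rt_c, (n_perm, 1)), axis=1)
            rho_perm = perms @ rp_c / denom
            p = (1.0 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (1.0 + n_perm)
            p = float(min(p, 1.0))
        else:
            p = np.nan
        rows.append((gene, float(rho), p, len(cells)))
    out = pd.DataFrame(rows, columns=["gene_id", "statistic", "p", "n"])
    if not out.empty and n_perm > 0:
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
    return out


def coupling_vs_pseudotime(
    per_cell_correlations: pd.DataFrame,
    tau: pd.Series,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Trend of per-cell layer coupling along pseudotime, per context.

    ``per_cell_correlations`` is the per-cell output of the across-genes
    scan (columns ``unit_id``, ``context_class``, ``r``).  For each
    context the statistic is the Pearson correlation of the per-cell r
    with pseudotime (two-tailed t-test); a negative statistic means the
    coupling grows more negative — i.e. stronger methylation–
    accessibility anticoupling — as pseudotime advances.  Contexts with
    fewer than ``min_cells`` cells carrying both quantities are skipped.
    """
    rows = []
    for context, grp in per_cell_correlations.groupby("context_class", sort=False):
        sub = grp.set_index("unit_id")["r"]
        cells = sub.index.intersection(tau.index)
        if len(cells) < min_cells:
            continue
        r = weighted_pearson(sub[cells].to_numpy(), tau[cells].to_numpy())
        if not np.isfinite(r):
            continue
        t, p = pearson_t_test(r, len(cells))
        rows.append((context, float(r), t, p, len(cells)))
    out = pd.DataFrame(rows, columns=["context_class", "statistic", "t", "p", "n"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
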