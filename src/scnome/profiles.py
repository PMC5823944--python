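"""Accessibility profiles: pseudo-bulk windows and single-cell models.

Rate parameters in fixed windows wash out nucleosome structure: a GpC
landscape oscillating between linkers and nucleosome footprints can
average to the same number as a flat one.  The single-cell model here
fits, per cell and TSS window, a smooth accessibility curve — a
generalised linear model with radial basis functions and a Bernoulli
likelihood under a probit link — and clusters the per-cell curves with
an EM finite mixture, choosing the number of clusters by BIC.  The
chosen K is a per-gene measure of cell-to-cell chromatin heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .coupling import bh_adjust

# ---------------------------------------------------------------------------
# Pseudo-bulk running-window profiles
# ---------------------------------------------------------------------------

@dataclass
class PseudobulkProfile:
    """Running-window layer profile averaged across cells."""

    starts: np.ndarray          # window start offsets within the region
    mean: np.ndarray            # across-cell mean of per-cell window means
    sd: np.ndarray              # across-cell sd
    n_cells: np.ndarray
    window: int
    step: int

    @property
    def centers(self) -> np.ndarray:
        return self.starts + (self.window - 1) / 2.0


def pseudobulk_profile(
    site_rates: Mapping[str, pd.DataFrame],
    region_length: int,
    window: int = 50,
    step: int = 25,
) -> PseudobulkProfile:
    """Running average of site rates in sliding windows, across cells.

    ``site_rates`` maps cell id to a frame with ``pos`` (1-based offset
    within the region) and ``rate`` columns.  Per cell, each window's
    value is the plain mean of the covered sites it contains; across
    cells, mean and sd are computed over the cells with any coverage in
    the window (windows no cell covers are NaN).
    """
    if window > region_length:
        raise ValueError("window exceeds region length")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    n_windows = (region_length - window) // step + 1
    starts = np.arange(n_windows) * step + 1
    per_cell = np.full((len(site_rates), n_windows), np.nan)
    for i, (cell, df) in enumerate(site_rates.items()):
        if df.empty:
            continue
        order = np.argsort(df["pos"].to_numpy(), kind="mergesort")
        pos = df["pos"].to_numpy()[order]
        rate = df["rate"].to_numpy(dtype=float)[order]
        csum = np.concatenate([[0.0], np.cumsum(rate)])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window - 1, side="right")
        cnt = hi - lo
        with np.errstate(invalid="ignore"):
            vals = (csum[hi] - csum[lo]) / cnt
        per_cell[i] = np.where(cnt > 0, vals, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(per_cell, axis=0)
        sd = np.nanstd(per_cell, axis=0, ddof=0)
    n_cells = np.sum(~np.isnan(per_cell), axis=0)
    sd[n_cells == 0] = np.nan
    return PseudobulkProfile(
        starts=starts, mean=mean, sd=sd, n_cells=n_cells, window=window, step=step
    )


def peak_spacing(profile: PseudobulkProfile, min_prominence: float = 0.05) -> float:
    """Median distance in bp between adjacent local maxima of the mean."""
    from scipy.signal import find_peaks

    y = profile.mean
    ok = np.isfinite(y)
    peaks, _ = find_peaks(y[ok], prominence=min_prominence)
    if peaks.size < 2:
        return float("nan")
    centers = profile.centers[ok][peaks]
    return float(np.median(np.diff(centers)))


# ---------------------------------------------------------------------------
# Expression stratification and gene selection
# ---------------------------------------------------------------------------

def stratify_genes_by_expression(mean_log_counts: pd.Series) -> pd.Series:
    """Three-way Low / Medium / High split of mean log2 expression.

    Low: x < 2; Medium: 2 <= x <= 6; High: x > 6 (boundaries fall in
    Medium, consistent with strict inequalities on both outer classes).
    """
    x = mean_log_counts
    out = pd.Series("Medium", index=x.index, name="expression_class")
    out[x < 2] = "Low"
    out[x > 6] = "High"
    return out


def select_profiled_genes(
    site_counts: pd.DataFrame,
    min_cell_frac: float = 0.4,
    min_sites: int = 10,
) -> pd.Index:
    """Genes with enough GpC coverage for profile fitting.

    ``site_counts`` is genes x cells, giving covered GpC sites in each
    gene's TSS window.  A gene is kept iff at least ``min_cell_frac`` of
    the cells (inclusive) have at least ``min_sites`` sites (inclusive).
    """
    enough = (site_counts.fillna(0) >= min_sites).mean(axis=1)
    kept = site_counts.index[enough >= min_cell_frac]
    if len(kept) == 0:
        warnings.warn("no gene passes the profiling coverage filter", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# Bernoulli basis-function (probit) profile regression
# ---------------------------------------------------------------------------

@dataclass
class BasisSet:
    """Radial basis functions on the scaled window [-1, 1], plus intercept."""

    M: int = 9
    gamma_scale: float = 1.0
    link: str = "probit"

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("need at least one basis function")
        self.centers = np.linspace(-1.0, 1.0, self.M)
        spacing = 2.0 / (self.M - 1) if self.M > 1 else 2.0
        self.gamma = spacing * self.gamma_scale

    def design(self, x: np.ndarray) -> np.ndarray:
        """Design matrix [1, rbf_1(x), ..., rbf_M(x)]."""
        x = np.asarray(x, dtype=float)
        H = np.empty((x.size, self.M + 1))
        H[:, 0] = 1.0
        H[:, 1:] = np.exp(
            -0.5 * ((x[:, None] - self.centers[None, :]) / self.gamma) ** 2
        )
        return H

    def mean(self, eta: np.ndarray) -> np.ndarray:
        if self.link == "probit":
            return special.ndtr(eta)
        return special.expit(eta)


@dataclass
class ProfileFit:
    """Fitted basis weights for one cell x one TSS window."""

    weights: np.ndarray
    loglik: float
    n_sites: int
    converged: bool
    cell_id: str = ""
    gene_id: str = ""

    def predict(self, x: np.ndarray, basis: BasisSet) -> np.ndarray:
        return basis.mean(basis.design(x) @ self.weights)


_LOG_NORM_CONST = -0.5 * np.log(2.0 * np.pi)


def _bernoulli_negll(w, H, m, n, penalty, link):
    eta = H @ w
    if link == "probit":
        log_p = special.log_ndtr(eta)
        log_q = special.log_ndtr(-eta)
        log_phi = _LOG_NORM_CONST - 0.5 * eta * eta
        # d/deta log Phi(eta) = phi/Phi
        d_p = np.exp(log_phi - log_p)
        d_q = -np.exp(log_phi - log_q)
    else:
        log_p = -np.logaddexp(0.0, -eta)
        log_q = -np.logaddexp(0.0, eta)
        p = special.expit(eta)
        d_p = 1.0 - p
        d_q = -p
    ll = np.sum(m * log_p + (n - m) * log_q)
    grad = H.T @ (m * d_p + (n - m) * d_q)
    pen = np.zeros_like(w)
    pen[1:] = penalty * w[1:]
    return -(ll - 0.5 * penalty * np.sum(w[1:] ** 2)), -(grad - pen)


def _fit_bernoulli_newton(H, m, n, penalty, link, max_iter=50, tol=1e-10):
    """Damped Newton ascent of the penalised Bernoulli objective.

    The objective is concave under both links, so Newton with step
    halving converges quickly; returns None on breakdown so the caller
    can fall back to L-BFGS.
    """
    P = H.shape[1]
    w = np.zeros(P)
    pen_diag = np.full(P, penalty)
    pen_diag[0] = 0.0
    f, g = _bernoulli_negll(w, H, m, n, penalty, link)
    for _ in range(max_iter):
        eta = H @ w
        if link == "probit":
            log_p = special.log_ndtr(eta)
            log_q = special.log_ndtr(-eta)
            log_phi = _LOG_NORM_CONST - 0.5 * eta * eta
            u = np.exp(log_phi - log_p)
            v = np.exp(log_phi - log_q)
            d2 = -m * (eta * u + u * u) + (n - m) * (eta * v - v * v)
        else:
            p = special.expit(eta)
            d2 = -n * p * (1.0 - p)
        Hess = (H * (-d2)[:, None]).T @ H + np.diag(pen_diag)
        try:
            step = np.linalg.solve(Hess, -g)
        except np.linalg.LinAlgError:
            return None
        alpha = 1.0
        for _ in range(30):
            w_new = w + alpha * step
            f_new, g_new = _bernoulli_negll(w_new, H, m, n, penalty, link)
            if np.isfinite(f_new) and f_new <= f:
                break
            alpha *= 0.5
        else:
            return None
        done = f - f_new <= tol * max(1.0, abs(f))
        w, f, g = w_new, f_new, g_new
        if done:
            return w
    return w


def fit_bpr_profile(
    positions: np.ndarray,
    n_meth: np.ndarray,
    n_total: np.ndarray,
    basis: Optional[BasisSet] = None,
    penalty: float = 0.01,
    weights: Optional[np.ndarray] = None,
    cell_id: str = "",
    gene_id: str = "",
) -> ProfileFit:
    """Penalised Bernoulli basis-function regression for one window.

    ``positions`` are site coordinates scaled to [-1, 1]; ``n_meth`` of
    ``n_total`` reads at each site support the methylated (accessible)
    state.  The objective — Bernoulli log-likelihood under the basis
    expansion with an L2 penalty on the non-intercept weights — is
    concave, so the fit is deterministic from the zero start.
    ``weights`` optionally scales each observation's likelihood
    contribution (used by the mixture's M-step).
    """
    basis = basis or BasisSet()
    x = np.asarray(positions, dtype=float)
    m = np.asarray(n_meth, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        m = m * weights
        n = n * weights
    H = basis.design(x)
    w = _fit_bernoulli_newton(H, m, n, penalty, basis.link)
    converged = w is not None
    if w is None:
        res = optimize.minimize(
            _bernoulli_negll,
            np.zeros(H.shape[1]),
            args=(H, m, n, penalty, basis.link),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        w = res.x
        converged = bool(res.success)
    ll = -_bernoulli_negll(w, H, m, n, 0.0, basis.link)[0]
    return ProfileFit(
        weights=w,
        loglik=float(ll),
        n_sites=int(x.size),
        converged=converged,
        cell_id=cell_id,
        gene_id=gene_id,
    )


# ---------------------------------------------------------------------------
# EM mixture clustering of per-cell profiles
# ---------------------------------------------------------------------------

@dataclass
class MixtureResult:
    """BIC-selected finite mixture of accessibility profiles at one gene."""

    gene_id: str
    k: int
    bic: Dict[int, float]
    assignments: np.ndarray          # cluster index per cell (fitted order)
    cluster_weights: np.ndarray      # k x (M+1) profile weight vectors
    mixing: np.ndarray
    loglik: float
    cell_ids: List[str] = field(default_factory=list)


def _cell_loglik(cluster_w: np.ndarray, Hs, ms, ns, link: str) -> np.ndarray:
    """Log-likelihood of each cell's data under each cluster profile."""
    K = cluster_w.shape[0]
    out = np.empty((len(Hs), K))
    for i, (H, m, n) in enumerate(zip(Hs, ms, ns)):
        eta = H @ cluster_w.T          # sites x K
        if link == "probit":
            log_p = special.log_ndtr(eta)
            log_q = special.log_ndtr(-eta)
        else:
            log_p = -np.logaddexp(0.0, -eta)
            log_q = -np.logaddexp(0.0, eta)
        out[i] = m @ log_p + (n - m) @ log_q
    return out


def cluster_profiles(
    cell_data: Sequence[Tuple[np.ndarray, np.ndarray, np.ndarray]],
    k_candidates: Sequence[int] = (1, 2, 3, 4, 5, 6),
    basis: Optional[BasisSet] = None,
    penalty: float = 0.01,
    init_penalty: float = 1.0,
    n_restarts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    gene_id: str = "",
    cell_ids: Optional[List[str]] = None,
) -> MixtureResult:
    """EM mixture of basis-function profiles over the cells of one gene.

    ``cell_data`` holds per cell ``(positions, n_meth, n_total)`` with
    positions scaled to [-1, 1].  Each candidate K is fitted with
    ``n_restarts`` k-means-initialised EM runs (restart 0 uses the
    pooled/k-means solution, later restarts perturb); each cell's
    likelihood is the Bernoulli likelihood of its own observed sites, so
    deeply covered cells carry proportionally more information.  K is
    chosen to minimise BIC = -2 logL + p log(N_cells); ties prefer the
    smaller K.

    ``init_penalty`` shrinks the per-cell fits that feed the k-means
    initialisation; single-cell windows hold few sites per parameter, so
    unshrunk per-cell weights are noise-dominated and seed EM into poor
    local optima.  The mixture M-step itself uses ``penalty``.
    """
    if len(cell_data) < 2:
        raise ValueError("need at least 2 fitted cells to cluster")
    basis = basis or BasisSet()
    rng = np.random.default_rng(seed)
    Hs = [basis.design(np.asarray(x, dtype=float)) for x, _, _ in cell_data]
    ms = [np.asarray(m, dtype=float) for _, m, _ in cell_data]
    ns = [np.asarray(n, dtype=float) for _, _, n in cell_data]
    N = len(cell_data)
    P = basis.M + 1

    # individual per-cell fits drive the k-means initialisation
    solo = np.stack(
        [
            fit_bpr_profile(x, m, n, basis=basis, penalty=init_penalty).weights
            for (x, m, n) in cell_data
        ]
    )

    H_all = np.concatenate(Hs)

    def _m_step(resp: np.ndarray) -> np.ndarray:
        W = np.empty((resp.shape[1], P))
        for k in range(resp.shape[1]):
            r = resp[:, k]
            mk = np.concatenate([m * r[i] for i, m in enumerate(ms)])
            nk = np.concatenate([n * r[i] for i, n in enumerate(ns)])
            w = _fit_bernoulli_newton(H_all, mk, nk, penalty, basis.link)
            if w is None:
                w = optimize.minimize(
                    _bernoulli_negll,
                    np.zeros(P),
                    args=(H_all, mk, nk, penalty, basis.link),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": 200, "ftol": 1e-12},
                ).x
            W[k] = w
        return W

    def _run_em(K: int, restart: int):
        from sklearn.cluster import KMeans

        if K == 1:
            labels = np.zeros(N, dtype=int)
        else:
            km = KMeans(
                n_clusters=K, n_init=3,
                random_state=int(rng.integers(2**31 - 1)),
            )
            X = solo + (0.0 if restart == 0 else rng.normal(0, 0.3, solo.shape))
            labels = km.fit_predict(X)
        resp = np.zeros((N, K))
        resp[np.arange(N), labels] = 1.0
        if (resp.sum(axis=0) == 0).any():
            return None
        prev = -np.inf
        for _ in range(max_iter):
            W = _m_step(resp)
            pi = resp.sum(axis=0) / N
            if (pi <= 1e-12).any():
                return None
            ll_ik = _cell_loglik(W, Hs, ms, ns, basis.link) + np.log(pi)
            norm = special.logsumexp(ll_ik, axis=1)
            loglik = float(norm.sum())
            resp = np.exp(ll_ik - norm[:, None])
            if abs(loglik - prev) <= tol * max(1.0, abs(prev)):
                break
            prev = loglik
        return loglik, W, pi, resp

    bic: Dict[int, float] = {}
    best: Dict[int, tuple] = {}
    for K in k_candidates:
        if K > N:
            continue
        runs = []
        for restart in range(1 if K == 1 else n_restarts):
            out = _run_em(K, restart)
            if out is not None:
                runs.append(out)
        if not runs:
            continue
        loglik, W, pi, resp = max(runs, key=lambda r: r[0])
        p_free = K * P + (K - 1)
        bic[K] = float(-2.0 * loglik + p_free * np.log(N))
        best[K] = (loglik, W, pi, resp)
    if not bic:
        raise RuntimeError("EM failed for every candidate K")
    k_star = min(sorted(bic), key=lambda k: (round(bic[k], 9), k))
    loglik, W, pi, resp = best[k_star]
    return MixtureResult(
        gene_id=gene_id,
        k=k_star,
        bic=bic,
        assignments=resp.argmax(axis=1),
        cluster_weights=W,
        mixing=pi,
        loglik=loglik,
        cell_ids=list(cell_ids) if cell_ids is not None else [],
    )


def heterogeneity_report(
    mixture_results: Mapping[str, MixtureResult],
    mean_expression: pd.Series,
    promoter_marks: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Summarise expression (and marks) by per-gene cluster count K.

    One row per observed K with the number of genes and the median/mean
    expression of genes at that heterogeneity level; with a
    ``promoter_marks`` annotation (gene -> mark class, e.g. bivalent),
    per-class proportions are appended.
    """
    ks = pd.Series({g: res.k for g, res in mixture_results.items()}, name="k")
    genes = ks.index.intersection(mean_expression.index)
    df = pd.DataFrame({"k": ks[genes], "expression": mean_expression[genes]})
    rows = []
    for k, grp in df.groupby("k"):
        row = {
            "k": int(k),
            "n_genes": len(grp),
            "median_expression": float(grp["expression"].median()),
            "mean_expression": float(grp["expression"].mean()),
        }
        if promoter_marks is not None:
            marks = promoter_marks.reindex(grp.index).dropna()
            for cls in promoter_marks.dropna().unique():
                row[f"frac_{cls}"] = (
                    float((marks == cls).mean()) if len(marks) else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("k").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression prediction: rates vs profiles
# ---------------------------------------------------------------------------

def predict_expression(
    features_by_cell: Mapping[str, pd.DataFrame],
    expression: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell linear regression of expression on accessibility features.

    ``features_by_cell`` maps each cell to a genes x p frame — a single
    rate column in rate mode, or fitted basis weights in profile mode.
    For each cell, genes are the observations: expression is regressed
    on the features, and accuracy is reported as the cross-validated
    Pearson r between observed and predicted expression plus the
    in-sample adjusted R^2 (which accounts for differing feature
    counts).  Returns a frame indexed by cell with ``cv_r``,
    ``adj_r2`` and ``n_genes``.
    """
    from sklearn.linear_model import LinearRegression
    from sklearn.model_selection import KFold

    rows = {}
    for cell, X in features_by_cell.items():
        if cell not in expression.columns:
            continue
        genes = X.index.intersection(expression.index)
        Xm = X.loc[genes].to_numpy(dtype=float)
        y = expression.loc[genes, cell].to_numpy(dtype=float)
        n, p = Xm.shape
        if n <= p + 1:
            raise ValueError(f"cell {cell}: fewer genes ({n}) than features ({p}) + 2")
        model = LinearRegression().fit(Xm, y)
        resid = y - model.predict(Xm)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        pred = np.empty_like(y)
        kf = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
        for train, test in kf.split(Xm):
            f = LinearRegression().fit(Xm[train], y[train])
            pred[test] = f.predict(Xm[test])
        if np.std(pred) > 0 and np.std(y) > 0:
            cv_r = float(np.corrcoef(y, pred)[0, 1])
        else:
            cv_r = float("nan")
        rows[cell] = {"cv_r": cv_r, "adj_r2": adj_r2, "n_genes": n}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    query_genes: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Fisher's exact test of a query gene list against each gene set.

    Gene sets are intersected with the universe; the 2x2 table counts
    query/non-query x in-set/out-of-set genes.  Odds ratios are the
    sample (cross-product) odds ratios; p-values are two-sided and
    BH-adjusted across sets.
    """
    query = set(query_genes)
    uni = set(universe)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & uni
        if not s:
            continue
        a = len(query & s)
        b = len(query - s)
        c = len(s - query)
        d = len(uni) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, a, len(s), odds, p))
    out = pd.DataFrame(
        rows, columns=["gene_set", "n_overlap", "n_set", "odds_ratio", "p"]
    )
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
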