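"""Synthetic single-cell NOMe-seq data with known ground truth.

Two tiers of generator:

* a full read-level simulator (:func:`simulate_genome`,
  :func:`simulate_cells`) that builds a random genome with regularly
  spaced genes, tiles nucleosomes with per-cell jitter, opens
  nucleosome-depleted regions (NDRs) at active promoters, draws CpG
  methylation anti-coupled to accessibility through a Gaussian copula,
  samples binomial reads per cytosine and emits Bismark-style cytosine
  reports, an expression count table, a QC table and truth tables;

* locus-level generators (:func:`simulate_coupled_loci`,
  :func:`simulate_cellwise_coupling`, :func:`simulate_profile_cells`,
  :func:`simulate_ndr_expression`) that start from latent per-(cell,
  locus) rates and push them through the same binomial observation
  model, for calibration and power studies of the correlation scans,
  the profile mixture model and expression prediction.

Reads are simulated at site level (counts per cytosine), not as
fragments: the pipeline consumes cytosine reports, and fragment
simulation would add no tested behaviour.  Bisulfite conversion error is
a single symmetric flip probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from . import context as ctx
from .quant import site_rate
from .types import FEATURE_COLUMNS, RateMatrix, SITE_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass
class SimConfig:
    """Study conditions for the read-level simulator.

    Defaults emulate a small embryoid-body-like experiment: 40 cells on
    a continuous differentiation trajectory (or two subpopulations),
    ~190 bp nucleosome repeat with 10 bp per-cell dyad jitter, NDRs at
    open promoters, GpC emission probabilities of 0.8 in linker/NDR and
    0.1 under nucleosomes, beta-distributed promoter methylation with
    logit-scale cell deviations, negative methylation–accessibility and
    methylation–expression coupling, positive accessibility–expression
    coupling, and shallow binomial read sampling.
    """

    seed: int = 0
    # genome and annotation
    genome_length: int = 200_000
    base_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    chrom: str = "chrS"
    n_genes: int = 40
    gene_length: int = 1000
    tss_margin: int = 3000
    # cells
    n_cells: int = 40
    trajectory: bool = True
    subpop_props: Tuple[float, float] = (0.5, 0.5)
    # chromatin
    nucleosome_repeat: int = 190
    nucleosome_halfwidth: int = 73
    jitter_sd: float = 10.0
    ndr_halfwidth: int = 75
    p_open: Tuple[float, float] = (0.7, 0.4)   # NDR occupancy at tau=0 / tau=1
    acc_high: float = 0.8
    acc_low: float = 0.1
    # methylation
    met_locus_alpha: float = 2.0
    met_locus_beta: float = 2.0
    met_cell_sd: float = 1.0
    met_window: int = 2000           # promoter methylation half-window
    background_met: float = 0.7
    cph_rate: float = 0.01
    # couplings (target signs; tau-ramped when endpoints differ)
    rho_ma: Tuple[float, float] = (-0.5, -0.5)
    rho_me: float = -0.3
    rho_ae: float = 0.3
    # reads
    coverage_prob: float = 0.2
    mean_depth: float = 5.0
    conversion_error: float = 0.005
    # expression
    expr_base_mean: float = 4.0
    expr_base_sd: float = 1.5
    nb_size: float = 2.0
    tau_gene_frac: float = 0.4
    n_extra_genes: int = 460         # expression-only genes beyond the loci
    marker_gene: str = "gene_001"    # programmed to decay along tau

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome length must be >= 10 kb")
        if not np.isclose(sum(self.base_probs), 1.0):
            raise ValueError("base probabilities must sum to 1")
        if self.nucleosome_repeat <= 0:
            raise ValueError("nucleosome repeat length must be positive")
        for p in (*self.p_open, self.acc_high, self.acc_low, self.coverage_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in (*self.rho_ma, self.rho_me, self.rho_ae):
            if not -1 <= r <= 1:
                raise ValueError("coupling parameters must lie in [-1, 1]")
        if max(abs(self.rho_ma[0]), abs(self.rho_ma[1])) > 0.95:
            raise ValueError(
                "|rho_ma| > 0.95 cannot be realised given the binary "
                "open/closed accessibility marginal"
            )
        if self.rho_ma[0] > 0 or self.rho_ma[1] > 0 or self.rho_me > 0:
            raise ValueError("rho_ma and rho_me must be <= 0")
        if self.rho_ae < 0:
            raise ValueError("rho_ae must be >= 0")


@dataclass
class TruthTables:
    """Simulator ground truth keyed like the emitted data."""

    tau: pd.Series                     # latent pseudotime per cell
    subpop: pd.Series                  # 0/1 population label
    rho_ma: pd.Series                  # realised coupling target per cell
    open_state: pd.DataFrame           # cells x genes, promoter NDR open?
    met_latent: pd.DataFrame           # cells x genes latent promoter methylation
    acc_latent: pd.DataFrame           # cells x genes latent promoter accessibility
    expr_log_mean: pd.DataFrame        # cells x genes latent log2 expression mean
    dyads: Dict[str, np.ndarray]       # per cell nucleosome dyad positions
    config: dict


@dataclass
class SimData:
    """Everything the read-level simulator emits."""

    genome: Dict[str, str]
    genes: pd.DataFrame                # feature frame of gene bodies (gene_id set)
    sites_by_cell: Dict[str, pd.DataFrame]
    counts: pd.DataFrame               # genes x cells
    qc: pd.DataFrame
    truth: TruthTables

    def tss_frame(
        self,
        halfwidth: int,
        context_class: str = "promoter",
        feature_ids: Optional[Sequence[str]] = None,
    ) -> pd.DataFrame:
        """Feature frame of +/- halfwidth windows around every TSS.

        Passing the same ``feature_ids`` for different half-widths yields
        layer-specific windows over shared ids — the convention for
        promoters, where accessibility is scored in a narrow TSS window
        (+/- 50 bp) and methylation in a wide one (+/- 2 kb).
        """
        tss = self.genes["start"]
        if feature_ids is None:
            feature_ids = [f"{g}_prom" for g in self.genes["gene_id"]]
        return pd.DataFrame(
            {
                "chrom": self.genes["chrom"],
                "start": (tss - halfwidth).clip(lower=1),
                "end": tss + halfwidth,
                "strand": self.genes["strand"],
                "feature_id": list(feature_ids),
                "context_class": context_class,
                "gene_id": self.genes["gene_id"],
            }
        )[FEATURE_COLUMNS]


def simulate_genome(config: SimConfig) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Random i.i.d. genome plus a regular grid of gene annotations."""
    rng = np.random.default_rng(config.seed)
    codes = rng.choice(_BASES, size=config.genome_length, p=config.base_probs)
    genome = {config.chrom: codes.tobytes().decode("ascii")}
    usable = config.genome_length - 2 * config.tss_margin
    spacing = usable // max(config.n_genes, 1)
    tss = config.tss_margin + spacing * np.arange(config.n_genes) + spacing // 2
    genes = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": tss.astype(np.int64),
            "end": (tss + config.gene_length - 1).astype(np.int64),
            "strand": "+",
            "feature_id": [f"gene_{i + 1:03d}" for i in range(config.n_genes)],
            "context_class": "gene_body",
        }
    )
    genes["gene_id"] = genes["feature_id"]
    return genome, genes[FEATURE_COLUMNS]


def simulate_trajectory(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.Series, pd.Series]:
    """Latent pseudotime tau per cell (and a 0/1 population label).

    Trajectory mode draws tau ~ Uniform(0, 1); two-subpopulation mode
    draws tau from a bimodal beta mixture so the populations sit at the
    ends of the axis.
    """
    if config.n_cells < 10:
        raise ValueError("need at least 10 cells")
    rng = rng or np.random.default_rng(config.seed)
    cells = [f"cell_{i + 1:03d}" for i in range(config.n_cells)]
    if config.trajectory:
        tau = rng.uniform(0.0, 1.0, config.n_cells)
        subpop = (tau > 0.5).astype(int)
    else:
        comp = rng.choice(2, size=config.n_cells, p=config.subpop_props)
        lo = rng.beta(2.0, 8.0, config.n_cells)
        hi = rng.beta(8.0, 2.0, config.n_cells)
        tau = np.where(comp == 0, lo, hi)
        subpop = comp
    return (
        pd.Series(tau, index=cells, name="tau"),
        pd.Series(subpop, index=cells, name="subpop"),
    )


def _site_table(genome: Dict[str, str]) -> pd.DataFrame:
    """All cytosines of the genome, both strands, with context labels."""
    chrom = next(iter(genome))
    arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
    frames = []
    for strand, base in (("+", ord("C")), ("-", ord("G"))):
        pos0 = np.flatnonzero(arr == base)
        df = pd.DataFrame({"chrom": chrom, "pos": pos0 + 1, "strand": strand})
        frames.append(df)
    sites = pd.concat(frames, ignore_index=True).sort_values(
        ["pos", "strand"], kind="mergesort", ignore_index=True
    )
    sites["label"] = ctx.classify_sites(sites, genome).to_numpy()
    tri = []
    seq = genome[chrom]
    for pos, strand in zip(sites["pos"], sites["strand"]):
        if pos == 1 or pos == len(seq):
            tri.append("NNN")
        elif strand == "+":
            tri.append(seq[pos - 2 : pos + 1])
        else:
            tri.append(ctx.revcomp(seq[pos - 2 : pos + 1]))
    sites["trinucleotide"] = tri
    sites["context"] = np.where(
        sites["label"].isin([ctx.CG_KEPT, ctx.CG_EXCLUDED_GCG, ctx.CG_EXCLUDED_CCG]),
        "CpG",
        np.where(sites["label"] == ctx.GC_KEPT, "GpC", "CHH"),
    )
    return sites


def _cell_dyads(
    config: SimConfig,
    rng: np.random.Generator,
    tss: np.ndarray,
    open_state: np.ndarray,
) -> np.ndarray:
    """Nucleosome dyad positions for one cell.

    A common template array (one dyad per repeat length) is jittered per
    cell; dyads whose footprint would invade the NDR of an open promoter
    are evicted, and closed promoters are guaranteed a TSS-covering
    nucleosome.
    """
    template = np.arange(
        config.nucleosome_repeat // 2,
        config.genome_length,
        config.nucleosome_repeat,
        dtype=float,
    )
    dyads = template + rng.normal(0.0, config.jitter_sd, template.size)
    keep = np.ones(dyads.size, dtype=bool)
    clearance = config.ndr_halfwidth + config.nucleosome_halfwidth
    for t, is_open in zip(tss, open_state):
        if is_open:
            keep &= np.abs(dyads - t) > clearance
        else:
            near = np.abs(dyads - t) <= config.nucleosome_repeat / 2
            if not near.any():
                dyads = np.append(dyads, t + rng.normal(0.0, config.jitter_sd))
                keep = np.append(keep, True)
    return np.sort(dyads[keep])


def _accessibility_at(
    positions: np.ndarray, dyads: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Linker/NDR-high, nucleosome-low emission probability per position."""
    if dyads.size == 0:
        return np.full(positions.size, config.acc_high)
    idx = np.searchsorted(dyads, positions)
    left = np.abs(positions - dyads[np.clip(idx - 1, 0, dyads.size - 1)])
    right = np.abs(dyads[np.clip(idx, 0, dyads.size - 1)] - positions)
    nearest = np.minimum(left, right)
    return np.where(
        nearest <= config.nucleosome_halfwidth, config.acc_low, config.acc_high
    )


def simulate_cells(
    config: SimConfig,
    genome: Optional[Dict[str, str]] = None,
    genes: Optional[pd.DataFrame] = None,
) -> SimData:
    """Full read-level simulation of a single-cell NOMe-seq experiment."""
    if genome is None or genes is None:
        genome, genes = simulate_genome(config)
    master = np.random.default_rng(config.seed + 1)
    tau, subpop = simulate_trajectory(config, master)
    cells = list(tau.index)
    gene_ids = genes["gene_id"].tolist()
    tss = genes["start"].to_numpy()
    n_genes = len(gene_ids)

    all_sites = _site_table(genome)
    pos_all = all_sites["pos"].to_numpy()
    is_gpc = (all_sites["label"] == ctx.GC_KEPT).to_numpy()
    is_cpg_ctx = all_sites["context"].to_numpy() == "CpG"
    is_gcg = (all_sites["label"] == ctx.CG_EXCLUDED_GCG).to_numpy()

    # promoter methylation loci: tss +/- met_window; map each CpG-context
    # site to its gene (-1 = background)
    met_gene = np.full(pos_all.size, -1)
    for g, t in enumerate(tss):
        inside = (pos_all >= t - config.met_window) & (pos_all <= t + config.met_window)
        met_gene[inside] = g

    # per-gene locus methylation means and tau ramps for expression;
    # expression-only genes model the rest of a real transcriptome
    n_total_genes = n_genes + config.n_extra_genes
    all_gene_ids = gene_ids + [
        f"xgene_{i + 1:03d}" for i in range(config.n_extra_genes)
    ]
    mu_g = master.beta(config.met_locus_alpha, config.met_locus_beta, n_genes)
    mu_g = np.clip(mu_g, 0.05, 0.95)
    p_open_gene_offset = master.normal(0.0, 0.5, n_genes)
    base_expr = master.normal(config.expr_base_mean, config.expr_base_sd, n_total_genes)
    is_tau_gene = master.random(n_total_genes) < config.tau_gene_frac
    ramp_amp = master.uniform(1.0, 3.0, n_total_genes) * master.choice(
        [-1.0, 1.0], n_total_genes
    )
    bump_amp = master.normal(0.0, 1.0, n_total_genes)
    ramp_amp[~is_tau_gene] = 0.0
    bump_amp[~is_tau_gene] = 0.0
    marker_idx = (
        all_gene_ids.index(config.marker_gene)
        if config.marker_gene in all_gene_ids
        else 0
    )
    is_tau_gene[marker_idx] = True
    ramp_amp[marker_idx] = -3.0
    bump_amp[marker_idx] = 0.0
    # an orientation marker must be reliably detected: give it a solid
    # baseline so its programmed decay is visible over sampling noise
    base_expr[marker_idx] = max(base_expr[marker_idx], 6.0)

    # expression coupling slopes (log2 units per unit latent deviation)
    beta_a = 4.0 * config.rho_ae
    beta_m = 4.0 * abs(config.rho_me)

    sites_by_cell: Dict[str, pd.DataFrame] = {}
    open_mat = np.zeros((config.n_cells, n_genes), dtype=bool)
    met_mat = np.zeros((config.n_cells, n_genes))
    acc_mat = np.zeros((config.n_cells, n_genes))
    logmean_mat = np.zeros((config.n_cells, n_total_genes))
    counts = np.zeros((n_total_genes, config.n_cells), dtype=np.int64)
    dyads_by_cell: Dict[str, np.ndarray] = {}
    rho_cells = np.empty(config.n_cells)
    qc_rows = []

    for i, cell in enumerate(cells):
        rng = np.random.default_rng(config.seed + 1000 + i)
        t_i = float(tau.iloc[i])
        rho_i = config.rho_ma[0] + (config.rho_ma[1] - config.rho_ma[0]) * t_i
        rho_cells[i] = rho_i
        c = -rho_i  # copula correlation: closed (z_a high) with methylated
        z_a = rng.normal(size=n_genes)
        z_m = c * z_a + np.sqrt(max(0.0, 1.0 - c * c)) * rng.normal(size=n_genes)

        p_open_i = special.expit(
            _logit(
                np.clip(
                    config.p_open[0] + (config.p_open[1] - config.p_open[0]) * t_i,
                    0.02,
                    0.98,
                )
            )
            + p_open_gene_offset
        )
        open_g = z_a < stats.norm.ppf(p_open_i)
        open_mat[i] = open_g
        met_g = special.expit(_logit(mu_g) + config.met_cell_sd * z_m)
        met_mat[i] = met_g

        dyads = _cell_dyads(config, rng, tss, open_g)
        dyads_by_cell[cell] = dyads

        # latent rate per cytosine
        acc_field = _accessibility_at(pos_all.astype(float), dyads, config)
        gm = special.expit(_logit(config.background_met) + rng.normal(0.0, 0.3))
        met_field = np.where(met_gene >= 0, met_g[np.clip(met_gene, 0, None)], gm)
        rate = np.where(
            is_gpc,
            acc_field,
            np.where(
                is_cpg_ctx & ~is_gcg,
                met_field,
                np.where(
                    is_gcg,
                    1.0 - (1.0 - acc_field) * (1.0 - met_field),
                    config.cph_rate,
                ),
            ),
        )

        # per-gene latent accessibility = mean emission in the NDR window
        for g, t_pos in enumerate(tss):
            win = np.abs(pos_all - t_pos) <= config.ndr_halfwidth
            sel = win & is_gpc
            acc_mat[i, g] = acc_field[sel].mean() if sel.any() else np.nan

        covered = rng.random(pos_all.size) < config.coverage_prob
        depth = 1 + rng.poisson(max(config.mean_depth - 1.0, 0.0), covered.sum())
        e = config.conversion_error
        p_obs = rate[covered] * (1 - e) + (1 - rate[covered]) * e
        n_meth = rng.binomial(depth, p_obs)
        df = all_sites.loc[covered, ["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
        df["n_meth"] = n_meth
        df["n_unmeth"] = depth - n_meth
        sites_by_cell[cell] = df[SITE_COLUMNS].reset_index(drop=True)

        # expression: locus genes couple to their promoter state, every
        # tau-gene follows a smooth function of pseudotime
        logmean = base_expr + ramp_amp * (t_i - 0.5) + bump_amp * np.sin(np.pi * t_i)
        logmean[:n_genes] += beta_a * (open_g.astype(float) - p_open_i) - beta_m * z_m
        logmean_mat[i] = logmean
        mu = np.maximum(2.0**logmean, 1e-6)
        size = config.nb_size
        counts[:, i] = rng.negative_binomial(size, size / (size + mu))

        n_cpg_cov = int((df["context"] == "CpG").sum())
        n_gpc_cov = int((df["context"] == "GpC").sum())
        qc_rows.append(
            {
                "cell_id": cell,
                "mapped_reads": int(rng.normal(1.2e6, 2e5)),
                "mito_frac": float(np.clip(rng.beta(2, 30), 0, 1)),
                "n_genes": int(rng.normal(6000, 1200)),
                "mapping_efficiency": float(np.clip(rng.normal(0.37, 0.04), 0, 1)),
                "cpg_sites": int(rng.normal(2e6, 3e5)),
                "gpc_sites": int(rng.normal(1.2e7, 1.5e6)),
                "n_genes_simulated": int((counts[:, i] > 0).sum()),
                "cpg_sites_simulated": n_cpg_cov,
                "gpc_sites_simulated": n_gpc_cov,
            }
        )

    counts_df = pd.DataFrame(counts, index=all_gene_ids, columns=cells)
    counts_df.index.name = "gene_id"
    qc = pd.DataFrame(qc_rows).set_index("cell_id")
    truth = TruthTables(
        tau=tau,
        subpop=subpop,
        rho_ma=pd.Series(rho_cells, index=cells, name="rho_ma"),
        open_state=pd.DataFrame(open_mat, index=cells, columns=gene_ids),
        met_latent=pd.DataFrame(met_mat, index=cells, columns=gene_ids),
        acc_latent=pd.DataFrame(acc_mat, index=cells, columns=gene_ids),
        expr_log_mean=pd.DataFrame(logmean_mat, index=cells, columns=all_gene_ids),
        dyads=dyads_by_cell,
        config=asdict(config),
    )
    return SimData(
        genome=genome,
        genes=genes,
        sites_by_cell=sites_by_cell,
        counts=counts_df,
        qc=qc,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Locus-level generators for the correlation scans
# ---------------------------------------------------------------------------

def _observe_rate_matrix(
    latent: np.ndarray,
    rng: np.random.Generator,
    mean_sites: float = 5.0,
    min_sites: int = 3,
    mean_depth: float = 8.0,
    coverage_prob: float = 0.85,
    layer: str = "met",
    prefix: str = "locus",
) -> RateMatrix:
    """Binomial observation of a loci x cells latent rate matrix.

    Each observed (locus, cell) entry receives ``min_sites`` plus a
    Poisson number of covered sites, each with 1 + Poisson read depth;
    site MAP rates under a flat prior are combined by inverse-variance
    weighting — the same estimator path real data takes.
    """
    n_loci, n_cells = latent.shape
    obs = rng.random(latent.shape) < coverage_prob
    k = np.where(obs, min_sites + rng.poisson(mean_sites - min_sites, latent.shape), 0)
    rates = np.full(latent.shape, np.nan)
    ses = np.full(latent.shape, np.nan)
    flat = np.flatnonzero(obs)
    ks = k.ravel()[flat]
    p = latent.ravel()[flat]
    reps = np.repeat(np.arange(flat.size), ks)
    depth = 1 + rng.poisson(mean_depth - 1.0, reps.size)
    m = rng.binomial(depth, p[reps])
    r_site, se_site = site_rate(m, depth, 1.0, 1.0)
    w = 1.0 / se_site**2
    wsum = np.bincount(reps, weights=w, minlength=flat.size)
    wrsum = np.bincount(reps, weights=w * r_site, minlength=flat.size)
    rates.ravel()[flat] = wrsum / wsum
    ses.ravel()[flat] = np.sqrt(1.0 / wsum)
    idx = [f"{prefix}_{j + 1:03d}" for j in range(n_loci)]
    cols = [f"cell_{i + 1:03d}" for i in range(n_cells)]
    return RateMatrix(
        rates=pd.DataFrame(rates, index=idx, columns=cols),
        se=pd.DataFrame(ses, index=idx, columns=cols),
        n_sites=pd.DataFrame(np.where(obs, k, np.nan), index=idx, columns=cols),
        layer=layer,
    )


def _loci_features(n_loci: int, context: str = "promoter") -> pd.DataFrame:
    """Feature frame for abstract loci (one per 10 kb of a virtual chrom)."""
    return pd.DataFrame(
        {
            "chrom": "chrV",
            "start": 1 + 10_000 * np.arange(n_loci),
            "end": 2_000 + 10_000 * np.arange(n_loci),
            "strand": "+",
            "feature_id": [f"locus_{j + 1:03d}" for j in range(n_loci)],
            "context_class": context,
            "gene_id": [f"g{j + 1:03d}" for j in range(n_loci)],
        }
    )[FEATURE_COLUMNS]


def simulate_coupled_loci(
    n_cells: int = 40,
    n_loci: int = 100,
    n_coupled: int = 20,
    r: float = -0.8,
    partner: str = "expr",
    seed: int = 0,
) -> Tuple[RateMatrix, object, pd.DataFrame, np.ndarray]:
    """Loci with (or without) true cross-layer coupling across cells.

    The first ``n_coupled`` loci couple their latent methylation
    deviations to the partner layer at correlation ``r`` on the latent
    Gaussian scale; the rest are null.  Coupled loci carry larger latent
    variance on both layers — coupling is only observable where cells
    actually vary, the same independent-filtering rationale the scan's
    variance filters encode.  ``partner`` is ``"expr"`` (log-normalised
    expression matrix) or ``"acc"`` (a second rate matrix).

    Returns ``(met_rates, partner_layer, features, coupled_mask)``.
    """
    rng = np.random.default_rng(seed)
    coupled = np.zeros(n_loci, dtype=bool)
    coupled[:n_coupled] = True
    mu = np.clip(rng.beta(2.0, 2.0, n_loci), 0.1, 0.9)
    sd = np.where(coupled, rng.uniform(0.8, 1.2, n_loci), rng.uniform(0.2, 0.8, n_loci))
    z = rng.normal(size=(n_loci, n_cells))
    eps = rng.normal(size=(n_loci, n_cells))
    y = np.where(coupled[:, None], r * z + np.sqrt(1 - r * r) * eps, eps)

    latent_met = special.expit(_logit(mu)[:, None] + sd[:, None] * z)
    met = _observe_rate_matrix(latent_met, rng, layer="met")
    features = _loci_features(n_loci)

    if partner == "expr":
        amp = np.where(
            coupled, rng.uniform(1.0, 1.5, n_loci), rng.uniform(0.3, 1.0, n_loci)
        )
        expr = 5.0 + amp[:, None] * y + rng.normal(0.0, 0.3, (n_loci, n_cells))
        expr_df = pd.DataFrame(
            expr, index=features["gene_id"].to_numpy(), columns=met.cells
        )
        return met, expr_df, features, coupled
    if partner == "acc":
        mu_b = np.clip(rng.beta(2.0, 2.0, n_loci), 0.1, 0.9)
        sd_b = np.where(
            coupled, rng.uniform(0.8, 1.2, n_loci), rng.uniform(0.2, 0.8, n_loci)
        )
        latent_acc = special.expit(_logit(mu_b)[:, None] + sd_b[:, None] * y)
        acc = _observe_rate_matrix(latent_acc, rng, layer="acc")
        return met, acc, features, coupled
    raise ValueError(f"unknown partner layer {partner!r}")


def simulate_cellwise_coupling(
    rho_per_cell: np.ndarray,
    n_loci: int = 80,
    seed: int = 0,
    locus_mean_sd: float = 0.4,
    cell_dev_sd: float = 1.0,
    return_latent: bool = False,
):
    """Methylation/accessibility layers with per-cell coupling strength.

    Within cell i the latent logit deviations of the two layers across
    loci are correlated at ``rho_per_cell[i]`` (negative = anticoupled);
    locus means vary on the logit scale with sd ``locus_mean_sd``.  Used
    to programme coupling ramps along a trajectory.
    """
    rho = np.asarray(rho_per_cell, dtype=float)
    if (np.abs(rho) > 1).any():
        raise ValueError("per-cell coupling must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    n_cells = rho.size
    mu_m = _logit(np.clip(rng.beta(2, 2, n_loci), 0.15, 0.85)) + rng.normal(
        0, locus_mean_sd, n_loci
    )
    mu_a = _logit(np.clip(rng.beta(2, 2, n_loci), 0.15, 0.85)) + rng.normal(
        0, locus_mean_sd, n_loci
    )
    z_m = rng.normal(size=(n_loci, n_cells))
    eps = rng.normal(size=(n_loci, n_cells))
    z_a = rho[None, :] * z_m + np.sqrt(1.0 - rho**2)[None, :] * eps
    latent_m = special.expit(mu_m[:, None] + cell_dev_sd * z_m)
    latent_a = special.expit(mu_a[:, None] + cell_dev_sd * z_a)
    met = _observe_rate_matrix(latent_m, rng, layer="met")
    acc = _observe_rate_matrix(latent_a, rng, layer="acc")
    feats = _loci_features(n_loci)
    if return_latent:
        return met, acc, feats, (latent_m, latent_a)
    return met, acc, feats


# ---------------------------------------------------------------------------
# Profile-level generators
# ---------------------------------------------------------------------------

#: Prototype accessibility curves on the scaled window [-1, 1].
def _profile_shape(kind: str, x: np.ndarray) -> np.ndarray:
    if kind == "open":       # nucleosome-depleted TSS
        return 0.10 + 0.80 * np.exp(-0.5 * (x / 0.35) ** 2)
    if kind == "closed":     # nucleosome over the TSS
        return np.full_like(x, 0.10)
    if kind == "shifted":    # depletion displaced to the +1 nucleosome
        return 0.10 + 0.80 * np.exp(-0.5 * ((x - 0.6) / 0.3) ** 2)
    raise ValueError(f"unknown profile shape {kind!r}")


def simulate_profile_cells(
    n_cells: int = 40,
    true_k: int = 2,
    sites_per_cell: Tuple[int, int] = (15, 30),
    mean_depth: float = 2.0,
    seed: int = 0,
) -> Tuple[List[Tuple[np.ndarray, np.ndarray, np.ndarray]], np.ndarray]:
    """Cells drawn from ``true_k`` well-separated profile clusters.

    Returns ``(cell_data, labels)`` where each cell is a tuple of
    (scaled positions, methylated counts, total counts) ready for
    profile fitting and clustering.
    """
    kinds = ["open", "closed", "shifted"][:true_k]
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, true_k, n_cells)
    # guarantee every cluster is populated
    labels[:true_k] = np.arange(true_k)
    data = []
    for lab in labels:
        n_sites = rng.integers(sites_per_cell[0], sites_per_cell[1] + 1)
        x = np.sort(rng.uniform(-1.0, 1.0, n_sites))
        p = _profile_shape(kinds[lab], x)
        depth = 1 + rng.poisson(mean_depth - 1.0, n_sites)
        m = rng.binomial(depth, p)
        data.append((x, m, depth))
    return data, labels


def simulate_ndr_expression(
    n_genes: int = 50,
    n_cells: int = 20,
    sites_per_gene: int = 30,
    mean_depth: float = 3.0,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Expression driven by NDR depth that window-mean rates cannot see.

    Each gene's accessibility curve is a central depletion bump whose
    depth varies between genes but whose *window average* is held
    constant, so a scalar rate feature carries no expression signal
    while the profile shape does.  Expression per gene is a linear
    function of the bump depth plus noise, shared across cells.

    Returns ``(gpc_by_gene_cell, expression, depth)`` where
    ``gpc_by_gene_cell[(gene, cell)] = (x, m, n)``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene_{j + 1:03d}" for j in range(n_genes)]
    cells = [f"cell_{i + 1:03d}" for i in range(n_cells)]
    depth_g = rng.uniform(0.0, 0.7, n_genes)
    # bump with window-mean removed: integral of the Gaussian over [-1,1]
    xx = np.linspace(-1, 1, 2001)
    bump = np.exp(-0.5 * (xx / 0.25) ** 2)
    bump_mean = float(bump.mean())
    base = 0.45

    def curve(g: int, x: np.ndarray) -> np.ndarray:
        b = np.exp(-0.5 * (x / 0.25) ** 2)
        return np.clip(base - depth_g[g] * (b - bump_mean), 0.02, 0.98)

    data = {}
    for g in range(n_genes):
        for i in range(n_cells):
            x = np.sort(rng.uniform(-1.0, 1.0, sites_per_gene))
            p = curve(g, x)
            d = 1 + rng.poisson(mean_depth - 1.0, sites_per_gene)
            m = rng.binomial(d, p)
            data[(genes[g], cells[i])] = (x, m, d)
    expr = pd.DataFrame(
        2.0
        + 4.0 * depth_g[:, None]
        + rng.normal(0.0, noise_sd, (n_genes, n_cells)),
        index=genes,
        columns=cells,
    )
    return data, expr, pd.Series(depth_g, index=genes, name="ndr_depth")
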