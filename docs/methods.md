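# Methods

`scnome` implements the computational side of single-cell NOMe-seq
analysis: a GpC methyltransferase labels accessible chromatin in vitro,
bisulfite sequencing reads out that label together with endogenous CpG
methylation, and an RNA library from the same cell provides the
transcriptome. All analysis starts from per-cell cytosine reports
(per-site methylated/unmethylated read counts), never from raw reads.

## Context partitioning

Every cytosine is classified by its trinucleotide, read 5'→3' on the
cytosine's own strand (minus-strand contexts use the reverse
complement). A-C-G and T-C-G carry endogenous methylation; G-C-A, G-C-C
and G-C-T carry the accessibility label. G-C-G is simultaneously a GpC
and a CpG, so its methylation state cannot be attributed to either
source; it is removed from **both** channels. C-C-G is removed from the
methylation channel because of possible enzyme off-target activity.
Edge cytosines (no flanking base) and contexts containing N are
unclassifiable. The genome sequence is authoritative when it disagrees
with the trinucleotide stored in a report; a `trust` policy skips the
genome lookup for workflows without the reference at hand.

On an i.i.d. uniform genome the GpC dinucleotide density is 1/16 per
position, so the expected spacing between accessibility-informative
sites is ~16 bp — the method's spatial resolution — and each of the
GCG/CCG exclusions removes ~25% of CpG cytosines. A real mammalian
genome, being CpG-depleted and non-uniform, gives different shares; the
census reports both cytosine- and dinucleotide-level totals so either
convention can be compared.

## Rate quantification

Reads at one site in one cell are modelled as binomial with a beta
prior; the reported site rate is the posterior mode
(m + α − 1)/(n + α + β − 2) and its uncertainty the posterior standard
deviation. The prior defaults to an empirical moments fit per cell and
layer: the latent rate variance is estimated by subtracting the
binomial sampling component from the spread of raw proportions (the
unbiased estimator of E[r(1−r)] corrects the bias that plain moments on
proportions suffer at finite depth). Hyperparameters are clipped to
≥ 1 so the mode is interior; degenerate inputs (no latent spread, or
all-extreme proportions) fall back to the uniform Beta(1, 1) with a
warning, which makes the MAP equal the raw proportion.

Feature rates combine the covered sites overlapping a 1-based inclusive
interval by inverse-variance weighting, se² = 1/Σ(1/se_i²); with equal
standard errors this is exactly the plain mean. Across cells, a
feature is summarised under a normal model with a method-of-moments
(DerSimonian–Laird) between-cell variance τ² added to each cell's
sampling variance; the reported spread is τ, the biological
cell-to-cell sd after removing per-cell sampling noise.

Promoter windows are layer-specific with shared feature ids:
accessibility ±50 bp around the TSS (the NDR scale), methylation
±2 kb. Expression is normalised by median-of-ratios size factors
(library-size fallback for cells sparse in the reference gene set;
factors rescaled to mean 1) followed by log2(x+1). QC presets: serum-ES
cells require ≥300k mapped RNA reads, ≤15% mitochondrial fraction,
≥2000 genes, ≥10% bisulfite mapping efficiency, ≥500k CpG and ≥5M GpC
sites; the embryoid-body preset lowers the read floor to 100k and the
CpG floor to 300k and drops the GpC threshold.

## Correlation scans

Association between layers is a weighted Pearson correlation with
sequencing coverage (covered-site counts) as weights, normalised to sum
to n so equal weights reduce exactly to the textbook estimator. CpG
coverage is the weight whenever methylation participates; GpC coverage
is used for accessibility–expression by analogy (the convention for
that pair is a package choice, flagged here). Significance uses the
t transform t = r√((n−2)/(1−r²)) with the **unweighted** n − 2 degrees
of freedom. Under weight concentration this df convention is mildly
anticonservative (measured ~5.6% of null p-values below 0.05 in the
package's own calibration simulations), which the FDR calibration test
accounts for by asserting the realised null FDP within Monte-Carlo
error of nominal.

The locus scan (one test per locus, across cells) filters to entries
with ≥3 covered sites, loci with ≥20 jointly observed cells, the top
50% most variable loci per genomic context (variance of layer-A rates;
ties at the cut kept), and, for expression partners, genes at or above
the median variance of log-normalised counts — the independent-
filtering rationale: loci without variability cannot display
correlation. Benjamini–Hochberg adjustment runs within each context;
significance is called at FDR < 0.1. The per-cell scan (one test per
cell, across loci) applies the same coverage filters, requires a
minimum number of qualifying loci per cell, and also reports the
pseudo-bulk correlation computed on cell-averaged locus values with
cell-summed weights.

## Single-cell accessibility profiles

Window-mean rates cannot distinguish a nucleosomal oscillation from a
flat landscape of the same mean. Per cell and TSS window (±200 bp,
positions scaled to [−1, 1]), accessibility is modelled as
Φ(h(x)ᵀw): a probit-link Bernoulli GLM over 9 Gaussian radial basis
functions plus intercept (centres equally spaced, width = centre
spacing; logistic link available). The objective, with an L2 penalty
λ = 0.01 on non-intercept weights, is concave; it is maximised by
damped Newton with an L-BFGS fallback, so fits are deterministic.
Genes enter profiling if ≥40% of cells (inclusive) carry ≥10 covered
GpC sites (inclusive) in the window.

Per gene, cells are clustered by an EM finite mixture over profile
curves with the Bernoulli likelihood evaluated on each cell's own
observed sites — deeply covered cells therefore carry proportionally
more information, a deliberate treatment of unequal coverage. Each
candidate K gets 5 restarts initialised by k-means on per-cell weight
vectors; those initialisation fits use a stronger shrinkage penalty
(1.0) because unshrunk per-cell estimates at ~20 sites per 10
parameters are noise-dominated and seed EM into poor local optima —
the mixture M-step itself keeps λ = 0.01. K ∈ {1..6} by default is
chosen by BIC = −2 logL + p log(N_cells) with p = K(M+1) + (K−1); ties
prefer the smaller K; degenerate (emptied) clusters trigger a restart.
The chosen K is the per-gene heterogeneity measure: K=1 promoters are
homogeneous across cells, higher K marks cell-to-cell chromatin
variation.

Expression prediction compares, per cell across genes, a linear
regression on the scalar accessibility rate against one on the fitted
basis weights; accuracy is the cross-validated (10-fold by default)
Pearson r between observed and predicted expression, with in-sample
adjusted R² reported alongside because the two feature sets differ in
dimension. Gene-set enrichment is Fisher's exact test per set with BH
adjustment across sets, over user-supplied sets.

## Pseudotime and dynamics

Genes are ranked for biological overdispersion by their variance
residual above a rolling-median mean–variance trend; the top 500 (by
default) feed a diffusion map: Gaussian kernel on Euclidean cell–cell
distances, bandwidth = median distance to the 5th neighbour,
symmetrically normalised, eigendecomposed. Pseudotime is the min–max
scaled **rank** along the first nontrivial component — robust for a
single linear trajectory, which is the intended regime (no branching).
A disconnected kernel graph is an error advising a larger bandwidth.
Orientation is fixed by a marker gene expected to fall (or rise) along
the process; reversing the marker's expected direction flips τ to 1−τ
exactly.

The profile–trajectory test is this package's construction (the
underlying statistic is not standardised in the field): per gene, the
per-cell basis-weight vectors are projected on their first principal
axis and the Spearman correlation of that projection with τ is tested
by permutation (1000 draws by default, two-sided, with the +1
correction), BH-adjusted across genes. Coupling dynamics regress each
cell's methylation–accessibility correlation on τ per context with the
Pearson t-test; a negative trend statistic means anticoupling
strengthens along the trajectory.

## The synthetic data generator

The generator is first-class, tested code; it defines the study
conditions under which every recovery guarantee is stated.

The read-level simulator draws an i.i.d. genome (200 kb, uniform
composition by default) with a regular grid of genes (40), tiles
nucleosomes at a 190 bp repeat with per-cell dyad jitter (sd 10 bp, so
pseudo-bulk keeps the repeat-length periodicity while single cells
differ), and opens an NDR (±75 bp) at promoters whose latent state is
open — evicting any dyad whose 73 bp half-footprint would invade it,
and guaranteeing closed promoters a TSS-covering nucleosome. GpC
emission probability is 0.8 in linker/NDR and 0.1 under a nucleosome.
Promoter methylation has beta-distributed locus means with logit-scale
cell deviations (sd 1.0); a Gaussian copula ties the methylation
deviation to the openness variable so the methylation–accessibility
coupling has target strength ρ_MA (≤0; endpoints may differ along τ,
giving a programmed coupling ramp). Expression is negative binomial
(size 2) with log-means coupled to promoter openness (+) and
methylation (−) and, for a 40% subset of genes, smooth functions of τ.
Besides the locus-linked genes, the simulator emits ~460
expression-only genes: a toy genome carries a few dozen promoters, but
pseudotime inference presupposes a transcriptome-scale matrix with
hundreds of informative genes. The orientation marker gene gets a fixed
decaying ramp and a guaranteed solid baseline, since an undetectable
marker cannot orient anything. Reads are simulated per site (coverage
probability 0.2, depth 1+Poisson(4)), with a symmetric bisulfite
conversion error flip of 0.005; reports are emitted in the 7-column
Bismark layout for all covered cytosines of every context, and
partitioning is left to the pipeline. Truth tables key every latent
quantity (τ, open states, latent rates, dyads, expression means) to the
emitted files. The QC table carries genome-scale plausible statistics
(plus the actual simulated coverage counts in `*_simulated` columns) so
the QC presets are exercisable on toy data.

Locus-level generators drive the calibration studies without a genome:
latent logit-normal rates observed through the same
sites-and-binomial-reads path and the package's own MAP/inverse-
variance estimators. In the coupled-loci generator, coupled loci carry
larger latent variance on both layers than null loci — coupling is
only observable where cells vary, the same independent-filtering logic
the scan encodes; this is what makes ≥80% power at r = −0.8 a
well-posed target under the scan's top-50% variance filters. The
profile generator uses three well-separated prototype curves (open,
closed, shifted-depletion TSS). The NDR-depth generator varies a
central depletion bump while holding the window average fixed, so
scalar rates carry no expression signal by construction and the
profile-vs-rate prediction comparison isolates shape information.

What the generator does **not** emulate: real genome composition
(CpG islands, repeats, CpG depletion), fragment-level read structure
and mapping artefacts, copy-number or allele effects, doublets,
branching trajectories, or realistic gene-gene correlation structure.
Passing recovery tests therefore demonstrates the correctness and
calibration of the estimators under the stated statistical model, not
performance on any particular real dataset.

## Numerical choices and problem sizes

Tolerances: EM converges at relative log-likelihood change < 1e-6 (200
iterations cap); Newton at relative objective change < 1e-10; BIC ties
break to smaller K; weighted correlations are clipped to [−1, 1]
against rounding. Zero-coverage report lines are retained on read and
filtered downstream. Boundary positions of features are inclusive on
both ends; BED input is converted to the internal 1-based inclusive
convention by an exact bijection.

The bundled test-suite and acceptance studies run at desk scale chosen
to keep the whole suite in a few minutes: 40-cell experiments, 60–200 kb
genomes, 10–20 replicate seeds per Monte-Carlo claim. The same
generators scale to larger designs through `SimConfig`.

## Known limitations

* The df = n − 2 convention under coverage weighting is mildly
  anticonservative when weights are very uneven (see Correlation
  scans); effective-sample-size corrections are deliberately not
  applied to keep the estimator the field-standard one.
* Symmetric CpG strand merging is available but off by default;
  strands are quantified separately.
* Missing-rate imputation, branching trajectories, RNA velocity and
  allele-specific analysis are out of scope.
* The mixture treats cells as exchangeable given their cluster; there
  is no explicit per-cell coverage normalisation inside EM beyond the
  likelihood's natural weighting.
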