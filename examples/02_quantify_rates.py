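"""Per-cell, per-promoter methylation and accessibility rates.

Each covered cytosine is a small binomial experiment; the site rate is
the posterior mode under a beta prior fitted to the cell's own sites,
and feature rates combine sites by inverse-variance weighting.  Cell
quality control applies the serum-ES thresholds to a per-cell
statistics table.
"""

import numpy as np

from scnome.context import partition_report
from scnome.quant import aggregate_across_cells, qc_filter, rate_matrix
from scnome.simulate import SimConfig, simulate_cells

sim = simulate_cells(SimConfig(seed=1, n_cells=20, genome_length=80_000, n_genes=15))

qc = qc_filter(sim.qc, "es")
print(f"QC: {int(qc['pass'].sum())}/{len(qc)} cells pass both layers")

cpg_by, gpc_by = {}, {}
for cell in qc.index[qc["pass"]]:
    cpg, gpc, _ = partition_report(sim.sites_by_cell[cell], sim.genome)
    cpg_by[cell], gpc_by[cell] = cpg, gpc

met = rate_matrix(cpg_by, sim.tss_frame(2000), prior="mom", layer="met")
acc = rate_matrix(gpc_by, sim.tss_frame(50), prior="mom", layer="acc")
print(f"methylation matrix: {met.rates.shape[0]} promoters x "
      f"{met.rates.shape[1]} cells, {100 * met.mask.values.mean():.0f}% observed")

fid = met.features[0]
mean, sd, n = aggregate_across_cells(met.rates.loc[fid], met.se.loc[fid])
print(f"promoter {fid}: mean methylation {mean:.2f}, "
      f"between-cell sd {sd:.2f} over {n} cells")
print("(the sd is the biological cell-to-cell spread after removing "
      "per-cell sampling error)")
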