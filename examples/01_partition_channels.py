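"""Split a single cell's cytosine report into CpG and GpC channels.

NOMe-seq encodes two signals in one bisulfite library: endogenous CpG
methylation and enzyme-written GpC accessibility.  The trinucleotide
context of each cytosine decides which channel it informs — G-C-G is
ambiguous and dropped from both, C-C-G is dropped from the methylation
channel against enzyme off-target risk.
"""

from scnome.context import context_census, partition_report, CG_EXCLUDED_GCG
from scnome.simulate import SimConfig, simulate_cells

sim = simulate_cells(SimConfig(seed=0, n_cells=12, genome_length=50_000, n_genes=8))
sites = sim.sites_by_cell["cell_001"]

cpg, gpc, census = partition_report(sites, sim.genome)
print(f"input calls:        {len(sites)}")
print(f"CpG (methylation):  {len(cpg)}")
print(f"GpC (accessibility):{len(gpc)}")
print(f"discarded:          {census}")

cen = context_census(sim.genome)
print(f"\ngenome census: {cen.n_cpg_dinucleotides} CpG and "
      f"{cen.n_gpc_dinucleotides} GpC dinucleotides")
print(f"mean GpC spacing: {list(cen.mean_gpc_spacing.values())[0]:.1f} bp "
      "(~16 bp on a uniform genome: the method's spatial resolution)")
print(f"share of CpG cytosines lost to the ambiguous GCG context: "
      f"{100 * cen.fraction_of_cpg(CG_EXCLUDED_GCG):.1f}%")
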