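"""Single-cell accessibility profiles at a TSS and their clustering.

A scalar rate in a fixed window cannot see nucleosome structure.  The
profile model fits each cell's GpC calls in the +/-200 bp TSS window
with probit basis-function regression, then clusters cells per gene
with an EM mixture; the BIC-chosen cluster count K measures chromatin
heterogeneity at that promoter.
"""

import numpy as np

from scnome.profiles import BasisSet, cluster_profiles, fit_bpr_profile
from scnome.simulate import simulate_profile_cells

basis = BasisSet()  # 9 RBFs + intercept on the scaled window [-1, 1]

# 40 cells split between an open-TSS and a closed-TSS state
data, labels = simulate_profile_cells(n_cells=40, true_k=2, seed=0)

x, m, n = data[0]
fit = fit_bpr_profile(x, m, n, basis=basis)
grid = np.linspace(-1, 1, 9)
curve = fit.predict(grid, basis)
print("one cell's fitted accessibility curve across the window:")
print("  " + " ".join(f"{v:.2f}" for v in curve))

res = cluster_profiles(data, k_candidates=(1, 2, 3, 4), seed=0)
acc = (res.assignments == labels).mean()
acc = max(acc, 1 - acc)
print(f"\nBIC per K: " + ", ".join(f"K={k}: {v:.0f}" for k, v in sorted(res.bic.items())))
print(f"chosen K = {res.k} (true 2); assignment accuracy {100 * acc:.0f}%")
print("K=1 genes are homogeneous promoters; higher K marks cell-to-cell "
      "chromatin heterogeneity")
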