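"""PCA of the 11-variable index space, with a biplot image.

The correlation-matrix PCA condenses Yp, Ys and the nine indices into a
few components; typically PC1 captures overall performance (everything but
TOL/SSI loads positively) and PC2 the tolerance-vs-potential contrast, so
genotypes far right on PC1 with moderate PC2 are the selection targets.
"""

from pathlib import Path

import stressidx as sx
from stressidx.plots import plot_biplot

trial = sx.generate_trial(n=30, seed=8)
table = sx.compute_indices(trial)
pca = sx.run_pca(table, trial, mode="correlation")

print("Component  Eigenvalue  Explained%  Cumulative%")
for k in range(4):
    print(
        f"      PC{k + 1}   {pca.eigenvalues[k]:9.3f}  {100 * pca.explained[k]:9.2f}"
        f"  {100 * pca.cumulative[k]:10.2f}"
    )
print("\nPC1 loadings (eigenvector · √eigenvalue):")
print(pca.loadings["PC1"].round(3).to_string())

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = plot_biplot(sx.biplot_data(pca, (1, 2)), out / "example_biplot.png")
print(f"\nBiplot written to {path}: arrows are index loadings, points genotype scores.")
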