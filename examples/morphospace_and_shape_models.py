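"""Build a shape space and test shape-covariate associations.

Generates landmark configurations with one latent shape axis, aligns them
by generalized Procrustes analysis, reduces them with PCA, fits a
permutation (residual-randomization) linear model of shape on a
covariate, and projects a small phylogeny into the morphospace.
"""

import numpy as np
import pandas as pd

from spinemech import morpho, synth

lms, latent = synth.generate_landmark_set(n_specimens=8, k=8, seed=2)
aligned = morpho.gpa(lms)
pca = morpho.shape_pca(aligned)

print(f"GPA converged in {aligned.n_iterations} iterations")
print(
    "variance explained: "
    + ", ".join(
        f"PC{i + 1} {100 * v:.1f}%" for i, v in enumerate(pca.variance_fraction[:3])
    )
)
print(f"|corr(PC1, latent axis)| = {abs(np.corrcoef(pca.scores[:, 0], latent)[0, 1]):.3f}")

# shape ~ covariate, permutation p-value
signal = morpho.procrustes_lm(aligned, latent, n_permutations=999, seed=0)
noise_cov = np.random.default_rng(5).normal(size=lms.n_specimens)
null = morpho.procrustes_lm(aligned, noise_cov, n_permutations=999, seed=0)
print(f"shape ~ latent axis : F = {signal.f_statistic:6.2f}, p = {signal.p_value:.3f}")
print(f"shape ~ noise       : F = {null.f_statistic:6.2f}, p = {null.p_value:.3f}")

# phylomorphospace over the specimens
newick = "((spec00:1,(spec01:1,spec02:0.5):0.5):1,((spec03:1,spec04:1):0.3,(spec05:1,(spec06:0.4,spec07:0.4):0.6):0.7):1);"
nodes, edges = morpho.phylomorphospace(
    morpho.load_tree(newick),
    pd.DataFrame(pca.scores[:, :2], index=list(aligned.ids), columns=["PC1", "PC2"]),
)
print("\nancestral (internal node) scores:")
print(nodes[~nodes.is_tip][["node_id", "PC1", "PC2"]].round(3).to_string(index=False))
print()
print("The latent deformation axis dominates PC1; the true covariate is")
print("detected at the smallest attainable p (1/1000) while an unrelated one")
print("is not; internal-node scores are Brownian ancestral estimates used to")
print("draw the phylogeny inside the morphospace.")
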