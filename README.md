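# scggm — sparse conditional Gaussian graphical models for eQTL-perturbed gene networks

`scggm` learns a gene network **jointly** with the SNPs that directly perturb
it from paired genotype/expression data (genetical-genomics / eQTL studies).
Instead of first estimating a network from expression alone and then mapping
eQTLs gene by gene, it fits a single conditional model

    p(y | x) ∝ exp( -½ yᵀ Λ y - xᵀ Θ y )

for expression traits `y` (p genes) given genotypes `x` (q SNPs, allele
counts):

* `Λ` — the gene network: a sparse precision matrix whose nonzero
  off-diagonals are conditional-dependence edges between genes;
* `Θ` — sparse **direct** SNP→gene perturbation weights (direct eQTLs).

Both are estimated at once by minimizing the convex L1-penalized negative
log-likelihood with an accelerated proximal-gradient solver.  Inference on
the fitted model then separates direct from indirect genetic effects: the
total-effect matrix `B = -ΘΛ⁻¹` shows how each direct perturbation propagates
through the network, decomposes into per-gene relay components, and splits
the observed expression covariance into network-induced and SNP-induced
parts.  Downstream analyses cover hub-gene modules, eQTL hotspots, cis/trans
classification and hypergeometric gene-set enrichment.

Intended users: statistical geneticists and systems biologists analyzing
eQTL datasets, and methodologists benchmarking joint network/eQTL estimation
— the package ships seeded simulators for module-structured and scale-free
networks with known ground truth.

## Worked example

```python
import numpy as np
from scggm import (simulate_cggm_dataset, cross_validate, fit_scggm,
                   indirect_effects, precision_recall, default_grid)

# 30 genes in 3 modules, 60 SNPs, 300 samples, known ground truth
X, Y, truth = simulate_cggm_dataset(p=30, q=60, n=300, seed=11)

grid = default_grid(3, 3)                      # log-spaced 3x3 penalty grid
cv = cross_validate(X, Y, grid, k=5, seed=11)  # five-fold CV
model = fit_scggm(X, Y, *cv.best)

B, Sigma = indirect_effects(model)             # total SNP effects, Cov[y|x]
pr_net = precision_recall(model.Lambda, np.abs(truth.Lambda_true) > 0, symmetric=True)
pr_th  = precision_recall(model.Theta,  np.abs(truth.Theta_true) > 0)
print(f"best penalties      lambda_net={cv.best[0]:g} lambda_perturb={cv.best[1]:g}")
print(f"network  AUPRC {pr_net.auprc:.3f}  (random baseline {pr_net.prevalence:.3f})")
print(f"perturb  AUPRC {pr_th.auprc:.3f}  (random baseline {pr_th.prevalence:.3f})")
```

Output:

```
best penalties      lambda_net=1 lambda_perturb=0.0316228
network  AUPRC 0.543  (random baseline 0.069)
perturb  AUPRC 0.566  (random baseline 0.006)
```

The fitted network recovers the true module edges at ~8× the random-ranking
baseline and the direct perturbations at ~100× theirs; `B` additionally
reveals the indirect effects each eQTL exerts on the rest of its module.

The same workflow is available from the shell:

```bash
scggm simulate --genes 30 --snps 60 --samples 300 --seed 11 --out data/
scggm cv   --genotypes data/genotypes.tsv --expressions data/expressions.tsv \
           --grid 1e-3:1:3 --folds 5 --seed 11 --out cv.json
scggm fit  --genotypes data/genotypes.tsv --expressions data/expressions.tsv \
           --lambda-net 1 --lambda-perturb 0.0316 --out model.json
scggm infer   --model model.json --out inference/
scggm analyze --model model.json --min-neighbors 5 --out analysis/
```

Matrices travel as TSV (samples × columns, full precision); models as
canonical JSON archives whose bytes are reproducible given config and seed.

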