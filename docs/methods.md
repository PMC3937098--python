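# Methods

## Model

`scggm` estimates a **sparse conditional Gaussian graphical model (CGGM)** for
gene-expression traits `y ∈ R^p` conditional on SNP genotypes `x ∈ R^q`:

    p(y | x) = exp( -½ yᵀ Λ y - xᵀ Θ y ) / Z(x)
    log Z(x) = ½ xᵀ Θ Λ⁻¹ Θᵀ x + (p/2) log 2π - ½ log det Λ

* `Λ` (p×p, symmetric positive definite) is the precision matrix of the gene
  network: a nonzero off-diagonal `Λ_jk` is a conditional-dependence edge
  between genes j and k given all other genes and all SNPs.
* `Θ` (q×p) holds **direct** SNP→gene perturbation weights; a nonzero `Θ_ij`
  means SNP i is an eQTL acting on gene j directly rather than through the
  network.

Completing the square gives the regression view `y | x ~ N(Bᵀx, Σ)` with
`Σ = Λ⁻¹` and `B = -ΘΛ⁻¹`: `B` contains the **total** SNP effects after
propagation through the network.  The sign convention (minus sign on the
cross term, hence `B = -ΘΛ⁻¹`) is fixed throughout; flipping the sign of `Θ`
only flips `B` and changes nothing else.

Assumptions: expressions are mean-centered per gene and genotypes (allele
counts in {0,1,2}) standardized per SNP before estimation; the conditional
distribution is Gaussian with a covariance that does not depend on `x`;
samples are i.i.d.  Constant genotype columns are an error, not silently
dropped, and fewer than two samples are rejected.

## Estimation

The estimator minimizes the per-sample penalized negative log-likelihood

    ℓ(Λ, Θ) + λ_net Σ_{j≠k} |Λ_jk| + λ_perturb Σ_{ij} |Θ_ij| ,
    ℓ = ½tr(ΛSyy) + ⟨Θ, Sxy⟩ + ½tr(Sxx Θ Λ⁻¹ Θᵀ) - ½log det Λ + (p/2)log 2π ,

a jointly convex problem whose data enter only through the covariance blocks
`Sxx = XᵀX/n`, `Syy = YᵀY/n`, `Sxy = XᵀY/n`.  The diagonal of `Λ` is not
penalized.  Expressing ℓ per sample keeps penalty scales comparable across
sample sizes, the same convention as the common graphical-lasso
implementations, so cross-validated grids transfer between datasets.

The solver is an accelerated proximal-gradient method (FISTA-type two-sequence
Nesterov scheme) with:

* **backtracking line search** (factor 0.5, initial step 1.0) on the quadratic
  majorizer of the smooth part;
* **positive definiteness by barrier, not projection** — a trial `Λ` that
  fails Cholesky evaluates to +∞ and the line search shrinks the step; the
  `-½log det Λ` term guarantees the minimizer is interior;
* **monotone restart** — if an accelerated step would increase the objective
  over the best accepted value, the momentum is reset at the best iterate
  (after which the majorizer argument guarantees descent), so the accepted
  objective trace is non-increasing by construction;
* **stopping** on relative change of the accepted objective below `tol`
  (default 1e-6) or `max_iter` (default 2000).  Non-convergence returns the
  model with `converged=False` and a logged warning rather than raising.

Initialization is `Λ⁰ = I`, `Θ⁰ = 0`; convexity makes the optimum independent
of it.  At convergence the subgradient optimality conditions hold to solver
accuracy (`kkt_violation` reports the maximal violation; the unit tests check
it at ~1e-5 for tight tolerances).

Per iteration the dominant costs are one Cholesky of `Λ` (O(p³)) and the
products with `Sxx` (O(q²p + qp²)); a fit at p=500 genes, q=1000 SNPs,
n=300 samples runs in seconds per iteration on one core.

Two limits recover classical estimators and are used as the internal
"two-stage" baseline: `λ_perturb → ∞` forces `Θ = 0` and leaves the
graphical-lasso problem on `Syy` (verified against scikit-learn's
`graphical_lasso` with `alpha = 2·λ_net`, the factor coming from the ½-scaled
likelihood and the double-counted off-diagonal); `λ_net → ∞` forces
off-diagonal `Λ` to zero, decoupling the problem into per-gene sparse
regressions.

### Penalty selection

`cross_validate` performs k-fold CV (default 5) over a user grid (default
log-spaced over [1e-3, 1] for standardized inputs).  Folds are contiguous
blocks of a seeded permutation; each training fold is centered/standardized
with its own statistics, which are then applied to the held-out fold.  The CV
error is the mean squared prediction error of `E[y|x] = Bᵀx` per held-out
sample and gene; exact ties break toward the larger `λ_net + λ_perturb`
(the sparser model).  Grid points are fit warm-started from the most to the
least penalized; duplicated grid points share one fit.

A known behavior of squared-error CV for this model: the error depends on the
parameters only through `B`, so it carries weak signal about the network
block, and on data where the network contributes little to prediction it can
select the largest `λ_net`.  Held-out predictive likelihood (which scores `Λ`
directly) is computed inside the two-stage baseline's network selection and
can be adopted for the joint model by the caller.

## Inference on a fitted model

* `indirect_effects` — `B = -ΘΛ⁻¹` (by Cholesky solve, no explicit inverse)
  and `Σ = Λ⁻¹`.  `B_ij ≠ 0` with `Θ_ij = 0` flags an **indirect** eQTL:
  SNP i reaches gene j only through the network; effects never leave a
  connected component of the `Λ` graph.
* `decompose_effects` — `B = Σ_k B_k` with `B_k = -Θ[:,k] ⊗ Σ[k,:]`, one rank-1
  component per directly perturbed gene k, quantifying how each perturbed gene
  relays its SNP effects onward.  The components sum to `B` exactly.
* `decompose_covariance` — at the unpenalized optimum the stationarity
  condition matches model and empirical second moments, giving
  `Syy = Λ⁻¹ + Bᵀ Sxx B`: observed expression covariance splits into a
  network-induced and a SNP-induced part.  The L1 penalty biases the fit, so
  for penalized models the identity holds only approximately; the relative
  Frobenius residual is reported (≈3e-7 for an unpenalized fit at n=2000,
  ≈0.09 for the same data at λ=0.1 — see `scripts/acceptance.py`).
* Support of estimated matrices is defined by |entry| > 1e-8: proximal steps
  produce exact zeros, but serialization and downstream arithmetic warrant a
  tolerance.

## Synthetic data

The generators reproduce the statistical structure the model assumes, with
every parameter explicit and seeded (all generators are pure functions of
their arguments):

* **Module networks** — genes randomly partitioned into `n_modules` (default
  3) similar-sized modules; edge probability `p_within = 0.2` inside,
  `p_between = 0.01` across; edge weights `U(0.4, 0.8)`; `Λ*` is the graph
  Laplacian plus `diag_jitter = 0.1` on the diagonal, hence PD by construction
  (row sums equal the jitter).  The defaults were chosen once to give
  well-conditioned, recoverable instances at the default problem size
  (30 genes, 60 SNPs, 300 samples).
* **Scale-free networks** — node degrees drawn from a discrete power law
  `P(k) ∝ k^-γ` (default γ = 2.5), repaired to a graphical sequence (parity
  fix, then Erdős–Gallai-guided capping), realized by Havel–Hakimi and
  randomized with seeded double-edge swaps; weights and Laplacian as above.
* **Direct perturbations** — magnitudes `U(0.6, 1.0)` with random signs;
  patterns: one perturbed gene per module (each SNP hits it with probability
  0.05), uniform Bernoulli over all SNP–gene pairs, or uniform plus one extra
  eQTL per hub gene.
* **Genotypes** — two haplotypes per sample from a Gaussian-copula AR(1)
  process (autocorrelation = `ld_decay`, default 0.5), thresholded at the
  per-site allele-frequency quantile (frequencies `U(maf_lo, maf_hi)`,
  default U(0.1, 0.5)), summed to allele counts {0,1,2}.  Marginal
  frequencies are exact and neighbor LD decays geometrically.
* **Expressions** — rows drawn from `N(B*ᵀx, Λ*⁻¹)` against standardized
  genotypes, or from the pleiotropic regression design `Y = XB* + E` in which
  every gene of a module shares its eQTL SNPs (each SNP selected with
  probability 0.05 per module).  For the regression design the equivalent
  CGGM parameterization `Θ* = -B*Λ*` is stored alongside `B*`.

What the simulator does **not** emulate: population structure, linkage beyond
first-order LD, non-Gaussian expression noise, heteroscedasticity,
genotype-dependent noise covariance, or missing data.  Tests passing on these
data therefore establish correctness of the estimator and inference under the
model's own assumptions, not robustness to real-data violations of them.

## Evaluation

Support recovery is scored exactly as ranked-retrieval: entries of an
estimated matrix are ordered by descending absolute value (ties entering as
one group, so curves are deterministic), swept against the true support,
and summarized by the trapezoid area under the precision–recall curve,
anchored at recall 0 with the first group's precision.  Network PR uses only
the strict upper triangle — self-edges are never network claims.  The
random-ranking baseline is the prevalence of true entries; random-permutation
AUPRC concentrates there with a small upward finite-sample bias.  Prediction
error is `Σᵢ‖yᵢ - Bᵀxᵢ‖² / (n_test·p)`; any positive scaling preserves
method ordering.

The benchmark experiments in `scripts/acceptance.py` use 30 genes / 60 SNPs /
300 samples with a 3×3 CV grid and 3 simulation replicates, and a 500-gene
scale-free network for the degree-distribution fit — sizes chosen so the full
recomputation stays at desk scale.  Typical recovery margins are several-fold
above the network prevalence baseline (seed-dependent, as CV occasionally
selects the largest λ_net) and two orders of magnitude above the perturbation
prevalence baseline.

## Serialization and determinism

Models are archived as canonical JSON — sorted keys, sparse triplets, floats
rendered by `repr` (shortest round-trip representation) — rather than a
compressed binary container: exact reproducibility is then auditable with a
byte comparison, and the pipeline test asserts byte-identical archives for
identical config and seed.  Matrix TSVs are written with `repr` floats and
read back with pandas' round-trip parser, so write/read is bit-exact.

## Known limitations

* First-order solver: parameter accuracy scales like the square root of the
  objective tolerance; tight tolerances (1e-10 and below) are cheap at small
  p but the default 1e-6 is deliberately modest for grids.
* Squared-error CV's weak `λ_net` signal (above).
* The hypergeometric enrichment requires an explicit gene universe — the
  choice changes p-values by tens of orders of magnitude and no default can
  be safely assumed.
* cis/trans classification uses a fixed window (default 20 kb) around the SNP
  interval, a proxy for dataset-specific linkage extents.
* No discrete genotype likelihood: allele counts enter as standardized
  numeric covariates.
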