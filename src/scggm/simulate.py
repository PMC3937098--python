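"""Synthetic genotype/expression generators with known network ground truth.

The generators reproduce the statistical structure assumed by the model:

* gene networks built as graph Laplacians of random weighted graphs — either
  module-structured (dense within modules, sparse between) or scale-free
  (degrees drawn from a discrete power law) — with a small positive jitter
  added to the diagonal to make the precision matrix positive definite;
* sparse direct-perturbation matrices Θ* with uniformly drawn effect sizes
  and random signs, under several sparsity patterns (one perturbed gene per
  module, uniform, or uniform plus extra eQTLs for hub genes);
* genotypes as sums of two haplotypes from a Gaussian-copula AR(1) process,
  giving {0,1,2} allele counts with controllable allele frequencies and
  neighbor LD;
* expressions sampled from the conditional Gaussian y|x ~ N(B*ᵀx, Λ*⁻¹), or
  from a pleiotropic multivariate linear-regression design Y = XB* + E where
  all genes of a module share their eQTL SNPs.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import scipy.linalg
from scipy.stats import norm

from .model import GeneExpressionMatrix, GenotypeMatrix, _cholesky

__all__ = [
    "NetworkSpec",
    "GroundTruth",
    "make_module_network",
    "make_scalefree_network",
    "make_direct_perturbations",
    "simulate_genotypes",
    "sample_expressions",
    "sample_regression_design",
    "simulate_cggm_dataset",
]


@dataclass
class NetworkSpec:
    """Parameters of a random gene-network precision matrix.

    Defaults give a well-conditioned, recoverable module design: 30 genes in
    3 modules, within-module edge probability 0.2, between-module 0.01, edge
    weights U(0.4, 0.8), diagonal jitter 0.1.
    """

    p: int = 30
    topology: str = "module"  # "module" | "scalefree"
    n_modules: int = 3
    p_within: float = 0.2
    p_between: float = 0.01
    degree_exponent: float = 2.5
    weight_lo: float = 0.4
    weight_hi: float = 0.8
    diag_jitter: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be positive")
        if self.topology not in ("module", "scalefree"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("need 0 <= p_between <= p_within <= 1")
        if not self.weight_lo < self.weight_hi:
            raise ValueError("need weight_lo < weight_hi")
        if self.diag_jitter <= 0:
            raise ValueError("diag_jitter must be positive")
        if self.topology == "scalefree" and self.degree_exponent <= 1:
            raise ValueError("degree_exponent must exceed 1")


@dataclass
class GroundTruth:
    """True model parameters behind a simulated dataset."""

    Lambda_true: np.ndarray
    Theta_true: np.ndarray
    B_true: np.ndarray
    modules: list[list[int]] | None = None
    generator_params: dict = field(default_factory=dict)


def _laplacian_from_edges(p: int, edges: list[tuple[int, int]],
                          weights: np.ndarray, diag_jitter: float) -> np.ndarray:
    """Graph Laplacian of the weighted edge list, plus jitter·I on the diagonal."""
    Lam = np.zeros((p, p))
    for (i, j), w in zip(edges, weights):
        Lam[i, j] -= w
        Lam[j, i] -= w
        Lam[i, i] += w
        Lam[j, j] += w
    Lam[np.diag_indices(p)] += diag_jitter
    return Lam


def _partition_modules(p: int, n_modules: int, rng: np.random.Generator) -> list[list[int]]:
    perm = rng.permutation(p)
    bounds = np.linspace(0, p, n_modules + 1).astype(int)
    return [sorted(int(g) for g in perm[bounds[m]:bounds[m + 1]]) for m in range(n_modules)]


def make_module_network(spec: NetworkSpec) -> tuple[np.ndarray, list[list[int]]]:
    """Module-structured precision matrix.

    Genes are randomly partitioned into modules of similar size; each gene
    pair is connected with probability ``p_within`` inside a module and
    ``p_between`` across modules.  Edge weights are U(weight_lo, weight_hi);
    the precision matrix is the graph Laplacian plus ``diag_jitter``·I, hence
    positive definite by construction (row sums equal the jitter).

    Returns (Λ*, module partition).
    """
    if spec.topology != "module":
        raise ValueError("spec.topology must be 'module'")
    rng = np.random.default_rng(spec.seed)
    modules = _partition_modules(spec.p, spec.n_modules, rng)
    member = np.empty(spec.p, dtype=int)
    for m, genes in enumerate(modules):
        member[genes] = m
    edges = []
    for i in range(spec.p):
        for j in range(i + 1, spec.p):
            prob = spec.p_within if member[i] == member[j] else spec.p_between
            if rng.random() < prob:
                edges.append((i, j))
    weights = rng.uniform(spec.weight_lo, spec.weight_hi, size=len(edges))
    Lam = _laplacian_from_edges(spec.p, edges, weights, spec.diag_jitter)
    _cholesky(Lam)  # construction guarantees PD; fail loudly if not
    return Lam, modules


def _power_law_degrees(p: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Degrees from a truncated discrete power law P(k) ∝ k^-exponent, k=1..p-1."""
    ks = np.arange(1, p)
    probs = ks.astype(float) ** (-exponent)
    probs /= probs.sum()
    return rng.choice(ks, size=p, p=probs)


def make_scalefree_network(spec: NetworkSpec, max_retries: int = 50) -> np.ndarray:
    """Scale-free precision matrix.

    Node degrees are drawn from a discrete power law with the given exponent
    and repaired to the nearest graphical sequence (parity fix, then capping
    of infeasible high degrees under the Erdős–Gallai condition).  The graph
    is realized by the Havel–Hakimi construction and randomized with seeded
    double-edge swaps; weights and Laplacian as in :func:`make_module_network`.
    """
    if spec.topology != "scalefree":
        raise ValueError("spec.topology must be 'scalefree'")
    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_retries):
        degs = _power_law_degrees(spec.p, spec.degree_exponent, rng)
        if degs.sum() % 2 == 1:
            # parity repair: drop one degree-1 node to 0 if possible, else decrement max
            ones = np.flatnonzero(degs == 1)
            if ones.size:
                degs[ones[0]] = 0
            else:
                degs[np.argmax(degs)] -= 1
        seq = sorted(int(d) for d in degs)
        while seq and not nx.is_graphical(seq):
            # cap the largest degree until the sequence is graphical
            i = len(seq) - 1
            seq[i] -= 2
            if seq[i] < 0:
                seq[i] = 0
            seq.sort()
        if seq and sum(seq) > 0:
            G = nx.havel_hakimi_graph(seq)
            n_swaps = 2 * G.number_of_edges()
            if G.number_of_edges() >= 2:
                try:
                    nx.double_edge_swap(
                        G, nswap=n_swaps, max_tries=50 * n_swaps,
                        seed=int(rng.integers(2**31)),
                    )
                except nx.NetworkXError:
                    pass  # too few swappable pairs; keep the deterministic graph
            edges = [tuple(sorted(e)) for e in G.edges()]
            weights = rng.uniform(spec.weight_lo, spec.weight_hi, size=len(edges))
            Lam = _laplacian_from_edges(spec.p, edges, weights, spec.diag_jitter)
            _cholesky(Lam)
            return Lam
    raise RuntimeError(f"could not realize a graphical degree sequence in {max_retries} tries")


def make_direct_perturbations(
    p: int,
    q: int,
    pattern: str = "per_module_single_gene",
    perturb_prob: float = 0.05,
    effect_lo: float = 0.6,
    effect_hi: float = 1.0,
    random_signs: bool = True,
    modules: list[list[int]] | None = None,
    hub_genes: list[int] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Sparse direct-perturbation matrix Θ* (q SNPs × p genes).

    Patterns
    --------
    per_module_single_gene
        One randomly chosen gene per module; each SNP perturbs it with
        probability ``perturb_prob`` (at most one nonzero column per module).
    uniform
        Every (SNP, gene) entry is nonzero independently with probability
        ``perturb_prob``.
    hub_extra
        The uniform pattern, plus one additional randomly chosen SNP as an
        eQTL for every gene listed in ``hub_genes``.

    Nonzero magnitudes are U(effect_lo, effect_hi) with random signs.
    """
    if not 0.0 <= perturb_prob <= 1.0:
        raise ValueError("perturb_prob must be in [0, 1]")
    if effect_lo > effect_hi:
        raise ValueError("need effect_lo <= effect_hi")
    rng = np.random.default_rng(seed)
    Theta = np.zeros((q, p))
    if pattern == "per_module_single_gene":
        if modules is None:
            raise ValueError("per_module_single_gene pattern requires a module partition")
        for genes in modules:
            target = int(rng.choice(genes))
            mask = rng.random(q) < perturb_prob
            Theta[mask, target] = _draw_effects(mask.sum(), effect_lo, effect_hi,
                                                random_signs, rng)
    elif pattern == "uniform":
        mask = rng.random((q, p)) < perturb_prob
        Theta[mask] = _draw_effects(int(mask.sum()), effect_lo, effect_hi, random_signs, rng)
    elif pattern == "hub_extra":
        mask = rng.random((q, p)) < perturb_prob
        Theta[mask] = _draw_effects(int(mask.sum()), effect_lo, effect_hi, random_signs, rng)
        for g in hub_genes or []:
            snp = int(rng.integers(q))
            Theta[snp, g] = _draw_effects(1, effect_lo, effect_hi, random_signs, rng)[0]
    else:
        raise ValueError(f"unknown perturbation pattern {pattern!r}")
    return Theta


def _draw_effects(n: int, lo: float, hi: float, random_signs: bool,
                  rng: np.random.Generator) -> np.ndarray:
    vals = rng.uniform(lo, hi, size=n)
    if random_signs:
        vals *= rng.choice((-1.0, 1.0), size=n)
    return vals


def simulate_genotypes(
    n: int,
    q: int,
    maf_lo: float = 0.1,
    maf_hi: float = 0.5,
    ld_decay: float = 0.5,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Genotypes with LD structure, emulating a dense SNP panel.

    Each of two haplotypes per sample is generated from a Gaussian-copula
    AR(1) process with autocorrelation ``ld_decay``; site j carries allele 1
    when the latent Gaussian falls below the quantile of its allele frequency
    f_j ~ U(maf_lo, maf_hi).  Marginal frequencies are exact; neighbor
    correlation decays geometrically.  Genotype = haplotype sum ∈ {0,1,2}.
    Constant columns are resampled so standardization never fails.
    """
    if not (0.0 < maf_lo <= maf_hi <= 0.5):
        raise ValueError("need 0 < maf_lo <= maf_hi <= 0.5")
    if not (0.0 <= ld_decay < 1.0):
        raise ValueError("need 0 <= ld_decay < 1")
    if n < 1 or q < 1:
        raise ValueError("n and q must be positive")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_lo, maf_hi, size=q)
    thresholds = norm.ppf(freqs)

    def haplotypes() -> np.ndarray:
        z = np.empty((n, q))
        z[:, 0] = rng.standard_normal(n)
        innov_sd = np.sqrt(1.0 - ld_decay**2)
        for j in range(1, q):
            z[:, j] = ld_decay * z[:, j - 1] + innov_sd * rng.standard_normal(n)
        return (z < thresholds).astype(float)

    X = haplotypes() + haplotypes()
    # resample constant columns (rare at moderate n·maf)
    for _ in range(100):
        const = np.flatnonzero(X.std(axis=0) == 0.0)
        if not const.size:
            break
        for j in const:
            hap = (rng.standard_normal((n, 2)) < thresholds[j]).astype(float)
            X[:, j] = hap.sum(axis=1)
    else:
        raise RuntimeError("could not avoid constant genotype columns")
    sample_ids = [f"s{i}" for i in range(n)]
    snp_ids = [f"snp{j}" for j in range(q)]
    return GenotypeMatrix(X, snp_ids, sample_ids, standardized=False)


def sample_expressions(
    truth: GroundTruth,
    X: GenotypeMatrix,
    seed: int | None = None,
) -> GeneExpressionMatrix:
    """Draw expressions from the conditional Gaussian y|x ~ N(B*ᵀx, Λ*⁻¹)."""
    if not X.standardized:
        raise ValueError("genotypes must be standardized before sampling expressions")
    rng = np.random.default_rng(seed)
    L = _cholesky(truth.Lambda_true)
    p = truth.Lambda_true.shape[0]
    n = X.n_samples
    mean = X.values @ truth.B_true
    z = rng.standard_normal((n, p))
    # noise with covariance Λ⁻¹ = (LLᵀ)⁻¹: e = L⁻ᵀ z
    noise = scipy.linalg.solve_triangular(L, z.T, lower=True, trans="T").T
    gene_ids = [f"g{j}" for j in range(p)]
    return GeneExpressionMatrix(mean + noise, gene_ids, list(X.sample_ids), centered=False)


def sample_regression_design(
    p: int = 30,
    q: int = 60,
    n: int = 300,
    network_spec: NetworkSpec | None = None,
    eqtl_prob: float = 0.05,
    effect_lo: float = 0.6,
    effect_hi: float = 1.0,
    maf_lo: float = 0.1,
    maf_hi: float = 0.5,
    ld_decay: float = 0.5,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, GeneExpressionMatrix, GroundTruth]:
    """Pleiotropic linear-regression design Y = XB* + E.

    Noise rows are N(0, Λ*⁻¹) with Λ* a module network; each SNP is chosen
    (with probability ``eqtl_prob``) as an eQTL for *all* genes of a module
    simultaneously, giving constant support across each module's columns of
    B*.  Returns (X raw allele counts, Y, truth with B* and the equivalent
    Θ* = -B*Λ*); expressions are sampled against the standardized genotypes.
    """
    rng = np.random.default_rng(seed)
    spec = network_spec or NetworkSpec(p=p, seed=int(rng.integers(2**31)))
    if spec.p != p:
        raise ValueError("network_spec.p must equal p")
    Lam, modules = make_module_network(spec)
    B = np.zeros((q, p))
    for genes in modules:
        snp_mask = rng.random(q) < eqtl_prob
        for snp in np.flatnonzero(snp_mask):
            vals = _draw_effects(len(genes), effect_lo, effect_hi, True, rng)
            B[snp, genes] = vals
    X = simulate_genotypes(n, q, maf_lo, maf_hi, ld_decay,
                           seed=int(rng.integers(2**31)))
    E_seed = int(rng.integers(2**31))
    truth = GroundTruth(
        Lambda_true=Lam,
        Theta_true=-B @ Lam,
        B_true=B,
        modules=modules,
        generator_params={
            "design": "regression", "p": p, "q": q, "n": n, "eqtl_prob": eqtl_prob,
            "effect_lo": effect_lo, "effect_hi": effect_hi, "seed": seed,
            "network": asdict(spec),
        },
    )
    Y = sample_expressions(truth, X.standardize(), seed=E_seed)
    return X, Y, truth


def simulate_cggm_dataset(
    p: int = 30,
    q: int = 60,
    n: int = 300,
    network_spec: NetworkSpec | None = None,
    pattern: str = "per_module_single_gene",
    perturb_prob: float = 0.05,
    effect_lo: float = 0.6,
    effect_hi: float = 1.0,
    maf_lo: float = 0.1,
    maf_hi: float = 0.5,
    ld_decay: float = 0.5,
    hub_min_neighbors: int = 20,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, GeneExpressionMatrix, GroundTruth]:
    """End-to-end conditional-Gaussian dataset with known (Λ*, Θ*).

    Builds the network (module or scale-free per ``network_spec``), the direct
    perturbations, LD-structured genotypes, and conditional expression draws.
    For the ``hub_extra`` pattern, hub genes are those with more than
    ``hub_min_neighbors`` network neighbors.
    """
    rng = np.random.default_rng(seed)
    spec = network_spec or NetworkSpec(p=p, seed=int(rng.integers(2**31)))
    if spec.p != p:
        raise ValueError("network_spec.p must equal p")
    if spec.topology == "module":
        Lam, modules = make_module_network(spec)
    else:
        Lam = make_scalefree_network(spec)
        modules = None
    hub_genes = None
    if pattern == "hub_extra":
        neighbor_counts = (np.abs(Lam) > 1e-12).sum(axis=1) - 1
        hub_genes = [int(g) for g in np.flatnonzero(neighbor_counts > hub_min_neighbors)]
    Theta = make_direct_perturbations(
        p, q, pattern=pattern, perturb_prob=perturb_prob,
        effect_lo=effect_lo, effect_hi=effect_hi, modules=modules,
        hub_genes=hub_genes, seed=int(rng.integers(2**31)),
    )
    B = -np.linalg.solve(Lam, Theta.T).T
    X = simulate_genotypes(n, q, maf_lo, maf_hi, ld_decay,
                           seed=int(rng.integers(2**31)))
    truth = GroundTruth(
        Lambda_true=Lam,
        Theta_true=Theta,
        B_true=B,
        modules=modules,
        generator_params={
            "design": "cggm", "p": p, "q": q, "n": n, "pattern": pattern,
            "perturb_prob": perturb_prob, "effect_lo": effect_lo,
            "effect_hi": effect_hi, "maf_lo": maf_lo, "maf_hi": maf_hi,
            "ld_decay": ld_decay, "seed": seed, "network": asdict(spec),
        },
    )
    Y = sample_expressions(truth, X.standardize(), seed=int(rng.integers(2**31)))
    return X, Y, truth
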