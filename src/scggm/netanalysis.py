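"""Downstream analyses of a fitted gene network and its eQTL perturbations.

Given an estimated precision matrix Λ and direct-perturbation matrix Θ, these
utilities compute weighted node degrees and a power-law fit of the cumulative
degree distribution (scale-freeness check), hub-gene modules (a high-degree
gene with its immediate neighbors), eQTL hotspots (SNPs directly perturbing
the most genes), cis/trans classification of SNP–gene pairs from genomic
coordinates, and hypergeometric (Fisher's exact, one-sided) gene-set
enrichment of gene modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GenomicInterval",
    "EnrichmentResult",
    "weighted_degree",
    "hub_modules",
    "eqtl_hotspots",
    "powerlaw_fit",
    "cis_trans_classify",
    "hypergeom_enrichment",
]

#: |entry| threshold defining an edge / a regulated gene in fitted matrices
SUPPORT_TOL = 1e-8


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start > self.end:
            raise ValueError(f"interval {self.id}: start {self.start} > end {self.end}")


@dataclass
class EnrichmentResult:
    """One-sided over-representation test of a gene module in a category."""

    module_size: int
    category_size: int
    overlap: int
    universe_size: int
    p_value: float


def weighted_degree(Lambda: np.ndarray) -> np.ndarray:
    """Per-gene weighted degree: sum of |off-diagonal| entries in its row."""
    Lambda = np.asarray(Lambda, dtype=float)
    if Lambda.ndim != 2 or Lambda.shape[0] != Lambda.shape[1]:
        raise ValueError("Lambda must be square")
    deg = np.abs(Lambda).sum(axis=1) - np.abs(np.diag(Lambda))
    return deg


def hub_modules(
    Lambda: np.ndarray,
    min_neighbors: int,
    gene_ids: list[str] | None = None,
    tol: float = SUPPORT_TOL,
) -> list[tuple[str, list[str]]]:
    """Hub genes and their immediate network neighbors.

    A neighbor is any gene with |Λ_ij| above ``tol``; hubs are genes with at
    least ``min_neighbors`` neighbors, sorted by neighbor count descending
    with ties broken by gene ID.
    """
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    Lambda = np.asarray(Lambda, dtype=float)
    p = Lambda.shape[0]
    ids = gene_ids if gene_ids is not None else [f"g{j}" for j in range(p)]
    adj = np.abs(Lambda) > tol
    np.fill_diagonal(adj, False)
    out = []
    for j in range(p):
        nbrs = np.flatnonzero(adj[j])
        if nbrs.size >= min_neighbors:
            out.append((ids[j], [ids[i] for i in nbrs]))
    out.sort(key=lambda t: (-len(t[1]), t[0]))
    return out


def eqtl_hotspots(
    Theta: np.ndarray,
    top_k: int,
    snp_ids: list[str] | None = None,
    tol: float = SUPPORT_TOL,
) -> list[dict]:
    """Top-k SNPs by number of directly perturbed genes.

    Each hotspot record carries the SNP ID, the count of nonzero Θ entries in
    its row, and the indices/IDs of the regulated genes.  SNPs perturbing no
    gene are excluded; ties break by SNP ID.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    Theta = np.asarray(Theta, dtype=float)
    q = Theta.shape[0]
    ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(q)]
    nz = np.abs(Theta) > tol
    counts = nz.sum(axis=1)
    ranked = sorted((i for i in range(q) if counts[i] > 0), key=lambda i: (-counts[i], ids[i]))
    return [
        {
            "snp": ids[i],
            "n_genes": int(counts[i]),
            "genes": [int(g) for g in np.flatnonzero(nz[i])],
        }
        for i in ranked[:top_k]
    ]


def powerlaw_fit(degrees: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of the log-log empirical cumulative degree distribution.

    Regresses log10(fraction of nodes with degree ≥ d) on log10(d) over the
    distinct positive degrees.  Returns (slope, intercept, r²); a scale-free
    network shows a negative slope.  Degenerate inputs (fewer than 3 positive
    degrees, or all degrees equal) are an error.
    """
    degrees = np.asarray(degrees, dtype=float)
    pos = degrees[degrees > 0]
    if pos.size < 3:
        raise ValueError("need at least 3 positive degrees for a power-law fit")
    uniq = np.unique(pos)
    if uniq.size < 2:
        raise ValueError("all degrees equal; cumulative distribution is a single point")
    frac_ge = np.array([(pos >= d).mean() for d in uniq])
    res = sps.linregress(np.log10(uniq), np.log10(frac_ge))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def cis_trans_classify(
    pairs: list[tuple[str, str]],
    snp_intervals: dict[str, GenomicInterval],
    gene_intervals: dict[str, GenomicInterval],
    window_bp: int = 20_000,
) -> list[dict]:
    """Label SNP–gene pairs cis or trans by genomic overlap.

    A pair is *cis* when the gene's interval overlaps the SNP's interval
    extended by ``window_bp`` on both sides, on the same chromosome (1-based
    inclusive coordinates; touching intervals overlap).  Pairs with missing
    coordinates are labeled ``unknown``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be nonnegative")
    out = []
    for snp_id, gene_id in pairs:
        snp = snp_intervals.get(snp_id)
        gene = gene_intervals.get(gene_id)
        if snp is None or gene is None:
            label = "unknown"
        elif (
            gene.chrom == snp.chrom
            and gene.start <= snp.end + window_bp
            and gene.end >= snp.start - window_bp
        ):
            label = "cis"
        else:
            label = "trans"
        out.append({"snp": snp_id, "gene": gene_id, "label": label})
    return out


def hypergeom_enrichment(
    module_genes: set[str],
    category_genes: set[str],
    universe: set[str],
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    p = P(overlap ≥ observed) when drawing |module| genes without replacement
    from a universe containing |category| category members.  Equivalent to a
    one-sided Fisher's exact test of the 2×2 overlap table.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    if not category_genes <= universe:
        raise ValueError("category genes must be a subset of the universe")
    N = len(universe)
    K = len(category_genes)
    n = len(module_genes)
    k = len(module_genes & category_genes)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        module_size=n, category_size=K, overlap=k, universe_size=N,
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
    )
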