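"""Post-fit inference: indirect perturbation effects and their decompositions.

Given an estimated model (Λ, Θ), inference recovers the regression view
``y|x ~ N(Bᵀx, Σ)`` with ``B = -ΘΛ⁻¹`` and ``Σ = Λ⁻¹``.  The sparsity pattern
of B reveals *indirect* eQTL effects: a SNP directly perturbing one gene
influences every gene reachable from it through the network, and only those.

Two decompositions characterize the perturbation machinery further:

* effect decomposition — B splits into per-gene components
  ``B_k = -Θ[:, k] · Σ[k, :]`` (outer product), one for each directly
  perturbed gene k, showing how each such gene relays its SNP perturbations;
* covariance decomposition — at the unpenalized optimum the observed
  expression covariance satisfies ``Syy = Λ⁻¹ + Bᵀ Sxx B``, splitting it into
  a network-induced and a SNP-induced part; the L1 penalty biases the fit, so
  for penalized models the identity holds only approximately and the residual
  is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CGGMModel, SufficientStats, conditional_moments

__all__ = [
    "InferenceResult",
    "PerturbationDecomposition",
    "CovarianceDecomposition",
    "indirect_effects",
    "decompose_effects",
    "decompose_covariance",
    "classify_effects",
    "SUPPORT_TOL",
]

#: absolute-value threshold defining the support of estimated parameters
SUPPORT_TOL = 1e-8


@dataclass
class InferenceResult:
    """Total (direct + propagated) SNP effects B and conditional covariance Σ."""

    B: np.ndarray
    Sigma: np.ndarray


@dataclass
class PerturbationDecomposition:
    """Per-gene components of B: ``components[i]`` relays gene ``gene_indices[i]``."""

    components: list[np.ndarray]
    gene_indices: list[int]

    def total(self) -> np.ndarray:
        if not self.components:
            raise ValueError("empty decomposition has no shape; use np.zeros explicitly")
        return np.sum(self.components, axis=0)


@dataclass
class CovarianceDecomposition:
    """Split of the observed expression covariance Syy.

    network_part = Λ⁻¹ (PD), snp_part = Bᵀ·Sxx·B (PSD),
    residual = Syy - network_part - snp_part.  ``relative_residual`` is
    ‖residual‖_F / ‖Syy‖_F; near zero for unpenalized fits.
    """

    network_part: np.ndarray
    snp_part: np.ndarray
    residual: np.ndarray
    relative_residual: float


def indirect_effects(model: CGGMModel) -> tuple[np.ndarray, np.ndarray]:
    """Compute ``(B, Σ)``; B solves BΛ = -Θ.

    Effects propagate only within connected components of the Λ graph: with a
    block-diagonal Λ, B is exactly zero outside the blocks containing directly
    perturbed genes, and with a diagonal Λ support(B) = support(Θ).
    """
    return conditional_moments(model)


def infer(model: CGGMModel) -> InferenceResult:
    B, Sigma = conditional_moments(model)
    return InferenceResult(B=B, Sigma=Sigma)


def decompose_effects(model: CGGMModel) -> PerturbationDecomposition:
    """Decompose B over directly perturbed genes.

    For each gene k with a nonzero Θ column, the component
    ``B_k = -Θ[:, k] ⊗ Σ[k, :]`` captures the share of every SNP's total
    effect that flows through gene k; the components sum exactly to B.
    Genes with all-zero Θ columns contribute nothing and are omitted.
    """
    _, Sigma = conditional_moments(model)
    comps: list[np.ndarray] = []
    idx: list[int] = []
    for k in range(model.n_genes):
        col = model.Theta[:, k]
        if np.any(col != 0.0):
            comps.append(-np.outer(col, Sigma[k, :]))
            idx.append(k)
    return PerturbationDecomposition(components=comps, gene_indices=idx)


def decompose_covariance(model: CGGMModel, stats: SufficientStats) -> CovarianceDecomposition:
    """Split Syy into network- and SNP-induced covariance plus residual."""
    if stats.n_genes != model.n_genes or stats.n_snps != model.n_snps:
        raise ValueError("model and sufficient statistics have inconsistent shapes")
    B, Sigma = conditional_moments(model)
    snp_part = B.T @ stats.Sxx @ B
    snp_part = 0.5 * (snp_part + snp_part.T)
    residual = stats.Syy - Sigma - snp_part
    denom = float(np.linalg.norm(stats.Syy))
    rel = float(np.linalg.norm(residual)) / denom if denom > 0 else 0.0
    return CovarianceDecomposition(
        network_part=Sigma, snp_part=snp_part, residual=residual, relative_residual=rel
    )


def classify_effects(model: CGGMModel, tol: float = SUPPORT_TOL) -> np.ndarray:
    """Label each SNP–gene pair: 0 none, 1 direct (Θ≠0), 2 indirect only (Θ=0, B≠0).

    "Direct" pairs may additionally propagate; "indirect" pairs receive the
    SNP's influence purely through the network.
    """
    B, _ = conditional_moments(model)
    direct = np.abs(model.Theta) > tol
    total = np.abs(B) > tol
    labels = np.zeros(model.Theta.shape, dtype=int)
    labels[direct] = 1
    labels[~direct & total] = 2
    return labels
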