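"""Core probability model: the sparse conditional Gaussian graphical model (CGGM).

A CGGM models a vector of gene-expression traits ``y`` (length ``p``)
conditional on a vector of SNP genotypes ``x`` (length ``q``) as

    p(y | x)  ∝  exp( -1/2 yᵀ Λ y  -  xᵀ Θ y )

where ``Λ`` (p×p, symmetric positive definite) is the precision matrix of the
gene network — nonzero off-diagonals are conditional-dependence edges between
genes — and ``Θ`` (q×p) holds direct SNP→gene perturbation weights — nonzeros
are direct eQTL effects.  Completing the square shows the conditional is
Gaussian with mean ``Bᵀx`` and covariance ``Λ⁻¹`` where ``B = -ΘΛ⁻¹``; ``B``
therefore carries the *total* (direct plus network-propagated) SNP effects.

This module defines the data containers and the likelihood machinery (log
partition function, negative log-likelihood and its analytic gradients) that
the penalized estimator in :mod:`scggm.optim` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "NotPositiveDefiniteError",
    "GeneExpressionMatrix",
    "GenotypeMatrix",
    "CGGMModel",
    "SufficientStats",
    "log_partition",
    "conditional_moments",
    "neg_log_likelihood",
    "nll_gradient",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Raised when a gene-network precision matrix fails Cholesky factorization."""


def _cholesky(Lambda: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of ``Lambda``, or :class:`NotPositiveDefiniteError`."""
    try:
        return scipy.linalg.cholesky(Lambda, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            "gene-network precision matrix is not positive definite"
        ) from exc


def _require_symmetric(M: np.ndarray, tol: float, name: str) -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    dev = float(np.max(np.abs(M - M.T))) if M.size else 0.0
    if dev > tol:
        raise ValueError(f"{name} is not symmetric (max asymmetry {dev:.3e} > {tol:g})")


@dataclass
class GeneExpressionMatrix:
    """Expression values, samples × genes.

    ``centered`` records whether each gene (column) has been mean-centered; the
    model assumes zero-mean traits, so estimation requires ``centered=True``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D samples × genes matrix")
        n, p = self.values.shape
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValueError("ID lists do not match expression matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains NaN or infinite values")
        if self.centered:
            col_means = self.values.mean(axis=0) if n else np.zeros(p)
            if n and np.max(np.abs(col_means)) > 1e-10:
                raise ValueError("centered=True but column means are not zero")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def center(self) -> "GeneExpressionMatrix":
        """Return a copy with each gene mean-centered."""
        vals = self.values - self.values.mean(axis=0, keepdims=True)
        return GeneExpressionMatrix(vals, list(self.gene_ids), list(self.sample_ids), centered=True)


@dataclass
class GenotypeMatrix:
    """Genotypes, samples × SNPs, raw values are minor-allele counts in {0, 1, 2}.

    ``standardized`` records whether each SNP (column) has been scaled to mean
    zero and unit variance, the preprocessing the estimator expects.
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D samples × SNPs matrix")
        n, q = self.values.shape
        if len(self.snp_ids) != q or len(self.sample_ids) != n:
            raise ValueError("ID lists do not match genotype matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype matrix contains NaN or infinite values")
        if not self.standardized and self.values.size:
            if not np.isin(self.values, (0.0, 1.0, 2.0)).all():
                bad = np.argwhere(~np.isin(self.values, (0.0, 1.0, 2.0)))[0]
                raise ValueError(
                    f"raw genotype values must be allele counts in {{0,1,2}}; "
                    f"offending cell: sample {self.sample_ids[bad[0]]!r}, "
                    f"SNP {self.snp_ids[bad[1]]!r}"
                )
        if self.standardized and n:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0)
            if np.max(np.abs(mu)) > 1e-8 or np.max(np.abs(sd - 1.0)) > 1e-8:
                raise ValueError("standardized=True but columns are not mean 0, variance 1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def standardize(self) -> "GenotypeMatrix":
        """Return a copy with each SNP scaled to mean 0, unit variance.

        Constant SNP columns carry no information and are an error rather than
        being silently dropped.
        """
        sd = self.values.std(axis=0)
        const = np.flatnonzero(sd == 0.0)
        if const.size:
            raise ValueError(
                f"constant genotype column(s) cannot be standardized: "
                f"{[self.snp_ids[i] for i in const[:5]]}"
            )
        vals = (self.values - self.values.mean(axis=0)) / sd
        return GenotypeMatrix(vals, list(self.snp_ids), list(self.sample_ids), standardized=True)


@dataclass
class CGGMModel:
    """An estimated (or ground-truth) sparse CGGM.

    Attributes
    ----------
    Lambda : (p, p) ndarray
        Gene-network precision matrix; symmetric positive definite.
    Theta : (q, p) ndarray
        Direct SNP-perturbation weight matrix.
    lambda_net, lambda_perturb : float
        L1 penalty strengths used to estimate ``Lambda`` (off-diagonal) and
        ``Theta``; zero for unpenalized or ground-truth models.
    fit_info : dict
        Optimizer record: iteration count, final objective, converged flag.
    """

    Lambda: np.ndarray
    Theta: np.ndarray
    lambda_net: float = 0.0
    lambda_perturb: float = 0.0
    fit_info: dict = field(default_factory=dict)
    gene_ids: list[str] | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.Theta = np.asarray(self.Theta, dtype=float)
        _require_symmetric(self.Lambda, 1e-12, "Lambda")
        if self.Theta.ndim != 2 or self.Theta.shape[1] != self.Lambda.shape[0]:
            raise ValueError(
                f"Theta shape {self.Theta.shape} inconsistent with "
                f"Lambda shape {self.Lambda.shape}"
            )
        if self.lambda_net < 0 or self.lambda_perturb < 0:
            raise ValueError("penalty strengths must be nonnegative")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length mismatch")
        if self.snp_ids is not None and len(self.snp_ids) != self.n_snps:
            raise ValueError("snp_ids length mismatch")

    @property
    def n_genes(self) -> int:
        return self.Lambda.shape[0]

    @property
    def n_snps(self) -> int:
        return self.Theta.shape[0]

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of Λ (raises if Λ is not PD)."""
        return _cholesky(self.Lambda)


@dataclass
class SufficientStats:
    """Sample (cross-)covariance blocks — the only data summary estimation needs.

    ``Sxx = XᵀX/n``, ``Syy = YᵀY/n``, ``Sxy = XᵀY/n`` computed from
    standardized genotypes and centered expressions.
    """

    Sxx: np.ndarray
    Syy: np.ndarray
    Sxy: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.Sxx = np.asarray(self.Sxx, dtype=float)
        self.Syy = np.asarray(self.Syy, dtype=float)
        self.Sxy = np.asarray(self.Sxy, dtype=float)
        _require_symmetric(self.Sxx, 1e-8, "Sxx")
        _require_symmetric(self.Syy, 1e-8, "Syy")
        q, p = self.Sxy.shape
        if self.Sxx.shape != (q, q) or self.Syy.shape != (p, p):
            raise ValueError("sufficient-statistic block shapes are inconsistent")
        if self.n < 2:
            raise ValueError(f"need at least 2 samples, got n={self.n}")

    @property
    def n_genes(self) -> int:
        return self.Syy.shape[0]

    @property
    def n_snps(self) -> int:
        return self.Sxx.shape[0]

    @classmethod
    def from_arrays(cls, X: np.ndarray, Y: np.ndarray) -> "SufficientStats":
        """Build from already-preprocessed numeric arrays (n×q, n×p)."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("genotype and expression sample counts differ")
        n = X.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 samples, got n={n}")
        Sxx = X.T @ X / n
        Syy = Y.T @ Y / n
        Sxy = X.T @ Y / n
        # exact symmetry for downstream tolerance checks
        return cls(0.5 * (Sxx + Sxx.T), 0.5 * (Syy + Syy.T), Sxy, n)

    @classmethod
    def from_data(cls, X: GenotypeMatrix, Y: GeneExpressionMatrix) -> "SufficientStats":
        if not X.standardized:
            raise ValueError("genotypes must be standardized (GenotypeMatrix.standardize)")
        if not Y.centered:
            raise ValueError("expressions must be centered (GeneExpressionMatrix.center)")
        if X.sample_ids != Y.sample_ids:
            raise ValueError("genotype/expression sample IDs are not aligned")
        return cls.from_arrays(X.values, Y.values)


# ---------------------------------------------------------------------------
# Likelihood machinery


def log_partition(model: CGGMModel, x: Sequence[float]) -> float:
    """Log normalizer of the conditional density at covariate vector ``x``.

    Integrating ``exp(-½yᵀΛy - xᵀΘy)`` over y gives

        log Z(x) = ½ xᵀ Θ Λ⁻¹ Θᵀ x + (p/2)·log(2π) - ½·log det Λ.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_snps:
        raise ValueError(f"x has length {x.shape[0]}, expected {model.n_snps}")
    L = model.cholesky()
    p = model.n_genes
    # v = L⁻¹ Θᵀ x  so that xᵀΘΛ⁻¹Θᵀx = ‖v‖²
    v = scipy.linalg.solve_triangular(L, model.Theta.T @ x, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return 0.5 * float(v @ v) + 0.5 * p * LOG_2PI - 0.5 * logdet


def conditional_moments(model: CGGMModel) -> tuple[np.ndarray, np.ndarray]:
    """Regression form of the model: ``E[y|x] = Bᵀx``, ``Cov[y|x] = Σ``.

    Returns ``(B, Sigma)`` with ``B = -ΘΛ⁻¹`` (q×p) and ``Σ = Λ⁻¹`` (p×p).
    """
    L = model.cholesky()
    eye = np.eye(model.n_genes)
    Sigma = scipy.linalg.cho_solve((L, True), eye)
    Sigma = 0.5 * (Sigma + Sigma.T)
    B = -scipy.linalg.cho_solve((L, True), model.Theta.T).T
    return B, Sigma


def neg_log_likelihood(model: CGGMModel, stats: SufficientStats) -> float:
    """Average negative conditional log-likelihood, ``-(1/n) Σᵢ log p(yᵢ|xᵢ)``.

    Closed form (per sample)::

        ℓ = ½ tr(Λ Syy) + <Θ, Sxy> + ½ tr(Sxx Θ Λ⁻¹ Θᵀ)
            - ½ log det Λ + (p/2) log 2π

    The ``-½ log det Λ`` term diverges as Λ approaches singularity, acting as a
    log barrier that keeps penalized estimation inside the PD cone.
    """
    _check_shapes(model, stats)
    L = model.cholesky()
    val, _, _ = _nll_core(model.Lambda, model.Theta, stats, L, want_grad=False)
    return val


def nll_gradient(model: CGGMModel, stats: SufficientStats) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`neg_log_likelihood`.

        ∂ℓ/∂Λ = ½ Syy - ½ Λ⁻¹ - ½ Λ⁻¹ Θᵀ Sxx Θ Λ⁻¹      (symmetric)
        ∂ℓ/∂Θ = Sxy + Sxx Θ Λ⁻¹
    """
    _check_shapes(model, stats)
    L = model.cholesky()
    _, gL, gT = _nll_core(model.Lambda, model.Theta, stats, L, want_grad=True)
    return gL, gT


def _check_shapes(model: CGGMModel, stats: SufficientStats) -> None:
    if stats.n_genes != model.n_genes or stats.n_snps != model.n_snps:
        raise ValueError(
            f"model ({model.n_snps} SNPs × {model.n_genes} genes) inconsistent with "
            f"stats ({stats.n_snps} × {stats.n_genes})"
        )


def _nll_core(
    Lambda: np.ndarray,
    Theta: np.ndarray,
    stats: SufficientStats,
    L: np.ndarray,
    want_grad: bool,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Shared value/gradient kernel given a precomputed Cholesky factor of Λ."""
    p = Lambda.shape[0]
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    W = scipy.linalg.cho_solve((L, True), Theta.T)  # Λ⁻¹Θᵀ, p×q
    ThetaLinvThetaT = Theta @ W  # q×q
    val = (
        0.5 * float(np.sum(Lambda * stats.Syy))
        + float(np.sum(Theta * stats.Sxy))
        + 0.5 * float(np.sum(stats.Sxx * ThetaLinvThetaT))
        - 0.5 * logdet
        + 0.5 * p * LOG_2PI
    )
    if not want_grad:
        return val, None, None
    Linv = scipy.linalg.cho_solve((L, True), np.eye(p))
    SxxW = stats.Sxx @ W.T  # Sxx Θ Λ⁻¹, q×p
    gT = stats.Sxy + SxxW
    gL = 0.5 * (stats.Syy - Linv - W @ SxxW)
    gL = 0.5 * (gL + gL.T)
    return val, gL, gT
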