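"""Penalized estimation of sparse CGGMs by accelerated proximal gradient descent.

The estimator solves the jointly convex problem

    min_{Λ ≻ 0, Θ}  ℓ(Λ, Θ)  +  λ_net · Σ_{i≠j} |Λ_ij|  +  λ_perturb · Σ_{ij} |Θ_ij|

where ℓ is the per-sample negative conditional log-likelihood
(:func:`scggm.model.neg_log_likelihood`).  The diagonal of Λ is not penalized.
The smooth part contains a -½ log det Λ barrier, so no explicit PD projection
is needed: trial points outside the PD cone evaluate to +∞ and the
backtracking line search rejects them.

The solver is a two-sequence accelerated proximal gradient scheme (FISTA-type
Nesterov acceleration) with backtracking on a quadratic majorizer and a
monotone restart: an accelerated step whose objective exceeds the best
accepted value resets the momentum to the best iterate, so the accepted
objective trace is non-increasing.  Convexity guarantees the global optimum
regardless of initialization (Λ⁰ = I, Θ⁰ = 0 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    CGGMModel,
    GeneExpressionMatrix,
    GenotypeMatrix,
    NotPositiveDefiniteError,
    SufficientStats,
    _cholesky,
    _nll_core,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitOptions",
    "CVResult",
    "objective",
    "prox_l1",
    "fit_scggm",
    "fit_from_stats",
    "fit_path",
    "cross_validate",
    "kkt_violation",
    "default_grid",
]


@dataclass
class FitOptions:
    """Solver settings.

    tol is the relative change of the accepted (monotone) objective below
    which iteration stops; backtracking_factor multiplies the step size when
    the quadratic majorizer test fails.
    """

    max_iter: int = 2000
    tol: float = 1e-6
    backtracking_factor: float = 0.5
    initial_step: float = 1.0
    seed: int | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if not 0.0 < self.backtracking_factor < 1.0:
            raise ValueError("backtracking_factor must be in (0, 1)")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")


@dataclass
class CVResult:
    """Cross-validation table over a (λ_net, λ_perturb) grid."""

    grid: list[tuple[float, float]]
    cv_errors: list[dict]  # one row per grid point: mean, sd, per-fold errors
    best: tuple[float, float]
    folds: int

    def as_records(self) -> list[dict]:
        return [
            {"lambda_net": ln, "lambda_perturb": lp, **row}
            for (ln, lp), row in zip(self.grid, self.cv_errors)
        ]


def objective(
    model: CGGMModel,
    stats: SufficientStats,
    lambda_net: float,
    lambda_perturb: float,
) -> float:
    """Penalized negative log-likelihood; Λ's diagonal is excluded from the penalty."""
    if lambda_net < 0 or lambda_perturb < 0:
        raise ValueError("penalty strengths must be nonnegative")
    L = model.cholesky()
    val, _, _ = _nll_core(model.Lambda, model.Theta, stats, L, want_grad=False)
    return val + _penalty(model.Lambda, model.Theta, lambda_net, lambda_perturb)


def _penalty(Lambda: np.ndarray, Theta: np.ndarray, lam_net: float, lam_perturb: float) -> float:
    off = np.abs(Lambda).sum() - np.abs(np.diag(Lambda)).sum()
    return lam_net * float(off) + lam_perturb * float(np.abs(Theta).sum())


def prox_l1(M: np.ndarray, threshold: float, skip_diagonal: bool = False) -> np.ndarray:
    """Elementwise soft-thresholding, ``sign(m)·max(|m|-t, 0)``.

    With ``skip_diagonal`` the diagonal is returned unchanged (the network
    penalty does not touch Λ's diagonal).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    M = np.asarray(M, dtype=float)
    out = np.sign(M) * np.maximum(np.abs(M) - threshold, 0.0)
    if skip_diagonal:
        np.fill_diagonal(out, np.diag(M))
    return out


def _smooth(Lambda: np.ndarray, Theta: np.ndarray, stats: SufficientStats):
    """Smooth part value + Cholesky, or (inf, None) outside the PD cone."""
    try:
        L = _cholesky(Lambda)
    except NotPositiveDefiniteError:
        return np.inf, None
    val, _, _ = _nll_core(Lambda, Theta, stats, L, want_grad=False)
    return val, L


def fit_from_stats(
    stats: SufficientStats,
    lambda_net: float,
    lambda_perturb: float,
    opts: FitOptions | None = None,
    Lambda0: np.ndarray | None = None,
    Theta0: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    snp_ids: list[str] | None = None,
) -> CGGMModel:
    """Solve the penalized problem given sufficient statistics (warm-startable)."""
    if lambda_net < 0 or lambda_perturb < 0:
        raise ValueError("penalty strengths must be nonnegative")
    opts = opts or FitOptions()
    p, q = stats.n_genes, stats.n_snps
    xL = np.eye(p) if Lambda0 is None else np.array(Lambda0, dtype=float)
    xT = np.zeros((q, p)) if Theta0 is None else np.array(Theta0, dtype=float)

    f_x, _ = _smooth(xL, xT, stats)
    if not np.isfinite(f_x):
        raise ValueError("initial Lambda must be positive definite")
    F_best = f_x + _penalty(xL, xT, lambda_net, lambda_perturb)
    bL, bT = xL.copy(), xT.copy()  # best (accepted) iterate
    yL, yT = xL.copy(), xT.copy()  # extrapolated point
    zL_prev, zT_prev = xL.copy(), xT.copy()
    tk = 1.0
    step = opts.initial_step
    beta = opts.backtracking_factor
    trace = [F_best]
    converged = False
    n_restarts = 0
    it = 0

    for it in range(1, opts.max_iter + 1):
        f_y, Ly = _smooth(yL, yT, stats)
        if Ly is None:
            # momentum overshot the PD cone: restart from the best iterate
            yL, yT = bL.copy(), bT.copy()
            zL_prev, zT_prev = bL.copy(), bT.copy()
            tk = 1.0
            n_restarts += 1
            f_y, Ly = _smooth(yL, yT, stats)
        _, gL, gT = _nll_core(yL, yT, stats, Ly, want_grad=True)

        # backtracking on the quadratic majorizer
        while True:
            zL = prox_l1(yL - step * gL, step * lambda_net, skip_diagonal=True)
            zL = 0.5 * (zL + zL.T)
            zT = prox_l1(yT - step * gT, step * lambda_perturb)
            f_z, _ = _smooth(zL, zT, stats)
            dL = zL - yL
            dT = zT - yT
            quad = (
                f_y
                + float(np.sum(gL * dL))
                + float(np.sum(gT * dT))
                + (float(np.sum(dL * dL)) + float(np.sum(dT * dT))) / (2.0 * step)
            )
            if f_z <= quad + 1e-12 * max(1.0, abs(f_y)):
                break
            step *= beta
            if step < 1e-18:
                raise RuntimeError("line search collapsed; data may be degenerate")

        F_z = f_z + _penalty(zL, zT, lambda_net, lambda_perturb)

        if F_z > F_best:
            # monotone restart: drop momentum, recompute from the best point
            yL, yT = bL.copy(), bT.copy()
            zL_prev, zT_prev = bL.copy(), bT.copy()
            tk = 1.0
            n_restarts += 1
            trace.append(F_best)
            continue

        rel_change = (F_best - F_z) / max(1.0, abs(F_best))
        bL, bT, F_best = zL, zT, F_z
        trace.append(F_best)

        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        coef = (tk - 1.0) / t_next
        yL = zL + coef * (zL - zL_prev)
        yT = zT + coef * (zT - zT_prev)
        zL_prev, zT_prev = zL, zT
        tk = t_next

        if opts.verbose and it % 50 == 0:
            logger.info("iter %d  objective %.8f  step %.2e", it, F_best, step)
        if rel_change < opts.tol:
            converged = True
            break

    if not converged:
        logger.warning(
            "sCGGM solver did not converge in %d iterations (last objective %.6g)",
            opts.max_iter,
            F_best,
        )
    fit_info = {
        "iterations": it,
        "objective": F_best,
        "converged": converged,
        "n_restarts": n_restarts,
        "objective_trace": trace,
    }
    return CGGMModel(
        Lambda=bL,
        Theta=bT,
        lambda_net=lambda_net,
        lambda_perturb=lambda_perturb,
        fit_info=fit_info,
        gene_ids=gene_ids,
        snp_ids=snp_ids,
    )


def fit_scggm(
    X: GenotypeMatrix,
    Y: GeneExpressionMatrix,
    lambda_net: float,
    lambda_perturb: float,
    opts: FitOptions | None = None,
) -> CGGMModel:
    """Estimate a sparse CGGM from genotype/expression data.

    Genotypes are standardized and expressions centered if they are not
    already; samples must be aligned by ID.
    """
    if not X.standardized:
        X = X.standardize()
    if not Y.centered:
        Y = Y.center()
    stats = SufficientStats.from_data(X, Y)
    return fit_from_stats(
        stats,
        lambda_net,
        lambda_perturb,
        opts,
        gene_ids=list(Y.gene_ids),
        snp_ids=list(X.snp_ids),
    )


def fit_path(
    X: GenotypeMatrix,
    Y: GeneExpressionMatrix,
    grid: list[tuple[float, float]],
    opts: FitOptions | None = None,
) -> list[CGGMModel | None]:
    """Fit every (λ_net, λ_perturb) grid point, warm-starting along the path.

    Grid points are visited from most to least penalized (sparsest solutions
    first) so warm starts stay feasible; failures are logged and reported as
    ``None`` without aborting the remaining points.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    if not X.standardized:
        X = X.standardize()
    if not Y.centered:
        Y = Y.center()
    stats = SufficientStats.from_data(X, Y)
    return _fit_path_stats(stats, grid, opts, list(Y.gene_ids), list(X.snp_ids))


def _fit_path_stats(
    stats: SufficientStats,
    grid: list[tuple[float, float]],
    opts: FitOptions | None,
    gene_ids: list[str] | None = None,
    snp_ids: list[str] | None = None,
) -> list[CGGMModel | None]:
    # duplicated grid points are fit once and share the identical solution
    unique = sorted(set(grid), key=lambda g: -(g[0] + g[1]))
    fits: dict[tuple[float, float], CGGMModel | None] = {}
    warmL, warmT = None, None
    for ln, lp in unique:
        try:
            m = fit_from_stats(
                stats, ln, lp, opts, Lambda0=warmL, Theta0=warmT,
                gene_ids=gene_ids, snp_ids=snp_ids,
            )
        except (ValueError, RuntimeError, NotPositiveDefiniteError) as exc:
            logger.warning("fit failed at grid point (%g, %g): %s", ln, lp, exc)
            fits[(ln, lp)] = None
            continue
        fits[(ln, lp)] = m
        warmL, warmT = m.Lambda, m.Theta
    return [fits[tuple(g)] for g in grid]


def default_grid(n_net: int = 5, n_perturb: int = 5,
                 lo: float = 1e-3, hi: float = 1.0) -> list[tuple[float, float]]:
    """Log-spaced penalty grid for standardized inputs."""
    lns = np.geomspace(lo, hi, n_net)
    lps = np.geomspace(lo, hi, n_perturb)
    return [(float(a), float(b)) for a in lns for b in lps]


def cross_validate(
    X: GenotypeMatrix,
    Y: GeneExpressionMatrix,
    grid: list[tuple[float, float]],
    k: int = 5,
    opts: FitOptions | None = None,
    seed: int | None = None,
) -> CVResult:
    """k-fold cross-validation of the penalty pair over a grid.

    Each training fold is centered/standardized with its own statistics, which
    are then applied to the held-out fold; the held-out error is the mean
    squared prediction error of E[y|x] (per sample, per gene).  The best pair
    minimizes the mean error; exact ties break toward the larger penalty sum
    (sparser model).
    """
    from .evaluate import prediction_error  # local import to avoid cycle
    from .inference import indirect_effects

    if k < 2:
        raise ValueError("need at least 2 folds")
    n = Y.n_samples
    if k > n:
        raise ValueError(f"more folds ({k}) than samples ({n})")
    if not grid:
        raise ValueError("grid must be nonempty")
    if X.sample_ids != Y.sample_ids:
        raise ValueError("genotype/expression sample IDs are not aligned")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    # contiguous blocks of the seeded permutation
    bounds = np.linspace(0, n, k + 1).astype(int)
    for f in range(k):
        fold_of[perm[bounds[f]:bounds[f + 1]]] = f

    Xraw, Yraw = X.values, Y.values
    errors = np.full((len(grid), k), np.nan)
    for f in range(k):
        test = fold_of == f
        train = ~test
        xm = Xraw[train].mean(axis=0)
        xs = Xraw[train].std(axis=0)
        if np.any(xs == 0.0):
            raise ValueError(f"fold {f}: constant genotype column in training split")
        ym = Yraw[train].mean(axis=0)
        Xtr = (Xraw[train] - xm) / xs
        Ytr = Yraw[train] - ym
        Xte = (Xraw[test] - xm) / xs
        Yte = Yraw[test] - ym
        stats = SufficientStats.from_arrays(Xtr, Ytr)
        models = _fit_path_stats(stats, grid, opts)
        for gi, m in enumerate(models):
            if m is None:
                continue
            B, _ = indirect_effects(m)
            errors[gi, f] = prediction_error(B, Xte, Yte)

    mean_err = np.nanmean(errors, axis=1)
    sd_err = np.nanstd(errors, axis=1)
    best_i = 0
    for i in range(1, len(grid)):
        if mean_err[i] < mean_err[best_i] - 1e-15 or (
            abs(mean_err[i] - mean_err[best_i]) <= 1e-15
            and sum(grid[i]) > sum(grid[best_i])
        ):
            best_i = i
    rows = [
        {
            "mean": float(mean_err[i]),
            "sd": float(sd_err[i]),
            "fold_errors": [float(e) for e in errors[i]],
        }
        for i in range(len(grid))
    ]
    return CVResult(grid=list(grid), cv_errors=rows, best=tuple(grid[best_i]), folds=k)


def kkt_violation(
    model: CGGMModel, stats: SufficientStats
) -> float:
    """Max violation of the subgradient optimality condition of the fitted model.

    At the optimum, for each penalized coordinate with value 0 the gradient
    lies in [-λ, λ]; for a nonzero coordinate, grad + λ·sign(value) = 0.  The
    unpenalized Λ-diagonal must have zero gradient.  Returns the max absolute
    violation over all coordinates.
    """
    from .model import nll_gradient

    gL, gT = nll_gradient(model, stats)
    viol = 0.0
    lam = model.lambda_net
    p = model.n_genes
    for i in range(p):
        for j in range(p):
            g = gL[i, j]
            if i == j:
                viol = max(viol, abs(g))
            elif model.Lambda[i, j] != 0.0:
                viol = max(viol, abs(g + lam * np.sign(model.Lambda[i, j])))
            else:
                viol = max(viol, max(0.0, abs(g) - lam))
    lam = model.lambda_perturb
    nz = model.Theta != 0.0
    viol = max(viol, float(np.max(np.abs(gT + lam * np.sign(model.Theta)) * nz, initial=0.0)))
    viol = max(viol, float(np.max((np.abs(gT) - lam) * ~nz, initial=0.0)))
    return viol
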