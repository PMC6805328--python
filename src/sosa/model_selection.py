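"""Cross-validated choice of the sparsity level lambda (and optionally K).

Three CV schemes mirror common designs for grouped expression data:

* ``group`` — one sample per replicate group goes to each test fold (the
  natural scheme when the grouping itself is of interest and every group
  has replicates);
* ``loo``   — leave-one-out;
* ``kfold`` — k-fold, stratified on the interest classes when they are
  categorical.

For every fold the whole Stage-1 adjustment (projector, surrogate factors,
nuisance coefficients) is re-estimated on the training samples only, so no
test information leaks into the fit; test rows are adjusted with the
train-estimated coefficients (latent-factor scores for test samples are
recovered by least squares against the train-estimated loadings).  The
selection criterion is the held-out optimal-scoring objective, averaged over
folds; ties break toward larger lambda (the more parsimonious model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .adjust import (
    ExpressionMatrix,
    FactorDesign,
    ResidualProjector,
    adjust_heterogeneity,
)
from .scoring import PenaltySpec, fit_sosa, objective

__all__ = [
    "CvScheme",
    "CvResult",
    "make_lambda_grid",
    "cv_select_lambda",
    "estimate_K_parallel_analysis",
]


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation fold layout: ``group``, ``loo`` or ``kfold``."""

    kind: str = "group"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("group", "loo", "kfold"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")
        if self.kind == "kfold" and self.n_folds < 2:
            raise ValueError("kfold needs at least 2 folds")


@dataclass
class CvResult:
    lambdas: np.ndarray
    mean_test_objective: np.ndarray
    per_fold_objectives: np.ndarray  # n_folds x n_lambdas, NaN for skipped folds
    best_lambda: float
    best_index: int
    n_folds_used: int = 0
    fold_assignments: list[np.ndarray] = field(default_factory=list)


def make_lambda_grid(
    lo: float, hi: float, count: int, spacing: str = "log"
) -> np.ndarray:
    """Strictly increasing lambda grid including both endpoints (log-spaced
    by default, since useful sparsity levels span decades)."""
    if lo <= 0:
        raise ValueError("lambda grid lower bound must be positive")
    if count < 1:
        raise ValueError("count must be at least 1")
    if count == 1:
        return np.array([lo])
    if hi <= lo:
        raise ValueError("need lo < hi")
    if spacing == "log":
        grid = np.geomspace(lo, hi, count)
    elif spacing == "linear":
        grid = np.linspace(lo, hi, count)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    grid[0], grid[-1] = lo, hi
    return grid


def _make_folds(design: FactorDesign, scheme: CvScheme) -> list[np.ndarray]:
    n = design.n_samples
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "loo":
        return [np.array([i]) for i in range(n)]
    group_of = np.argmax(design.G, axis=1)
    if scheme.kind == "group":
        sizes = design.G.sum(axis=0).astype(int)
        if np.any(sizes < 2):
            raise ValueError("group scheme requires every group size >= 2")
        members = [rng.permutation(np.flatnonzero(group_of == g))
                   for g in range(design.G.shape[1])]
        n_folds = int(sizes.max())
        return [
            np.sort(np.array([mem[r] for mem in members if len(mem) > r]))
            for r in range(n_folds)
        ]
    # kfold: stratify on the interest classes when categorical
    from sklearn.model_selection import KFold, StratifiedKFold

    M = design.interest_matrix()
    is_indicator = np.all(np.isin(M, (0.0, 1.0))) and np.all(M.sum(axis=1) == 1)
    if is_indicator:
        labels = np.argmax(M, axis=1)
        splitter = StratifiedKFold(
            n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed
        )
        return [test for _, test in splitter.split(np.zeros(n), labels)]
    splitter = KFold(n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed)
    return [test for _, test in splitter.split(np.zeros(n))]


def _subset_design(design: FactorDesign, rows: np.ndarray) -> tuple[FactorDesign, np.ndarray]:
    """Restrict a design to the given rows, dropping emptied group columns.

    Returns the sub-design and the indices of the retained group columns.
    """
    G = design.G[rows]
    keep = np.flatnonzero(G.sum(axis=0) >= 1)
    G = G[:, keep]
    Y = design.Y[rows] if design.Y is not None else None
    sub = FactorDesign(
        G=G,
        group_labels=[design.group_labels[j] for j in keep],
        Y=Y,
        mode=design.mode,
    )
    return sub, keep


def _adjust_test_rows(
    X_test: np.ndarray,
    M_test: np.ndarray,
    G_test: np.ndarray | None,
    beta_hat: np.ndarray,
    alpha_hat: np.ndarray,
    n_known_nuisance: int,
) -> np.ndarray:
    """Apply train-estimated adjustment to held-out rows.

    The known nuisance part of U (the leading ``n_known_nuisance`` rows of
    alpha_hat, batch indicators in supervised mode) is subtracted directly
    using the test samples' own indicators; latent-factor scores for test
    samples are unobserved, so they are recovered by least squares of the
    interest-and-batch residual onto the train-estimated loadings.
    """
    resid = X_test - M_test @ beta_hat
    X_a = X_test.copy()
    if n_known_nuisance:
        aG = alpha_hat[:n_known_nuisance]
        resid = resid - G_test @ aG
        X_a = X_a - G_test @ aG
    aF = alpha_hat[n_known_nuisance:]
    if aF.shape[0]:
        # F_test = argmin || resid - F aF ||  (aF: K x p loadings)
        F_test = np.linalg.lstsq(aF.T, resid.T, rcond=None)[0].T
        X_a = X_a - F_test @ aF
    return X_a


def cv_select_lambda(
    X: ExpressionMatrix,
    design: FactorDesign,
    K: int,
    grid: np.ndarray,
    scheme: CvScheme,
    m: int | None = None,
    penalty: PenaltySpec | None = None,
    l: int | None = None,
    include_penalty_in_test: bool = True,
    surrogate_scope: str = "per-fold",
    max_outer: int = 100,
    tol: float = 1e-6,
) -> CvResult:
    """Select lambda by the held-out optimal-scoring objective.

    ``surrogate_scope="per-fold"`` (default) re-runs Stage 1 inside every
    training fold; ``"global"`` adjusts once on all samples first (faster
    but leaks test rows into the factor estimates — provided for comparison
    only).  Deterministic given ``scheme.seed``.
    """
    grid = np.asarray(grid, dtype=float)
    penalty = penalty or PenaltySpec()
    folds = _make_folds(design, scheme)
    n = X.n_samples
    values = X.values
    if surrogate_scope not in ("per-fold", "global"):
        raise ValueError("surrogate_scope must be 'per-fold' or 'global'")
    X_a_global = None
    if surrogate_scope == "global":
        adj, _, _ = adjust_heterogeneity(X, design, K, m=m)
        X_a_global = adj.X_a

    M_full = design.interest_matrix()
    per_fold = np.full((len(folds), len(grid)), np.nan)
    used = 0
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        sub, kept_groups = _subset_design(design, train_idx)
        # a fold that loses an entire interest class cannot be scored
        if design.mode == "unsupervised":
            if len(kept_groups) < design.G.shape[1]:
                warnings.warn(f"fold {f}: training loses a group; skipped", stacklevel=2)
                continue
            M_test = design.G[test_idx][:, kept_groups]
        else:
            Y = design.Y
            assert Y is not None
            if design._y_is_indicator() and np.any(Y[train_idx].sum(axis=0) < 1):
                warnings.warn(f"fold {f}: training loses an outcome class; skipped",
                              stacklevel=2)
                continue
            M_test = Y[test_idx]
        X_test = values[test_idx]
        sub_X = ExpressionMatrix(
            values=values[train_idx],
            sample_ids=[X.sample_ids[i] for i in train_idx],
            gene_ids=X.gene_ids,
        )
        if surrogate_scope == "global":
            assert X_a_global is not None
            X_a_train = X_a_global[train_idx]
            X_a_test = X_a_global[test_idx]
            M_train = M_full[train_idx] if design.mode == "supervised" else sub.G
        else:
            adj, _, _ = adjust_heterogeneity(sub_X, sub, K, m=m)
            X_a_train = adj.X_a
            M_train = adj.M
            if design.mode == "supervised":
                # nuisance_columns indexes [G_sub | F]; the G columns that
                # survived redundancy removal lead, the factors follow
                g_sub = sub.G.shape[1]
                kept = adj.nuisance_columns or []
                kept_g = [j for j in kept if j < g_sub]
                n_known = len(kept_g)
                G_test = design.G[test_idx][:, kept_groups][:, kept_g]
            else:
                n_known, G_test = 0, None
            X_a_test = _adjust_test_rows(
                X_test, M_test, G_test, adj.beta_hat, adj.alpha_hat, n_known
            )
        used += 1
        for i, lam in enumerate(grid):
            fit = fit_sosa(
                X_a_train, M_train, lam, penalty=penalty, l=l,
                max_outer=max_outer, tol=tol,
            )
            n_test = len(test_idx)
            resid = X_a_test @ fit.B - M_test @ fit.Theta
            val = float(np.sum(resid**2) / n_test)
            if include_penalty_in_test:
                val += lam * penalty.phi(np.linalg.norm(fit.B, axis=1))
            per_fold[f, i] = val
    if used == 0:
        raise ValueError("every CV fold was skipped; scheme incompatible with design")
    means = np.nanmean(per_fold, axis=0)
    # ties break toward the larger lambda (more parsimonious)
    best_index = len(means) - 1 - int(np.argmin(means[::-1]))
    return CvResult(
        lambdas=grid,
        mean_test_objective=means,
        per_fold_objectives=per_fold,
        best_lambda=float(grid[best_index]),
        best_index=best_index,
        n_folds_used=used,
        fold_assignments=folds,
    )


def estimate_K_parallel_analysis(
    X: ExpressionMatrix | np.ndarray,
    R_N: ResidualProjector,
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Optional data-driven choice of the latent-factor count K.

    Parallel analysis: permuting the entries within each column of X
    destroys cross-gene factor structure while keeping marginal scales;
    projecting each permuted matrix through R_N and taking its largest
    singular value gives a null for "top residual singular value under no
    shared factors" that is exactly calibrated under pure noise (the null
    draw then undergoes the same projection as the observed data).  K is the number of observed singular values of R_N X
    exceeding the stated quantile of those per-permutation maxima.  Never
    applied silently — callers must opt in.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    resid = R_N.matrix @ V
    s_obs = np.linalg.svd(resid, compute_uv=False)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    n = resid.shape[0]
    for b in range(n_perm):
        perm = np.empty_like(V)
        for j in range(V.shape[1]):
            perm[:, j] = V[rng.permutation(n), j]
        null_max[b] = np.linalg.svd(R_N.matrix @ perm, compute_uv=False)[0]
    # 'higher' keeps the discrete permutation null conservative: with B
    # permutations the threshold is an exact order statistic, not an
    # interpolation below it
    thresh = np.quantile(null_max, quantile, method="higher")
    return int(np.sum(s_obs > thresh))
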