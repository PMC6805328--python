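"""Stage 1: adjustment of unwanted expression heterogeneity.

Expression data collected in groups (technical replicates, batches,
laboratories) and confounded by unknown latent factors follow, in the most
general form,

    X = N omega + F phi + eps,        eps ~ N(0, sigma^2 I)

where ``N`` collects the *known* factors (the group indicator ``G`` alone in
unsupervised problems, the outcome ``Y`` together with ``G`` in supervised
ones), ``F`` holds ``K`` unknown latent factors and ``phi`` their gene-wise
loadings.  This module removes the known-factor effects by projecting onto
the orthogonal complement of ``span(N)``, estimates the unknown factors from
the residual space by SVD (surrogate extraction followed by a gene-anchored
refinement), and finally builds the adjusted matrix

    X_a = X - U alpha_hat

in which only the factor of interest ``M`` and noise remain.  ``U`` is the
nuisance design: the estimated factors ``F`` alone when the grouping itself
is of interest, ``[G | F]`` when an outcome ``Y`` is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "FactorDesign",
    "ResidualProjector",
    "SurrogateSet",
    "AdjustedData",
    "KnownFactors",
    "build_known_factor_matrix",
    "residual_projector",
    "extract_surrogates",
    "estimate_unknown_factor",
    "build_adjusted",
    "adjust_heterogeneity",
]

# Relative cutoff used everywhere a pseudoinverse or numerical rank is taken.
RANK_RCOND = 1e-10


@dataclass
class ExpressionMatrix:
    """An n-samples x p-genes expression matrix with identifiers.

    Values are arbitrary expression units, typically log scale.  Missing
    values are rejected at construction; imputation (mean fill) is a separate
    explicit choice of the reader.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 gene")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class FactorDesign:
    """Known-factor encodings: group indicator G and optional outcome Y.

    ``mode`` decides which factor is of interest: in ``"unsupervised"`` mode
    the grouping G itself is the interest factor and only latent factors are
    nuisance; in ``"supervised"`` mode the outcome Y is of interest while G
    and the latent factors are nuisance.
    """

    G: np.ndarray
    group_labels: list[str]
    Y: np.ndarray | None = None
    mode: str = "unsupervised"

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-D indicator matrix")
        if not np.all(np.isin(self.G, (0.0, 1.0))):
            raise ValueError("G must be binary")
        if not np.all(self.G.sum(axis=1) == 1):
            raise ValueError("each sample must belong to exactly one group")
        if np.any(self.G.sum(axis=0) < 1):
            raise ValueError("every group needs at least one sample")
        if len(self.group_labels) != self.G.shape[1]:
            raise ValueError("group_labels length does not match G columns")
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.Y is not None:
            self.Y = np.asarray(self.Y, dtype=float)
            if self.Y.ndim == 1:
                self.Y = self.Y[:, None]
            if self.Y.shape[0] != self.G.shape[0]:
                raise ValueError(
                    f"Y has {self.Y.shape[0]} rows but G has {self.G.shape[0]}"
                )
            if self._y_is_indicator() and not np.all(self.Y.sum(axis=1) == 1):
                raise ValueError("indicator Y rows must sum to 1")
        if self.mode == "supervised" and self.Y is None:
            raise ValueError("supervised mode requires an outcome Y")

    def _y_is_indicator(self) -> bool:
        return (
            self.Y is not None
            and self.Y.shape[1] > 1
            and np.all(np.isin(self.Y, (0.0, 1.0)))
        )

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    def interest_matrix(self) -> np.ndarray:
        """The factor-of-interest design M: G when unsupervised, Y otherwise."""
        if self.mode == "unsupervised":
            return self.G
        return self.Y  # type: ignore[return-value]


@dataclass
class KnownFactors:
    """Known-factor design N after deterministic redundancy removal."""

    matrix: np.ndarray
    rank: int
    kept_columns: list[int]
    dropped_columns: list[int]


@dataclass
class ResidualProjector:
    """Orthogonal projector R_N = I - N (N^T N)^- N^T onto span(N)'s complement."""

    matrix: np.ndarray
    source_rank: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("projector must be square")

    def __matmul__(self, other: np.ndarray) -> np.ndarray:
        return self.matrix @ other


@dataclass
class SurrogateSet:
    """Surrogate factors h_k (left singular vectors of R_N X) and the matched
    unknown-factor estimates F_k extracted from associated genes."""

    H: np.ndarray
    F: np.ndarray
    match_correlations: list[float] = field(default_factory=list)
    selected_gene_indices: list[list[int]] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.H.shape[1]


@dataclass
class AdjustedData:
    """The adjusted matrix X_a = X - U alpha_hat together with the pieces used."""

    X_a: np.ndarray
    U: np.ndarray
    alpha_hat: np.ndarray
    M: np.ndarray
    beta_hat: np.ndarray
    # indices into the assembled nuisance design (e.g. [G | F]) that survived
    # redundancy removal; None when the caller supplied U directly
    nuisance_columns: list[int] | None = None


def _incremental_independent_columns(
    base: np.ndarray | None, candidates: np.ndarray
) -> tuple[list[int], list[int]]:
    """Greedy left-to-right scan keeping candidate columns that enlarge the
    span of ``base`` plus the columns kept so far.  Deterministic: the
    leftmost of any collinear set survives."""
    n = candidates.shape[0]
    kept: list[int] = []
    dropped: list[int] = []
    blocks = [] if base is None else [base]
    current = np.hstack(blocks) if blocks else np.empty((n, 0))
    rank = np.linalg.matrix_rank(current, tol=None) if current.size else 0
    for j in range(candidates.shape[1]):
        trial = np.hstack([current, candidates[:, j : j + 1]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept.append(j)
            current = trial
            rank = r
        else:
            dropped.append(j)
    return kept, dropped


def build_known_factor_matrix(design: FactorDesign) -> KnownFactors:
    """Assemble the known-factor matrix N of the general model X = N omega + ...

    N = G in unsupervised mode and N = [Y | G] in supervised mode.  An
    indicator Y together with a full indicator G is collinear with the
    all-ones vector, so redundant columns are dropped deterministically
    (leftmost kept) and the drop is recorded.
    """
    if design.mode == "unsupervised":
        N = design.G
    else:
        N = np.hstack([design.Y, design.G])  # type: ignore[list-item]
    if N.shape[1] == 0:
        raise ValueError("empty known-factor design")
    kept, dropped = _incremental_independent_columns(None, N)
    return KnownFactors(
        matrix=N[:, kept], rank=len(kept), kept_columns=kept, dropped_columns=dropped
    )


def residual_projector(N: np.ndarray | KnownFactors) -> ResidualProjector:
    """R_N = I - N (N^T N)^{-1} N^T, the projector onto span(N)'s orthogonal
    complement, computed through a pseudoinverse so near-collinear designs
    are handled gracefully."""
    if isinstance(N, KnownFactors):
        N = N.matrix
    N = np.asarray(N, dtype=float)
    if N.ndim != 2 or N.shape[1] < 1:
        raise ValueError("N must have at least one column")
    n = N.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to form a residual projector")
    R = np.eye(n) - N @ np.linalg.pinv(N, rcond=RANK_RCOND)
    R = (R + R.T) / 2.0  # exact symmetry despite roundoff
    rank = int(np.linalg.matrix_rank(N))
    return ResidualProjector(matrix=R, source_rank=rank)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry positive (first such index on ties)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def extract_surrogates(
    X: ExpressionMatrix | np.ndarray, R_N: ResidualProjector, K: int
) -> SurrogateSet:
    """Surrogate factors h_k: the K leading left singular vectors of R_N X.

    The residual matrix R_N X contains only latent-factor structure and
    noise, so its principal sample-space directions stand in for the unknown
    factors.  Signs are fixed (largest-magnitude loading positive) so the
    output is deterministic.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    resid = R_N.matrix @ V
    if K < 0:
        raise ValueError("K must be non-negative")
    n = V.shape[0]
    if K == 0:
        return SurrogateSet(H=np.empty((n, 0)), F=np.empty((n, 0)))
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    achievable = int(np.sum(s > s[0] * RANK_RCOND)) if s.size else 0
    if K > achievable:
        raise ValueError(
            f"K={K} exceeds the rank of the residual matrix; at most {achievable} "
            "surrogate factors are identifiable"
        )
    H = np.column_stack([_fix_sign(u[:, k]) for k in range(K)])
    return SurrogateSet(H=H, F=np.empty((n, 0)))


def _pearson_with_vector(columns: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each matrix column with v; constant columns -> 0."""
    vc = v - v.mean()
    vn = np.linalg.norm(vc)
    Xc = columns - columns.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ vc) / (norms * vn)
    r[~np.isfinite(r)] = 0.0
    return r


def estimate_unknown_factor(
    X: ExpressionMatrix | np.ndarray, h_k: np.ndarray, m: int
) -> tuple[np.ndarray, int, float, list[int]]:
    """Refine a surrogate h_k into an unknown-factor estimate F_k.

    The m genes most associated with h_k (absolute Pearson correlation, ties
    broken by ascending gene index) are pulled out; an SVD of that
    column-centered submatrix yields candidate sample-space eigenvectors
    e_j, and F_k is the one best correlated with h_k, sign-aligned so that
    cor(F_k, h_k) >= 0 and normalised to unit length.

    Returns ``(F_k, j_star, match_cor, selected_gene_indices)``.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n, p = V.shape
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}], got {m}")
    h_k = np.asarray(h_k, dtype=float).ravel()
    if np.ptp(h_k) == 0:
        raise ValueError("surrogate factor is constant")
    assoc = np.abs(_pearson_with_vector(V, h_k))
    # stable sort on descending association => ties resolve to the lower index
    order = np.argsort(-assoc, kind="stable")
    selected = sorted(int(j) for j in order[:m])
    sub = V[:, selected]
    spread = np.ptp(sub, axis=0)
    if np.any(spread == 0):
        warnings.warn(
            f"dropping {int(np.sum(spread == 0))} constant column(s) before SVD",
            stacklevel=2,
        )
        keep = spread > 0
        selected = [g for g, k in zip(selected, keep) if k]
        sub = sub[:, keep]
        if sub.shape[1] == 0:
            raise ValueError("all selected columns are constant")
    sub = sub - sub.mean(axis=0, keepdims=True)
    e, _, _ = np.linalg.svd(sub, full_matrices=False)
    cors = np.array([np.corrcoef(e[:, j], h_k)[0, 1] for j in range(e.shape[1])])
    cors[~np.isfinite(cors)] = 0.0
    j_star = int(np.argmax(np.abs(cors)))
    F_k = e[:, j_star].copy()
    if cors[j_star] < 0:
        F_k = -F_k
    F_k /= np.linalg.norm(F_k)
    return F_k, j_star, float(abs(cors[j_star])), selected


def build_adjusted(
    X: ExpressionMatrix | np.ndarray, M: np.ndarray, U: np.ndarray
) -> AdjustedData:
    """Jointly fit X = M beta + U alpha + eps by OLS and subtract only the
    nuisance part: X_a = X - U alpha_hat.

    The joint fit matters: regressing on U alone would also strip any
    interest-factor signal that happens to correlate with U.  Duplicate
    columns are dropped within U only (leftmost kept); a U column lying in
    the span of the interest design M is an error — silently "adjusting"
    along an interest direction would strip signal, so the caller must
    resolve the collision explicitly (as the Stage-1 pipeline does for the
    intrinsic outcome/group indicator collinearity).
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    n = V.shape[0]
    if M.shape[0] != n or (U.size and U.shape[0] != n):
        raise ValueError("row counts of X, M, U must agree")
    if U.shape[1] == 0:
        c = M.shape[1]
        beta = np.linalg.lstsq(M, V, rcond=RANK_RCOND)[0]
        return AdjustedData(
            X_a=V.copy(), U=U, alpha_hat=np.empty((0, V.shape[1])), M=M, beta_hat=beta
        )
    kept, _ = _incremental_independent_columns(None, U)
    U = U[:, kept]
    D = np.hstack([M, U])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        bad = [
            j for j in range(U.shape[1])
            if np.linalg.matrix_rank(np.hstack([M, U[:, j: j + 1]])) == M.shape[1]
        ]
        raise ValueError(
            "[M | U] is rank-deficient after removing redundant U columns; "
            f"nuisance column(s) {bad} collide with the interest design"
        )
    coef = np.linalg.lstsq(D, V, rcond=RANK_RCOND)[0]
    c = M.shape[1]
    beta_hat, alpha_hat = coef[:c], coef[c:]
    X_a = V - U @ alpha_hat
    return AdjustedData(X_a=X_a, U=U, alpha_hat=alpha_hat, M=M, beta_hat=beta_hat)


def adjust_heterogeneity(
    X: ExpressionMatrix,
    design: FactorDesign,
    K: int,
    m: int | None = None,
) -> tuple[AdjustedData, SurrogateSet, KnownFactors]:
    """Run the whole Stage-1 pipeline.

    1. build N (G, or [Y | G]) and the residual projector R_N;
    2. extract K surrogate factors from R_N X by SVD;
    3. refine each into an unknown-factor estimate F_k via its associated
       genes (``m`` of them, default min(p, 100));
    4. assemble the nuisance design U (F when unsupervised, [G | F] when
       supervised) and subtract its jointly-estimated effect from X.

    Returns the adjusted data, the surrogate set and the known-factor record.
    """
    if m is None:
        m = min(X.n_genes, 100)
    known = build_known_factor_matrix(design)
    R_N = residual_projector(known)
    surr = extract_surrogates(X, R_N, K)
    F_cols, cors, gene_sets = [], [], []
    for k in range(K):
        F_k, _, cor, sel = estimate_unknown_factor(X, surr.H[:, k], m)
        F_cols.append(F_k)
        cors.append(cor)
        gene_sets.append(sel)
    F = np.column_stack(F_cols) if F_cols else np.empty((X.n_samples, 0))
    surrogates = SurrogateSet(
        H=surr.H, F=F, match_correlations=cors, selected_gene_indices=gene_sets
    )
    M = design.interest_matrix()
    if design.mode == "unsupervised":
        U = F
        kept = list(range(F.shape[1]))
    else:
        # [G | F]; an indicator Y plus a full indicator G are collinear with
        # the intercept, so drop redundant nuisance columns against M first
        U = np.hstack([design.G, F]) if F.size else design.G
        kept, _ = _incremental_independent_columns(M, U)
        U = U[:, kept]
    adjusted = build_adjusted(X, M, U)
    adjusted.nuisance_columns = kept
    return adjusted, surrogates, known
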