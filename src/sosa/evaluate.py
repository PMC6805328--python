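"""Evaluation of gene rankings against known positive/negative controls.

When the truly associated genes (e.g. spiked-in transcripts, sex-chromosome
genes) and known-unassociated genes (e.g. housekeeping genes) are available,
a ranking is scored by counting, at each top-N cut,

    TPR = #true positives / #true genes,
    FPR = #false positives / #false genes,

sweeping N to trace a ROC curve whose trapezoid area (AUC) equals the
tie-corrected Mann-Whitney probability that a true control outranks a false
one.  Genes in neither control set are ignored by these formulas.

Rankings can also be scored by downstream utility: the mean cross-validated
test error of a 1-nearest-neighbour classifier restricted to the top-N
genes, the standard protocol for multi-class tumour-type panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .scoring import GeneRanking

__all__ = [
    "ControlSets",
    "RocResult",
    "hits_at_n",
    "tpr_fpr",
    "roc_auc",
    "knn_utility",
]


@dataclass
class ControlSets:
    """Disjoint sets of known-associated (true) and known-unassociated
    (false) control gene ids."""

    true_genes: set[str]
    false_genes: set[str]

    def __post_init__(self) -> None:
        self.true_genes = set(self.true_genes)
        self.false_genes = set(self.false_genes)
        if self.true_genes & self.false_genes:
            raise ValueError("control sets must be disjoint")


@dataclass
class RocResult:
    thresholds: np.ndarray  # top-N cuts at which the curve has vertices
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _ordered_ids(ranking: GeneRanking) -> list[str]:
    if ranking.gene_ids is None:
        return [str(j) for j in ranking.order]
    return [ranking.gene_ids[j] for j in ranking.order]


def hits_at_n(
    ranking: GeneRanking, controls: ControlSets, N: int
) -> tuple[int, int]:
    """Counts of true and false control genes in the top-N of the ranking."""
    if N < 1:
        raise ValueError("N must be at least 1")
    p = len(ranking.order)
    if N > p:
        raise ValueError(f"N={N} exceeds the number of ranked genes ({p})")
    top = set(_ordered_ids(ranking)[:N])
    return len(top & controls.true_genes), len(top & controls.false_genes)


def tpr_fpr(
    ranking: GeneRanking, controls: ControlSets, N: int
) -> tuple[float, float]:
    """True/false positive rates at the top-N cut."""
    if not controls.true_genes or not controls.false_genes:
        raise ValueError("both control sets must be nonempty")
    tp, fp = hits_at_n(ranking, controls, N)
    return tp / len(controls.true_genes), fp / len(controls.false_genes)


def roc_auc(ranking: GeneRanking, controls: ControlSets) -> RocResult:
    """ROC over the full ranking sweep, restricted to control genes.

    The curve is built from the scores so that tied scores form a single
    diagonal segment; the trapezoid area then equals the Mann-Whitney
    statistic with ties counted half.
    """
    if not controls.true_genes or not controls.false_genes:
        raise ValueError("both control sets must be nonempty")
    ids = ranking.gene_ids
    if ids is None:
        ids = [str(j) for j in range(len(ranking.order))]
    is_true = np.array([g in controls.true_genes for g in ids])
    is_false = np.array([g in controls.false_genes for g in ids])
    in_ctrl = is_true | is_false
    if not is_true.any() or not is_false.any():
        raise ValueError("ranking contains no genes from one of the control sets")
    scores = ranking.scores[in_ctrl]
    labels = is_true[in_ctrl]
    nT, nF = int(labels.sum()), int((~labels).sum())
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # group tied scores into single curve vertices
    boundaries = np.flatnonzero(np.diff(scores) != 0) + 1
    cut_points = np.concatenate([boundaries, [len(scores)]])
    tp = np.concatenate([[0], np.cumsum(labels)[cut_points - 1]])
    fp = np.concatenate([[0], np.cumsum(~labels)[cut_points - 1]])
    tpr = tp / nT
    fpr = fp / nF
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.concatenate([[0], cut_points])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def knn_utility(
    X: np.ndarray,
    labels: Sequence,
    top_ns: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    ranker: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    ranking: GeneRanking | None = None,
) -> dict[int, float]:
    """Mean 1-NN test error using only the top-N ranked genes, per N.

    ``ranker(X_train, labels_train) -> gene index order`` is called on each
    training fold (the default contract: selection must not see test
    samples).  Alternatively a fixed precomputed ``ranking`` may be supplied
    when the caller guarantees it was built without the test folds.
    Distances are Euclidean on the selected columns, unscaled.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.neighbors import KNeighborsClassifier

    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    p = X.shape[1]
    top_ns = list(top_ns)
    for N in top_ns:
        if not 1 <= N <= p:
            raise ValueError(f"top-N value {N} outside [1, {p}]")
    if (ranker is None) == (ranking is None):
        raise ValueError("supply exactly one of ranker= or ranking=")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = {N: [] for N in top_ns}
    for train_idx, test_idx in splitter.split(X, y):
        if ranker is not None:
            order = np.asarray(ranker(X[train_idx], y[train_idx]))
        else:
            order = ranking.order
        for N in top_ns:
            cols = order[:N]
            clf = KNeighborsClassifier(n_neighbors=1)
            clf.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            pred = clf.predict(X[np.ix_(test_idx, cols)])
            errors[N].append(float(np.mean(pred != y[test_idx])))
    return {N: float(np.mean(v)) for N, v in errors.items()}
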