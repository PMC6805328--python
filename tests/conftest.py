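"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: ranking
AUC by exhaustive pairwise comparison, group-lasso by accelerated proximal
gradient, 1-NN by explicit distance matrices.
"""

from __future__ import annotations

import numpy as np
import pytest

import sosa


# ---------------------------------------------------------------- oracles


def pairwise_auc(scores: np.ndarray, true_idx, false_idx) -> float:
    """AUC by brute-force pairwise comparison, ties counted half."""
    t = np.asarray(scores)[list(true_idx)]
    f = np.asarray(scores)[list(false_idx)]
    wins = (t[:, None] > f[None, :]).sum() + 0.5 * (t[:, None] == f[None, :]).sum()
    return float(wins / (len(t) * len(f)))


def ranking_auc(scores: np.ndarray, signal_idx, p: int) -> float:
    """AUC of a gene ranking against planted signal genes vs all others."""
    signal = set(int(j) for j in signal_idx)
    rest = [j for j in range(p) if j not in signal]
    return pairwise_auc(scores, sorted(signal), rest)


def prox_group_lasso(
    X: np.ndarray,
    target: np.ndarray,
    lam: float,
    max_iter: int = 200_000,
    tol: float = 1e-13,
) -> np.ndarray:
    """FISTA for min_B (1/n)||X B - T||_F^2 + lam * sum_j ||b_j||_2."""
    n, p = X.shape
    L = 2.0 * np.linalg.norm(X, 2) ** 2 / n
    step = 1.0 / L
    B = np.zeros((p, target.shape[1]))
    Yk, tk = B.copy(), 1.0
    prev = np.inf
    for it in range(max_iter):
        grad = (2.0 / n) * X.T @ (X @ Yk - target)
        Z = Yk - step * grad
        norms = np.linalg.norm(Z, axis=1, keepdims=True)
        Bn = Z * np.maximum(0.0, 1.0 - lam * step / np.maximum(norms, 1e-300))
        tk1 = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
        Yk = Bn + (tk - 1.0) / tk1 * (Bn - B)
        B, tk = Bn, tk1
        if it % 500 == 0:
            obj = np.sum((X @ B - target) ** 2) / n + lam * np.linalg.norm(B, axis=1).sum()
            if abs(prev - obj) < tol * max(1.0, obj):
                break
            prev = obj
    return B


def group_lasso_objective(X, B, target, lam) -> float:
    n = X.shape[0]
    return float(np.sum((X @ B - target) ** 2) / n
                 + lam * np.linalg.norm(B, axis=1).sum())


def brute_1nn_errors(X, y, cols, train_idx, test_idx) -> float:
    """1-NN test error via an explicit Euclidean distance matrix."""
    A = X[np.ix_(test_idx, cols)]
    B = X[np.ix_(train_idx, cols)]
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    pred = np.asarray(y)[np.asarray(train_idx)[np.argmin(d2, axis=1)]]
    return float(np.mean(pred != np.asarray(y)[test_idx]))


def random_two_class_design(rng: np.random.Generator, n: int):
    """A balanced-ish 2-class indicator matrix with both classes present."""
    labels = rng.integers(0, 2, n)
    labels[0], labels[1] = 0, 1
    M = np.zeros((n, 2))
    M[np.arange(n), labels] = 1.0
    return M, labels


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_spike_in():
    """A desk-scale spike-in-shaped dataset with latent confounding."""
    return sosa.spike_in_scenario(seed=1, n_genes=400)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
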