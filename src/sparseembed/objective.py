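"""The sparse supervised embedding objective and its Adam optimizer.

The embedding seeks an m x k transform T of the standardized beta matrix
that maximizes

    (1/|R|^2) sum_{f1,f2} M[f1,f2] * ||mean(B_f1 T) - mean(B_f2 T)||^2
    - (1/|R|) sum_f sum |cov(B_f T)|
    - S * sum |T|

i.e. weighted pairwise squared distances between parcel centroids in the
embedding, minus the summed absolute entries of each parcel's embedded
covariance (off-diagonals included, penalizing correlated components), minus
an L1 sparsity penalty.  The double sum over (f1, f2) visits ordered pairs,
so each unordered pair contributes twice.

Both quadratic terms scale with ||T||^2, so the maximizer is only
well-defined under a scale constraint: by default each column of T is
re-projected to unit L2 norm after every gradient step.  Optimization is
plain Adam ascent on the (sub)gradient, from a Gaussian initialization.
"""

from __future__ import annotations

import numpy as np

from .core import (
    EmbeddingTransform,
    FitConfig,
    ObjectiveBreakdown,
    PairWeights,
    ParcelLabeling,
    StandardizedBetaMatrix,
)

__all__ = ["objective", "objective_terms", "fit", "class_centroids", "class_covariances"]


def class_centroids(values: np.ndarray, labels: ParcelLabeling) -> np.ndarray:
    """|R| x m matrix of per-class mean beta profiles."""
    out = np.empty((labels.n_classes, values.shape[1]))
    for f in range(labels.n_classes):
        out[f] = values[labels.members(f)].mean(axis=0)
    return out


def class_covariances(values: np.ndarray, labels: ParcelLabeling) -> np.ndarray:
    """|R| x m x m stack of per-class sample covariances (n-1 denominator)."""
    m = values.shape[1]
    out = np.empty((labels.n_classes, m, m))
    for f in range(labels.n_classes):
        rows = values[labels.members(f)]
        out[f] = np.cov(rows, rowvar=False, ddof=1).reshape(m, m)
    return out


def _check_shapes(betas: StandardizedBetaMatrix, labels: ParcelLabeling, M: PairWeights, T: np.ndarray):
    if labels.n_voxels != betas.n_voxels:
        raise ValueError("labeling covers a different number of voxels than the beta matrix")
    if M.n_classes != labels.n_classes:
        raise ValueError("pair-weight matrix does not conform to the class catalog")
    if T.shape[0] != betas.n_conditions:
        raise ValueError("transform rows must match the number of conditions")


def _pair_scatter(centroids: np.ndarray, M: PairWeights) -> np.ndarray:
    """m x m matrix A = sum_{f1,f2} M[f1,f2] d^T d with d = c_f1 - c_f2.

    The distance term is then tr(T^T A T) / |R|^2, and its gradient
    (2/|R|^2) A T.
    """
    W = M.weights
    # sum_{a,b} M_ab (c_a - c_b)^T (c_a - c_b)
    #   = 2 * [ C^T diag(row sums) C - C^T W C ]   for symmetric W
    row = W.sum(axis=1)
    return 2.0 * (centroids.T * row) @ centroids - 2.0 * centroids.T @ W @ centroids


def _terms(T: np.ndarray, A: np.ndarray, covs: np.ndarray, n_classes: int):
    dist = float(np.einsum("ik,ij,jk->", T, A, T)) / n_classes**2
    ST = np.einsum("rij,jk->rik", covs, T)        # Sigma_f T, per class
    G = np.einsum("ji,rjk->rik", T, ST)            # T' Sigma_f T
    cov = float(np.abs(G).sum()) / n_classes
    l1 = float(np.abs(T).sum())
    return dist, cov, l1, ST, G


def objective_terms(
    T: np.ndarray, A: np.ndarray, covs: np.ndarray, n_classes: int, sparsity: float
) -> ObjectiveBreakdown:
    dist, cov, l1, _, _ = _terms(T, A, covs, n_classes)
    return ObjectiveBreakdown(dist, cov, l1, sparsity)


def objective(
    betas: StandardizedBetaMatrix,
    labels: ParcelLabeling,
    M: PairWeights,
    T: EmbeddingTransform | np.ndarray,
    sparsity: float = 0.005,
) -> ObjectiveBreakdown:
    """Evaluate the embedding objective term by term at a given transform."""
    comps = T.components if isinstance(T, EmbeddingTransform) else np.asarray(T, dtype=float)
    if isinstance(T, EmbeddingTransform) and T.fit_config is not None:
        sparsity = T.fit_config.sparsity
    _check_shapes(betas, labels, M, comps)
    cents = class_centroids(betas.values, labels)
    covs = class_covariances(betas.values, labels)
    A = _pair_scatter(cents, M)
    return objective_terms(comps, A, covs, labels.n_classes, sparsity)


def _gradient(T: np.ndarray, A: np.ndarray, covs: np.ndarray, n_classes: int, sparsity: float):
    """(Sub)gradient of the full objective (L1 included) and its value."""
    dist, cov, l1, ST, G = _terms(T, A, covs, n_classes)
    grad = (2.0 / n_classes**2) * (A @ T)
    grad -= (2.0 / n_classes) * np.einsum("rik,rkl->il", ST, np.sign(G))
    grad -= sparsity * np.sign(T)
    total = dist - cov - sparsity * l1
    return grad, total


def _smooth_gradient(T: np.ndarray, A: np.ndarray, covs: np.ndarray, n_classes: int, sparsity: float):
    """Gradient of the smooth part (distance - covariance) and the full value."""
    dist, cov, l1, ST, G = _terms(T, A, covs, n_classes)
    grad = (2.0 / n_classes**2) * (A @ T)
    grad -= (2.0 / n_classes) * np.einsum("rik,rkl->il", ST, np.sign(G))
    total = dist - cov - sparsity * l1
    return grad, total


def _soft_threshold(T: np.ndarray, thresh) -> np.ndarray:
    return np.sign(T) * np.maximum(np.abs(T) - thresh, 0.0)


def _renormalize(T: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(T, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return T / norms


def fit(
    betas: StandardizedBetaMatrix,
    labels: ParcelLabeling,
    M: PairWeights,
    k: int | None = None,
    sparsity: float | None = None,
    config: FitConfig | None = None,
) -> EmbeddingTransform:
    """Fit the embedding transform by Adam gradient ascent.

    ``k`` and ``sparsity`` override the corresponding config fields.  The fit
    is deterministic given the config seed.  Convergence is declared when the
    relative change of the objective over ``tol_window`` consecutive
    iterations falls below ``tol``; otherwise the returned transform is
    flagged ``converged=False``.
    """
    cfg = config if config is not None else FitConfig()
    if k is not None or sparsity is not None:
        cfg = cfg.replace(
            **{kk: vv for kk, vv in (("k", k), ("sparsity", sparsity)) if vv is not None}
        )
    m = betas.n_conditions
    if cfg.k > m:
        raise ValueError("k must not exceed the number of conditions")
    _check_shapes(betas, labels, M, np.zeros((m, cfg.k)))

    cents = class_centroids(betas.values, labels)
    covs = class_covariances(betas.values, labels)
    A = _pair_scatter(cents, M)
    R = labels.n_classes

    rng = np.random.default_rng(cfg.seed)
    T = rng.normal(0.0, cfg.init_sd, size=(m, cfg.k))
    if cfg.normalize_columns:
        T /= np.linalg.norm(T, axis=0, keepdims=True)

    # Phase 1 — Adam on the smooth part with a proximal soft-threshold for
    # the L1 term after each step.  Adam's sign-like steps make fast global
    # progress but chatter near the optimum, so no convergence check here.
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    adam_iter = cfg.adam_iter if cfg.adam_iter is not None else max(cfg.max_iter // 3, 1)
    adam_iter = min(adam_iter, cfg.max_iter)
    mom = np.zeros_like(T)
    vel = np.zeros_like(T)
    lr = cfg.learning_rate
    for it in range(1, adam_iter + 1):
        grad, _ = _smooth_gradient(T, A, covs, R, cfg.sparsity)
        mom = beta1 * mom + (1 - beta1) * grad
        vel = beta2 * vel + (1 - beta2) * grad**2
        denom = np.sqrt(vel / (1 - beta2**it)) + eps
        T = T + lr * (mom / (1 - beta1**it)) / denom
        T = _soft_threshold(T, lr * cfg.sparsity / denom)
        if cfg.normalize_columns:
            T = _renormalize(T)

    # Phase 2 — proximal projected-gradient ascent with a fixed step (halved
    # on sustained decrease of the objective) until the objective is flat
    # over ``tol_window`` consecutive iterations.
    history: list[float] = []
    converged = False
    step = cfg.polish_step
    bad = 0
    n_iter = adam_iter
    for it in range(adam_iter + 1, cfg.max_iter + 1):
        n_iter = it
        grad, total = _smooth_gradient(T, A, covs, R, cfg.sparsity)
        if history and total < history[-1] - 1e-12:
            bad += 1
            if bad >= 10:
                step *= 0.5
                bad = 0
        else:
            bad = 0
        history.append(total)
        T = _soft_threshold(T + step * grad, step * cfg.sparsity)
        if cfg.normalize_columns:
            T = _renormalize(T)
        if len(history) >= cfg.tol_window:
            window = history[-cfg.tol_window:]
            span = max(window) - min(window)
            if span <= cfg.tol * max(abs(window[-1]), 1e-12):
                converged = True
                break

    breakdown = objective_terms(T, A, covs, R, cfg.sparsity)
    return EmbeddingTransform(
        components=T,
        condition_names=betas.condition_names,
        fit_config=cfg,
        converged=converged,
        n_iter=n_iter,
        breakdown=breakdown,
    )
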