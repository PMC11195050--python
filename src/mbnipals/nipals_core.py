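"""Stable multi-block NIPALS solver for MCIA and consensus PCA.

Per order, the iteration alternates three exact partial maximizations of

    sum_k cov^2(X_k a_k, f),   f = sum_k w_k X_k a_k,
    ||a_k||_2 = 1,  ||w||_2 = 1,

with cov(u, v) = u^T v / (n - 1) on centered data:

    (i)   a_k <- X_k^T f / ||X_k^T f||,  f_k <- X_k a_k
    (ii)  w_k <- f_k^T f, then w <- w / ||w||
    (iii) f  <- sum_k w_k f_k

Each step cannot decrease the objective, so the recorded objective trace is
monotone non-decreasing — this is the defining property of the stable
multi-block extension and is enforced by the test suite rather than assumed.

Deflation between orders selects the variant: removing each block's captured
loading direction (``block``) yields MCIA with orthonormal block loadings;
regressing out the global score (``global``) yields consensus PCA with
orthogonal global scores.

The converged objective value serves as the order's pseudo-eigenvalue, so
variance explained needs no eigendecomposition.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .data_model import (
    DecompositionConfig,
    DecompositionResult,
    MultiBlockDataset,
    OrderSolution,
    _require_valid,
    concatenate_global,
)
from .preprocessing import PreprocessConfig, apply_preprocessor, fit_preprocessor

__all__ = [
    "objective_value",
    "solve_order",
    "deflate",
    "decompose",
    "variance_explained",
    "block_contributions",
    "top_features",
    "NoSignalError",
]

logger = logging.getLogger(__name__)

_DEGENERATE_NORM = 1e-12


class NoSignalError(RuntimeError):
    """All blocks are degenerate: no signal remains to extract an order."""


def _check_unit(v: np.ndarray, label: str, allow_zero: bool = False) -> None:
    nrm = np.linalg.norm(v)
    if allow_zero and nrm < _DEGENERATE_NORM:
        return
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError(f"{label} must be unit-norm (||.|| = {nrm!r})")


def objective_value(
    blocks: list[np.ndarray],
    block_loadings: list[np.ndarray],
    weights: np.ndarray,
) -> float:
    """Evaluate sum_k cov^2(X_k a_k, f) with f = sum_k w_k X_k a_k.

    Pure function; inputs must be unit-norm (a degenerate all-zero ``a_k``
    is accepted when its weight is zero).
    """
    weights = np.asarray(weights, dtype=np.float64)
    _check_unit(weights, "weights")
    n = blocks[0].shape[0]
    scores = []
    for k, (X, a) in enumerate(zip(blocks, block_loadings)):
        _check_unit(a, f"block_loadings[{k}]", allow_zero=True)
        scores.append(X @ a)
    f = sum(w * s for w, s in zip(weights, scores))
    denom = (n - 1) ** 2
    return float(sum((s @ f) ** 2 for s in scores) / denom)


def _initial_score(
    blocks: list[np.ndarray], config: DecompositionConfig, order_index: int
) -> np.ndarray:
    n = blocks[0].shape[0]
    if config.init == "random":
        seed = 0 if config.seed is None else config.seed
        rng = np.random.default_rng(seed + order_index)
        return rng.standard_normal(n)
    # Deterministic default: the concatenated column with the largest norm
    # (largest variance, since blocks are centered upstream).
    X = np.concatenate(blocks, axis=1)
    norms = np.linalg.norm(X, axis=0)
    return X[:, int(np.argmax(norms))].copy()


def solve_order(
    blocks: list[np.ndarray],
    config: DecompositionConfig,
    order_index: int = 0,
) -> OrderSolution:
    """Run the stable multi-block NIPALS iteration for one order.

    ``blocks`` are the (possibly deflated) centered matrices. Convergence is
    declared when the relative change of the global score drops below
    ``config.tol``; hitting ``max_iter`` is recorded in the diagnostics, not
    fatal. The returned global score is un-normalized — its scale carries the
    pseudo-eigenvalue.
    """
    N = len(blocks)
    n = blocks[0].shape[0]
    denom = (n - 1) ** 2

    f = _initial_score(blocks, config, order_index)
    if np.linalg.norm(f) < _DEGENERATE_NORM:
        raise NoSignalError(f"order {order_index}: no remaining signal")

    loadings = [np.zeros(X.shape[1]) for X in blocks]
    scores = [np.zeros(n) for _ in blocks]
    w = np.zeros(N)
    trace: list[float] = []
    rel_change = np.inf
    converged = False
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        degenerate: list[int] = []
        for k, X in enumerate(blocks):
            v = X.T @ f
            nv = np.linalg.norm(v)
            if nv < _DEGENERATE_NORM:
                loadings[k] = np.zeros(X.shape[1])
                scores[k] = np.zeros(n)
                degenerate.append(k)
            else:
                loadings[k] = v / nv
                scores[k] = X @ loadings[k]
        w = np.array([s @ f for s in scores])
        for k in degenerate:
            w[k] = 0.0
        nw = np.linalg.norm(w)
        if nw < _DEGENERATE_NORM or len(degenerate) == N:
            raise NoSignalError(f"order {order_index}: no remaining signal")
        w = w / nw
        f_new = sum(wk * s for wk, s in zip(w, scores))
        trace.append(float(sum((s @ f_new) ** 2 for s in scores) / denom))
        rel_change = np.linalg.norm(f_new - f) / np.linalg.norm(f)
        f = f_new
        if rel_change < config.tol:
            converged = True
            break

    if not converged:
        logger.warning(
            "order %d: max_iter=%d reached (rel change %.3e >= tol %.3e)",
            order_index,
            config.max_iter,
            rel_change,
            config.tol,
        )

    # Sign convention: flip so the largest-|.| entry of the global loading
    # (concatenation of w_k * a_k) is positive. w_k = f_k^T f is invariant
    # under jointly flipping every a_k, f_k and f.
    global_loading = np.concatenate([wk * a for wk, a in zip(w, loadings)])
    pivot = int(np.argmax(np.abs(global_loading)))
    if global_loading[pivot] < 0:
        loadings = [-a for a in loadings]
        scores = [-s for s in scores]
        f = -f

    return OrderSolution(
        block_loadings=loadings,
        block_scores=scores,
        block_weights=w,
        global_score=f,
        eigenvalue=trace[-1],
        n_iter=n_iter,
        objective_trace=trace,
        converged=converged,
        final_rel_change=float(rel_change),
        degenerate_blocks=[k for k in range(N) if np.linalg.norm(loadings[k]) < 0.5],
    )


def deflate(
    blocks: list[np.ndarray], solution: OrderSolution, mode: str
) -> list[np.ndarray]:
    """Remove one order's captured structure from every block.

    ``mode='block'`` (MCIA): project each block off its own loading
    direction, ``X_k <- X_k - (X_k a_k) a_k^T``; degenerate blocks pass
    through unchanged. ``mode='global'`` (CPCA): regress each block on the
    global score, ``X_k <- X_k - f (f^T X_k) / (f^T f)``.
    """
    if mode == "block":
        out = []
        for X, a in zip(blocks, solution.block_loadings):
            if np.linalg.norm(a) < 0.5:  # degenerate at this order
                out.append(X.copy())
            else:
                out.append(X - np.outer(X @ a, a))
        return out
    if mode == "global":
        f = solution.global_score
        ff = f @ f
        if ff < _DEGENERATE_NORM:
            raise ValueError("global deflation: global score has vanishing norm")
        return [X - np.outer(f, (f @ X) / ff) for X in blocks]
    raise ValueError(f"mode must be 'block' or 'global', got {mode!r}")


def decompose(
    dataset: MultiBlockDataset,
    preproc: PreprocessConfig | None = None,
    config: DecompositionConfig | None = None,
) -> DecompositionResult:
    """Fit the full multi-order MCIA/CPCA decomposition.

    Fits and applies the preprocessor, then alternates :func:`solve_order`
    and :func:`deflate` for ``config.num_factors`` orders. Deterministic
    given (dataset, configs, seed). If the data runs out of signal before
    reaching the requested number of orders, the result is truncated with a
    warning.
    """
    preproc = preproc or PreprocessConfig()
    config = config or DecompositionConfig()
    _require_valid(dataset)

    n = dataset.n_samples
    p_total = sum(dataset.block_widths)
    r_max = min(n - 1, p_total)
    if config.num_factors > r_max:
        raise ValueError(
            f"num_factors={config.num_factors} exceeds min(n-1, sum p_k)={r_max}"
        )

    fitted = fit_preprocessor(dataset, preproc)
    transformed = apply_preprocessor(fitted, dataset)
    work = [X.copy() for X in transformed.blocks]

    solutions: list[OrderSolution] = []
    for j in range(config.num_factors):
        try:
            sol = solve_order(work, config, order_index=j)
        except NoSignalError:
            warnings.warn(
                f"signal exhausted after {j} orders "
                f"(requested {config.num_factors}); result truncated",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        logger.info(
            "order %d: %d iterations, objective %.6e, converged=%s",
            j,
            sol.n_iter,
            sol.eigenvalue,
            sol.converged,
        )
        solutions.append(sol)
        if j < config.num_factors - 1:
            work = deflate(work, sol, config.deflation)

    R = len(solutions)
    if R == 0:
        raise NoSignalError("no signal in dataset: could not extract any order")

    F = np.column_stack([s.global_score for s in solutions])
    W = np.column_stack([s.block_weights for s in solutions])
    block_loadings = [
        np.column_stack([s.block_loadings[k] for s in solutions])
        for k in range(dataset.n_blocks)
    ]
    block_scores = [
        np.column_stack([s.block_scores[k] for s in solutions])
        for k in range(dataset.n_blocks)
    ]
    A = np.concatenate(
        [W[k, :][None, :] * block_loadings[k] for k in range(dataset.n_blocks)],
        axis=0,
    )
    result = DecompositionResult(
        global_scores=F,
        global_loadings=A,
        block_scores=block_scores,
        block_loadings=block_loadings,
        block_weights=W,
        eigenvalues=np.array([s.eigenvalue for s in solutions]),
        fitted_preprocessor=fitted,
        config=config,
        per_order=solutions,
        block_names=list(dataset.block_names),
        sample_ids=list(dataset.sample_ids),
        feature_ids=[list(ids) for ids in dataset.feature_ids],
    )
    result.check_eigenvalue_order()
    return result


def variance_explained(result: DecompositionResult) -> np.ndarray:
    """Per-order proportion of variance from the pseudo-eigenvalues.

    ``proportion_j = eigenvalue_j / sum(eigenvalues)`` — no eigendecomposition
    involved. Entries lie in [0, 1] and sum to 1.
    """
    ev = np.asarray(result.eigenvalues, dtype=np.float64)
    total = ev.sum()
    if not total > 0:
        raise ValueError("all eigenvalues are zero; variance explained undefined")
    return ev / total


def block_contributions(result: DecompositionResult) -> np.ndarray:
    """N x R matrix of squared block weights; each column sums to 1."""
    return result.block_weights**2


def top_features(
    result: DecompositionResult, order: int, count: int
) -> list[tuple[str, str, float]]:
    """Rank features of one order's global loading by absolute magnitude.

    ``order`` is 1-based. Ties are broken by (block order, feature order) so
    the ranking is deterministic. If ``count`` exceeds the number of
    features, all are returned (with a log note).
    """
    R = result.n_factors
    if not 1 <= order <= R:
        raise ValueError(f"order must be in [1, {R}], got {order}")
    col = result.global_loadings[:, order - 1]
    labels: list[tuple[str, str]] = []
    for name, ids in zip(result.block_names, result.feature_ids):
        labels.extend((name, f) for f in ids)
    if count > len(col):
        logger.info(
            "top_features: count=%d exceeds p=%d; returning all", count, len(col)
        )
        count = len(col)
    ranked = sorted(range(len(col)), key=lambda i: (-abs(col[i]), i))[:max(count, 0)]
    return [(labels[i][0], labels[i][1], float(col[i])) for i in ranked]
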