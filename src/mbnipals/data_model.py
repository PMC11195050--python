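"""Multi-block data container and decomposition result types.

All matrices are samples-in-rows, features-in-columns. Indices in validation
reports are 0-based; column ranges are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MultiBlockDataset",
    "DecompositionConfig",
    "OrderSolution",
    "DecompositionResult",
    "validate_dataset",
    "concatenate_global",
    "InvalidDatasetError",
]


class InvalidDatasetError(ValueError):
    """Raised when an operation receives a dataset that fails validation."""


@dataclass
class MultiBlockDataset:
    """An ordered, named collection of sample-by-feature blocks.

    Every block shares the same ``n`` samples (rows, same IDs in the same
    order); the feature dimension ``p_k`` may differ per block.

    Parameters
    ----------
    block_names : list of str
        One name per block, unique.
    blocks : list of ndarray
        Block ``k`` has shape ``(n, p_k)``; coerced to float64.
    sample_ids : list of str
        Shared row identifiers, length ``n``.
    feature_ids : list of list of str
        Per-block column identifiers; unique within a block.
    """

    block_names: list[str]
    blocks: list[np.ndarray]
    sample_ids: list[str]
    feature_ids: list[list[str]]

    def __post_init__(self) -> None:
        self.block_names = [str(b) for b in self.block_names]
        self.blocks = [np.asarray(b, dtype=np.float64) for b in self.blocks]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [[str(f) for f in ids] for ids in self.feature_ids]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def block_widths(self) -> list[int]:
        return [b.shape[1] for b in self.blocks]

    def block(self, name: str) -> np.ndarray:
        return self.blocks[self.block_names.index(name)]

    def global_feature_ids(self) -> list[str]:
        """Concatenated feature IDs; IDs present in more than one block are
        namespaced as ``<block>::<feature>`` to disambiguate."""
        seen: dict[str, int] = {}
        for ids in self.feature_ids:
            for f in ids:
                seen[f] = seen.get(f, 0) + 1
        out: list[str] = []
        for name, ids in zip(self.block_names, self.feature_ids):
            for f in ids:
                out.append(f"{name}::{f}" if seen[f] > 1 else f)
        return out

    def subset_samples(self, indices: Sequence[int]) -> "MultiBlockDataset":
        """Row-subset every block by positional indices (e.g. train/test splits)."""
        idx = list(indices)
        return MultiBlockDataset(
            block_names=list(self.block_names),
            blocks=[b[idx, :].copy() for b in self.blocks],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=[list(ids) for ids in self.feature_ids],
        )


def validate_dataset(dataset: MultiBlockDataset) -> list[str]:
    """Check every dataset invariant; return a report of violations.

    The report is empty iff the dataset is valid. Each entry names the
    offending block and index. Purely a reporting operation — loaders and
    solvers raise :class:`InvalidDatasetError` on a non-empty report.
    """
    report: list[str] = []
    ds = dataset
    if ds.n_blocks < 1:
        report.append("dataset has no blocks (N must be >= 1)")
        return report
    if len(ds.block_names) != ds.n_blocks:
        report.append(
            f"{len(ds.block_names)} block names for {ds.n_blocks} blocks"
        )
    if len(set(ds.block_names)) != len(ds.block_names):
        report.append(f"duplicate block names: {ds.block_names}")
    if len(ds.feature_ids) != ds.n_blocks:
        report.append(
            f"{len(ds.feature_ids)} feature-ID lists for {ds.n_blocks} blocks"
        )
        return report
    n = ds.n_samples
    if len(set(ds.sample_ids)) != n:
        report.append("duplicate sample IDs")
    for name, X, ids in zip(ds.block_names, ds.blocks, ds.feature_ids):
        if X.ndim != 2:
            report.append(f"block '{name}': expected 2-D matrix, got {X.ndim}-D")
            continue
        if X.shape[0] != n:
            report.append(
                f"block '{name}': {X.shape[0]} rows but {n} sample IDs "
                "(row-count mismatch)"
            )
        if X.shape[1] < 1:
            report.append(f"block '{name}': zero features (p_k must be >= 1)")
        if X.shape[1] != len(ids):
            report.append(
                f"block '{name}': {X.shape[1]} columns but {len(ids)} feature IDs"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({f for f in ids if ids.count(f) > 1})
            report.append(f"block '{name}': duplicate feature IDs {dupes}")
        bad = ~np.isfinite(X)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            report.append(
                f"block '{name}': non-finite entry at row {i}, column {j}"
            )
    return report


def _require_valid(dataset: MultiBlockDataset) -> None:
    report = validate_dataset(dataset)
    if report:
        raise InvalidDatasetError("; ".join(report))


def concatenate_global(
    dataset: MultiBlockDataset,
) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Column-wise concatenation of all blocks into the global matrix.

    Returns
    -------
    X : ndarray of shape (n, sum p_k)
    index_map : dict
        ``block_name -> (start, stop)`` half-open column range of that block.
    """
    _require_valid(dataset)
    X = np.concatenate(dataset.blocks, axis=1)
    index_map: dict[str, tuple[int, int]] = {}
    start = 0
    for name, b in zip(dataset.block_names, dataset.blocks):
        index_map[name] = (start, start + b.shape[1])
        start += b.shape[1]
    return X, index_map


@dataclass
class DecompositionConfig:
    """Options for the multi-block NIPALS decomposition.

    ``deflation='block'`` gives MCIA (orthonormal block loadings);
    ``deflation='global'`` gives consensus PCA (orthogonal global scores).
    """

    num_factors: int = 2
    deflation: str = "block"
    tol: float = 1e-9
    max_iter: int = 5000
    init: str = "max_variance_column"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.num_factors < 1:
            raise ValueError(f"num_factors must be >= 1, got {self.num_factors}")
        if self.deflation not in ("block", "global"):
            raise ValueError(
                f"deflation must be 'block' or 'global', got {self.deflation!r}"
            )
        if not self.tol > 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.init not in ("max_variance_column", "random"):
            raise ValueError(
                "init must be 'max_variance_column' or 'random', "
                f"got {self.init!r}"
            )


@dataclass
class OrderSolution:
    """Converged quantities for one order of the decomposition.

    ``global_score`` equals ``sum_k block_weights[k] * block_scores[k]``;
    ``eigenvalue`` is the converged objective value (pseudo-eigenvalue).
    Degenerate blocks (no remaining signal at this order) carry a zero
    loading vector and zero weight, and are listed in ``degenerate_blocks``.
    """

    block_loadings: list[np.ndarray]
    block_scores: list[np.ndarray]
    block_weights: np.ndarray
    global_score: np.ndarray
    eigenvalue: float
    n_iter: int
    objective_trace: list[float]
    converged: bool = True
    final_rel_change: float = 0.0
    degenerate_blocks: list[int] = field(default_factory=list)


@dataclass
class DecompositionResult:
    """Stacked multi-order output of :func:`mbnipals.nipals_core.decompose`.

    Attributes
    ----------
    global_scores : ndarray (n, R)
        Sample embedding F.
    global_loadings : ndarray (p, R)
        A, rows ordered by block concatenation; column j is the concatenation
        over blocks of ``block_weights[k, j] * block_loadings[k][:, j]`` so
        that ``F = X_preproc @ A`` holds under block deflation.
    block_scores, block_loadings : lists of ndarray
        Per-block F_k (n, R) and A_k (p_k, R).
    block_weights : ndarray (N, R)
        Unit-norm block-contribution vectors, one column per order.
    eigenvalues : ndarray (R,)
        Converged objective values, used for variance explained.
    """

    global_scores: np.ndarray
    global_loadings: np.ndarray
    block_scores: list[np.ndarray]
    block_loadings: list[np.ndarray]
    block_weights: np.ndarray
    eigenvalues: np.ndarray
    fitted_preprocessor: "object"
    config: DecompositionConfig
    per_order: list[OrderSolution]
    block_names: list[str]
    sample_ids: list[str]
    feature_ids: list[list[str]]

    @property
    def n_factors(self) -> int:
        return self.global_scores.shape[1]

    @property
    def n_blocks(self) -> int:
        return len(self.block_names)

    def global_feature_ids(self) -> list[str]:
        seen: dict[str, int] = {}
        for ids in self.feature_ids:
            for f in ids:
                seen[f] = seen.get(f, 0) + 1
        out: list[str] = []
        for name, ids in zip(self.block_names, self.feature_ids):
            for f in ids:
                out.append(f"{name}::{f}" if seen[f] > 1 else f)
        return out

    def check_eigenvalue_order(self) -> None:
        """Warn (never fail) if eigenvalues are not non-increasing."""
        ev = self.eigenvalues
        if np.any(np.diff(ev) > 1e-10 * max(1.0, float(np.max(ev, initial=0.0)))):
            warnings.warn(
                "eigenvalues are not non-increasing across orders: "
                f"{ev.tolist()}",
                RuntimeWarning,
                stacklevel=2,
            )
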