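"""Within-block (column) and whole-block scaling transforms.

Fitted parameters are retained so held-out data can be transformed with the
training statistics (never re-estimated). Order of operations is fixed:
column transform first, then the whole-block scalar, which is computed on the
column-transformed block. The standard-deviation denominator is ``n - 1``
throughout the package.

Column methods
--------------
``none``
    Identity.
``center``
    Subtract column means.
``center_scale``
    Subtract column means, divide by column standard deviations (``ddof=1``).
    Zero-variance columns get divisor 1 (the column becomes all-zero) and a
    warning is emitted rather than the column being dropped.
``colprofile``
    Correspondence-analysis-style profile transform for non-negative blocks.
    With ``P = X / sum(X)``, row masses ``r`` and column masses ``c``,
    entries become ``sqrt(r_i) * (P_ij / r_i - c_j)``. Column masses are
    fitted on training data and reused on new data; row masses are recomputed
    from the data being transformed (they are per-sample quantities). This is
    one fixed convention among several used in the co-inertia literature.

Block methods (scalar divisor per block)
----------------------------------------
``none`` -> 1; ``unit_variance`` -> Frobenius norm / sqrt(n - 1) (total
variance becomes 1); ``largest_singular_value`` -> leading singular value;
``num_columns`` -> sqrt(p_k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import MultiBlockDataset, _require_valid

__all__ = [
    "PreprocessConfig",
    "FittedPreprocessor",
    "fit_preprocessor",
    "apply_preprocessor",
]

COLUMN_METHODS = ("none", "center", "center_scale", "colprofile")
BLOCK_METHODS = ("none", "unit_variance", "largest_singular_value", "num_columns")


@dataclass
class PreprocessConfig:
    column_method: str = "center"
    block_method: str = "unit_variance"

    def __post_init__(self) -> None:
        if self.column_method not in COLUMN_METHODS:
            raise ValueError(
                f"column_method must be one of {COLUMN_METHODS}, "
                f"got {self.column_method!r}"
            )
        if self.block_method not in BLOCK_METHODS:
            raise ValueError(
                f"block_method must be one of {BLOCK_METHODS}, "
                f"got {self.block_method!r}"
            )


@dataclass
class FittedPreprocessor:
    """Per-block transform parameters estimated by :func:`fit_preprocessor`."""

    config: PreprocessConfig
    block_names: list[str]
    feature_ids: list[list[str]]
    centers: list[np.ndarray]
    scales: list[np.ndarray]
    block_scalars: list[float]
    col_masses: list[Optional[np.ndarray]] = field(default_factory=list)
    zero_variance: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.col_masses:
            self.col_masses = [None] * len(self.block_names)
        if not self.zero_variance:
            self.zero_variance = [[] for _ in self.block_names]
        for k, s in enumerate(self.scales):
            if np.any(s <= 0):
                raise ValueError(f"block '{self.block_names[k]}': non-positive scale divisor")
        for k, b in enumerate(self.block_scalars):
            if not b > 0:
                raise ValueError(f"block '{self.block_names[k]}': non-positive block scalar")


def _colprofile_transform(X: np.ndarray, name: str, col_masses: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Profile-transform one block. Returns (transformed, column masses used)."""
    if np.any(X < 0):
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(
            f"colprofile requires non-negative entries; block '{name}' has "
            f"{X[i, j]} at row {i}, column {j}"
        )
    total = X.sum()
    if not total > 0:
        raise ValueError(f"colprofile: block '{name}' has zero grand total")
    row_sums = X.sum(axis=1)
    if np.any(row_sums == 0):
        i = int(np.argwhere(row_sums == 0)[0][0])
        raise ValueError(f"colprofile: block '{name}' row {i} is all zero")
    P = X / total
    r = row_sums / total
    c = P.sum(axis=0) if col_masses is None else col_masses
    T = np.sqrt(r)[:, None] * (P / r[:, None] - c[None, :])
    return T, c


def _column_transform(
    X: np.ndarray,
    method: str,
    name: str,
    centers: Optional[np.ndarray] = None,
    scales: Optional[np.ndarray] = None,
    col_masses: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Optional[np.ndarray], list[int]]:
    """Apply (or fit-and-apply when parameters are None) the column transform.

    Returns (transformed, centers, scales, col_masses, zero_variance_columns).
    """
    p = X.shape[1]
    flagged: list[int] = []
    if method == "colprofile":
        T, c = _colprofile_transform(X, name, col_masses)
        return T, np.zeros(p), np.ones(p), c, flagged
    if method == "none":
        return X.copy(), np.zeros(p), np.ones(p), None, flagged
    if centers is None:
        centers = X.mean(axis=0)
    if method == "center":
        return X - centers, centers, np.ones(p), None, flagged
    # center_scale
    if scales is None:
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(p)
        flagged = [int(j) for j in np.where(sd == 0)[0]]
        if flagged:
            warnings.warn(
                f"block '{name}': zero-variance columns {flagged} scaled by 1",
                RuntimeWarning,
                stacklevel=3,
            )
        scales = np.where(sd == 0, 1.0, sd)
    return (X - centers) / scales, centers, scales, None, flagged


def _block_scalar(T: np.ndarray, method: str, name: str) -> float:
    n = T.shape[0]
    if method == "none":
        return 1.0
    if method == "num_columns":
        return float(np.sqrt(T.shape[1]))
    if method == "unit_variance":
        denom = np.sqrt(max(n - 1, 1))
        s = float(np.linalg.norm(T) / denom)
    elif method == "largest_singular_value":
        s = float(np.linalg.svd(T, compute_uv=False)[0])
    else:  # pragma: no cover
        raise ValueError(method)
    if not s > 0:
        raise ValueError(
            f"block '{name}' is all zero after column transform; cannot scale"
        )
    return s


def fit_preprocessor(
    dataset: MultiBlockDataset, config: PreprocessConfig
) -> FittedPreprocessor:
    """Estimate column centers/scales and the whole-block scalar per block."""
    _require_valid(dataset)
    centers, scales, scalars, masses, zv = [], [], [], [], []
    for name, X in zip(dataset.block_names, dataset.blocks):
        T, ctr, scl, cm, flagged = _column_transform(X, config.column_method, name)
        scalars.append(_block_scalar(T, config.block_method, name))
        centers.append(ctr)
        scales.append(scl)
        masses.append(cm)
        zv.append(flagged)
    return FittedPreprocessor(
        config=config,
        block_names=list(dataset.block_names),
        feature_ids=[list(ids) for ids in dataset.feature_ids],
        centers=centers,
        scales=scales,
        block_scalars=scalars,
        col_masses=masses,
        zero_variance=zv,
    )


def apply_preprocessor(
    fitted: FittedPreprocessor, dataset: MultiBlockDataset
) -> MultiBlockDataset:
    """Transform ``dataset`` with previously fitted parameters.

    A pure function of ``(fitted, dataset)``: parameters are never
    re-estimated, so applying the training transform to held-out samples is
    exact. Feature IDs must match the fitted ones per block, in order.
    """
    _require_valid(dataset)
    if dataset.block_names != fitted.block_names:
        raise ValueError(
            f"block names {dataset.block_names} do not match fitted "
            f"{fitted.block_names}"
        )
    out = []
    for k, (name, X) in enumerate(zip(dataset.block_names, dataset.blocks)):
        got, want = dataset.feature_ids[k], fitted.feature_ids[k]
        if got != want:
            missing = sorted(set(want) - set(got))
            extra = sorted(set(got) - set(want))
            detail = (
                f"missing={missing}, extra={extra}"
                if (missing or extra)
                else "same IDs in different order"
            )
            raise ValueError(f"block '{name}': feature mismatch ({detail})")
        if fitted.config.column_method == "colprofile":
            T, _, _, _, _ = _column_transform(
                X, "colprofile", name, col_masses=fitted.col_masses[k]
            )
        else:
            T = (X - fitted.centers[k]) / fitted.scales[k]
        out.append(T / fitted.block_scalars[k])
    return MultiBlockDataset(
        block_names=list(dataset.block_names),
        blocks=out,
        sample_ids=list(dataset.sample_ids),
        feature_ids=[list(ids) for ids in dataset.feature_ids],
    )
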