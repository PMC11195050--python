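"""Seeded multi-block fixture generator with planted latent structure.

Blocks are built as low-rank signal plus Gaussian noise:

    X_k = sum_r signal[k, r] * (factor_r @ loading_{k,r}^T) + noise

with one shared set of factor scores (orthogonalized after sampling and
scaled to unit per-entry variance, so "the planted factor" is unambiguous
for correlation-based recovery checks) and unit-norm per-block loadings. Optional cluster structure is injected
into the first factor's scores (shifted means) rather than into raw
features, so it survives any column preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import MultiBlockDataset

__all__ = ["SyntheticSpec", "generate", "nci60_like_fixture"]


@dataclass
class SyntheticSpec:
    n: int
    block_widths: list[int]
    n_factors: int
    block_signal: np.ndarray  # (N, n_factors); 0 = factor absent from block
    noise_sd: float = 0.1
    n_clusters: Optional[int] = None
    seed: int = 0
    block_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.block_signal = np.atleast_2d(
            np.asarray(self.block_signal, dtype=np.float64)
        )
        N = len(self.block_widths)
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if N < 1 or any(p < 1 for p in self.block_widths):
            raise ValueError(f"invalid block widths {self.block_widths}")
        if self.n_factors < 1 or self.n_factors > min(self.n, min(self.block_widths)):
            raise ValueError(
                f"n_factors={self.n_factors} must be in [1, min(n, min p_k)]"
            )
        if self.block_signal.shape != (N, self.n_factors):
            raise ValueError(
                f"block_signal shape {self.block_signal.shape} != "
                f"({N}, {self.n_factors})"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_clusters is not None and not 2 <= self.n_clusters <= self.n:
            raise ValueError(f"n_clusters={self.n_clusters} out of range")
        if not self.block_names:
            self.block_names = [f"block{k + 1}" for k in range(N)]


def generate(
    spec: SyntheticSpec,
) -> tuple[MultiBlockDataset, np.ndarray, list[np.ndarray]]:
    """Draw a dataset from ``spec``.

    Returns
    -------
    dataset : MultiBlockDataset
    scores : ndarray (n, n_factors)
        Orthogonal planted factor scores, columns of norm sqrt(n)
        (ground truth).
    loadings : list of ndarray (p_k, n_factors)
        Unit-norm planted per-block loadings.
    """
    rng = np.random.default_rng(spec.seed)
    scores = rng.standard_normal((spec.n, spec.n_factors))
    if spec.n_clusters is not None:
        labels = cluster_labels(spec.n, spec.n_clusters)
        # Shift factor-1 means per cluster before orthonormalization; QR
        # keeps column 1's direction, so the separation survives.
        shifts = np.linspace(-3.0, 3.0, spec.n_clusters)
        scores[:, 0] = 0.3 * scores[:, 0] + shifts[labels]
    Q, _ = np.linalg.qr(scores)
    # Orthogonal columns scaled to norm sqrt(n): unit per-entry variance, so
    # block_signal is directly comparable to noise_sd at the entry level.
    scores = Q[:, : spec.n_factors] * np.sqrt(spec.n)

    blocks, loadings = [], []
    for k, p in enumerate(spec.block_widths):
        L = rng.standard_normal((p, spec.n_factors))
        L /= np.linalg.norm(L, axis=0, keepdims=True)
        X = (scores * spec.block_signal[k]) @ L.T
        if spec.noise_sd > 0:
            X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
        blocks.append(X)
        loadings.append(L)

    dataset = MultiBlockDataset(
        block_names=list(spec.block_names),
        blocks=blocks,
        sample_ids=[f"sample{i + 1}" for i in range(spec.n)],
        feature_ids=[
            [f"{name}_feat{j + 1}" for j in range(p)]
            for name, p in zip(spec.block_names, spec.block_widths)
        ],
    )
    return dataset, scores, loadings


def cluster_labels(n: int, n_clusters: int) -> np.ndarray:
    """Deterministic near-balanced cluster assignment for n samples."""
    return np.arange(n) % n_clusters


def nci60_like_fixture(
    seed: int = 42,
) -> tuple[MultiBlockDataset, np.ndarray]:
    """A 21-sample, three-block fixture with 3 planted sample groups.

    Shapes (21 x 200, 21 x 50, 21 x 120) are a scaled-down emulation of a
    three-assay tumor cell-line panel. Returns (dataset, cluster labels).
    """
    spec = SyntheticSpec(
        n=21,
        block_widths=[200, 50, 120],
        n_factors=3,
        block_signal=np.array(
            [[5.0, 2.0, 1.0], [4.0, 1.5, 1.0], [5.0, 1.0, 2.0]]
        ),
        noise_sd=0.08,
        n_clusters=3,
        seed=seed,
        block_names=["rna", "mirna", "protein"],
    )
    dataset, _, _ = generate(spec)
    return dataset, cluster_labels(21, 3)
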