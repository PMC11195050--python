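"""Out-of-sample embedding of new samples into a trained score space.

Loadings are linear combinations of the original features, so new samples
with the same features can be embedded without refitting: transform with the
FITTED preprocessor, concatenate, and multiply by the trained global
loadings. Under block deflation this is exact on the training data
(``F = X_preproc @ A``); under global deflation the identity does not hold
exactly and predictions are flagged approximate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import DecompositionResult, MultiBlockDataset
from .preprocessing import apply_preprocessor

__all__ = ["PredictionResult", "predict_global_scores"]

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Embedding of new samples. ``block_scores_new`` is populated only under
    block deflation, where per-block projection is exactly defined."""

    global_scores_new: np.ndarray
    block_scores_new: Optional[list[np.ndarray]]
    sample_ids: list[str]
    approximate: bool = False


def predict_global_scores(
    model: DecompositionResult, new_data: MultiBlockDataset
) -> PredictionResult:
    """Project new samples onto a trained model's global (and block) loadings.

    ``new_data`` must contain exactly the training blocks with exactly the
    training feature IDs per block; missing or mismatched features are
    rejected (feature subsetting would change the loadings' meaning).
    """
    missing = [b for b in model.block_names if b not in new_data.block_names]
    if missing:
        raise ValueError(f"new data is missing block(s): {missing}")
    # apply_preprocessor enforces per-block feature-ID equality and order.
    transformed = apply_preprocessor(model.fitted_preprocessor, new_data)
    X_new = np.concatenate(transformed.blocks, axis=1)
    F_new = X_new @ model.global_loadings

    approximate = model.config.deflation != "block"
    block_scores = None
    if not approximate:
        block_scores = [
            Xk @ Ak for Xk, Ak in zip(transformed.blocks, model.block_loadings)
        ]
    else:
        logger.warning(
            "prediction under global-score deflation is approximate: the "
            "training identity F = XA does not hold exactly in that mode"
        )
    return PredictionResult(
        global_scores_new=F_new,
        block_scores_new=block_scores,
        sample_ids=list(new_data.sample_ids),
        approximate=approximate,
    )
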