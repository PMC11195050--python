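# mbnipals

Multi-block joint dimensionality reduction for multi-omics data via a stable
multi-block NIPALS iteration. Implements **multiple co-inertia analysis
(MCIA)** (block-loading deflation) and **consensus PCA (CPCA)**
(global-score deflation) for collections of sample-by-feature blocks sharing
the same samples, with:

- within-block (column) and whole-block preprocessing, with fitted
  parameters retained for identical application to new data;
- per-order global/block scores and loadings, unit-norm block-contribution
  weights, and eigendecomposition-free variance explained (the converged
  per-order objective value serves as the pseudo-eigenvalue);
- out-of-sample embedding: project new samples with the same features onto a
  trained model without refitting;
- a seeded synthetic-data generator with planted latent factors and cluster
  structure, so every stage is testable without external datasets;
- a CLI (`decompose`, `predict`, `simulate`) operating on open text formats
  (TSV/CSV, MatrixMarket MTX) — model artifacts are directories of TSV + JSON
  files, consumable from any language.

## Python API

```python
import numpy as np
from mbnipals import (
    SyntheticSpec, generate, decompose, predict_global_scores,
    PreprocessConfig, DecompositionConfig, variance_explained,
    block_contributions, top_features,
)

spec = SyntheticSpec(n=30, block_widths=[50, 20], n_factors=1,
                     block_signal=np.array([[3.0], [3.0]]),
                     noise_sd=0.1, seed=0)
dataset, truth_scores, _ = generate(spec)

result = decompose(
    dataset,
    PreprocessConfig(column_method="center", block_method="unit_variance"),
    DecompositionConfig(num_factors=2, deflation="block"),  # block = MCIA
)
result.global_scores          # (n, R) sample embedding F
result.global_loadings       # (sum p_k, R), F = X_preproc @ A under MCIA
variance_explained(result)    # proportions, sum to 1
block_contributions(result)   # squared block weights, columns sum to 1
top_features(result, order=1, count=10)

new_scores = predict_global_scores(result, dataset)  # out-of-sample embedding
```

Conventions worth knowing (documented in the module docstrings):

- standard deviations and covariances use denominator `n - 1` everywhere;
- the per-order pseudo-eigenvalue is the converged objective value
  `sum_k cov^2(X_k a_k, f)`; other MCIA implementations may scale
  eigenvalues differently;
- `colprofile` column preprocessing is one fixed correspondence-analysis
  style convention: entries become `sqrt(r_i) * (P_ij / r_i - c_j)` with `P`
  the block divided by its grand total and `r`, `c` the row/column masses;
  column masses are frozen at fit time for reuse on new data;
- each order's sign is fixed so the largest-magnitude global-loading entry
  is positive;
- prediction under global-score deflation (CPCA) is flagged approximate:
  the identity `F = X_preproc @ A` is exact only under block deflation.

## CLI

```bash
# generate a synthetic two-block dataset with one planted factor
mbnipals simulate --seed 7 --n 30 --widths 50,20 --factors 1 \
    --signal 3 --noise-sd 0.1 --out-dir sim/

# fit MCIA, write result tables (+ scree / contribution plots)
mbnipals decompose --blocks sim/block1.tsv --blocks sim/block2.tsv \
    --num-factors 2 --deflation block --out-dir model/ \
    --scree --contributions --top-features 10

# embed new samples with the trained model
mbnipals predict --model model/ --blocks sim/block1.tsv \
    --blocks sim/block2.tsv --names block1,block2 --out predicted.tsv
```

Options may also come from a YAML config (`--config`), with keys
`preprocess.column_method`, `preprocess.block_method`,
`decompose.num_factors`, `decompose.deflation`, `decompose.tol`,
`decompose.max_iter`, `decompose.init`, `decompose.seed`; explicit flags
override the file. Sparse blocks are read from `.mtx` files with
`<stem>.rows.txt` / `<stem>.cols.txt` ID sidecars (features-in-rows by
default; see `--mtx-orientation`).

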