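# drfs

Dual-regularized feature selection for labeled sample-by-feature matrices
(bulk or single-cell expression, or any numeric tabular data with class
labels).

The selector fits a non-negative sparse regression of the one-hot class
indicator on the features, with two graph-based penalties on the d×r weight
matrix `W`:

* **class-local term** — for each class, a k-NN RBF similarity graph is
  built over the *features* using only that class's samples; the graph
  Laplacian quadratic form keeps weights of locally interacting features
  coherent within the class;
* **global redundancy term** — a feature graph over all samples penalizes
  cross-column bilinear forms `w_p^T M w_q` (p ≠ q), discouraging large
  weights on globally near-duplicate features.

The objective

```
min_{W≥0} ||XW − Y||_F² + α||W||_{2,1} + β( Ω_local(W)/r + Ω_global(W)/(r(r−1)) )
```

is solved with an augmented-Lagrangian scheme: a slack copy `Z` of `W`
carries the graph penalties, `W` is updated with NMF-style multiplicative
steps, the columns of `Z` have closed-form SPD solves (Gauss–Seidel sweep +
projection), and the multiplier/penalty follow the standard ALM schedule
(μ₀ = 1, ρ = 1.1, μ_max = 1e8). Feature importance is the row sum of the
fitted `W`; ranking is by descending score.

A two-parameter variant (`lambda1`, `lambda2`) decouples the strengths of
the two penalty terms; by default both inherit `beta`.

## CLI

```
# generate the reference synthetic fixture (n=150, d=100, r=3,
# planted informative blocks + near-duplicate features + noise)
drfs simulate --preset reference -o out/sim

# fit: z-score -> graphs (k=10) -> ALM solve -> ranking
drfs fit out/sim/dataset.csv --alpha 100 --beta 1 -o out/fit

# stratified 5-fold CV accuracy of top-k prefixes (linear SVM C=1, 1-NN)
drfs eval out/sim/dataset.csv out/fit/ranking.tsv -o out/eval

# numeric self-test of the two structural identities
drfs check-identities
```

Datasets are delimited text (samples × features plus a `label` column) or
MAT containers with variables `X` (n×d) and `Y` (n×1). Labels are remapped
to contiguous `1..r` by first appearance. Every run directory receives a
YAML config snapshot for reproducibility. Exit codes: 0 ok, 2 bad input,
3 numerical failure.

Note: rankings are computed on the full dataset before cross-validation
(filter-style protocol); the resulting optimism is deliberate and matches
the evaluation design.

## Python API

```python
from drfs import SolverConfig, fit, standardize
from drfs.selection import select
from drfs.synthetic import reference_instance

X, truth = reference_instance()
state = fit(standardize(X), SolverConfig(alpha=100, beta=1, k=10))
result = select(state.W)
result.ranking[:10]      # top features
state.trace_frame()      # per-iteration objective / residual trace
```

## Tests and acceptance report

```
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes, from scratch, the structural-identity
deviations, the update-monotonicity and stationarity checks, the
convergence envelope on the reference fixture, planted-feature recovery
AUROC against a variance baseline, the redundancy-asymmetry count, and the
end-to-end CV accuracy, and writes them as JSON.

One acceptance test (`test_criterion8_redundancy_behavior`) fails by
design: with both penalties tied to a single `beta`, the class-local term's
pull toward equal weights on near-duplicate features dominates the global
term's asymmetric suppression. The companion test shows the suppression
does occur when the global term acts alone (`lambda1=0`).
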