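# mtoscca

Multi-task sparse canonical correlation analysis (CCA) with per-column
orthogonality penalties, for associating one "imaging" feature block with
several "genetic" blocks over the same samples. The package bundles:

- **Solvers** (`mtoscca.solvers`): the orthogonality-penalized model
  (`fit_mtoscca`) and the plain multi-task sparse CCA baseline
  (`fit_mtscca`), solved by alternating regularized least squares with
  half-quadratic reweighting for the L2,1/L1,1 sparsity norms, a linearized
  rank-one orthogonality term, and exact unit-score rescaling after every
  update.
- **Data model** (`mtoscca.data`): validated feature matrices, CSV/TSV I/O,
  column standardization, and sample-id alignment across blocks.
- **Metrics & model selection** (`mtoscca.metrics`): canonical correlation
  coefficients, exhaustive penalty grid search, train/test splitting and
  k-fold utilities.
- **Simulation** (`mtoscca.simulate`): a latent-factor generator
  (rank-one signal plus Gaussian noise, sparse ±1 loadings) and a
  noise-sweep benchmark comparing the two solvers on held-out data.
- **Biomarker evaluation** (`mtoscca.evaluate`): random-forest feature
  screening, top-k weight extraction, ROC/AUC with DeLong or stratified
  bootstrap confidence intervals, and combined-panel evaluation with a
  ridge-logistic combiner.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (oracle equivalence of
the solver updates, monotone descent, constraint satisfaction, baseline
reduction, support recovery at low noise, noise-sweep ordering, exact ROC
pair-counting); the simulation-based ones take a few minutes.

## CLI

The `mtoscca` entry point has four subcommands. Each accepts `--config`
(YAML; flags override file values) and writes a JSON manifest alongside its
outputs with the resolved configuration, seed and package version.

```bash
# generate a synthetic three-block dataset (X.csv, Y1.csv, Y2.csv, truth.csv)
mtoscca simulate --seed 1 --out sim_out

# fit a solver and write per-feature weights
mtoscca fit --x sim_out/X.csv --y sim_out/Y1.csv --y sim_out/Y2.csv \
    --solver mtoscca --out fit_out

# exhaustive penalty grid search (use a YAML config to set candidate lists;
# --resume skips combinations already present in the output CSV)
mtoscca gridsearch --x sim_out/X.csv --y sim_out/Y1.csv --y sim_out/Y2.csv \
    --out grid_out

# train/test evaluation of top-k features (per-feature and combined AUC + CI)
mtoscca evaluate --x sim_out/X.csv --y sim_out/Y1.csv --y sim_out/Y2.csv \
    --labels sim_out/labels.csv --k 10 --out eval_out
```

Example YAML config for `gridsearch`:

```yaml
hyperparams:
  epsilon: 0.01
  max_iter: 50
grid:
  lambda_v1: [0.001, 0.01, 0.1, 1]
  lambda_v2: [0.001, 0.01, 0.1, 1]
  lambda_v3: [0.001, 0.01, 0.1, 1]
  lambda_u1: [0.001, 0.01, 0.1, 1]
  lambda_u2: [0.001, 0.01, 0.1, 1]
```

## Input format

Matrices are delimited text with a header row of feature names and a first
column of sample ids (`sample_id`). Labels files have `sample_id,label`
columns with binary labels. Blocks are aligned by sample-id intersection in
the X block's order; missing or non-numeric cells are rejected with the
offending coordinates.
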