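# cigbls

Channel-independent anchor-graph-regularized broad learning for bioprocess
soft sensing.

A soft sensor predicts a hard-to-measure quality variable (here: product
concentration in fed-batch fermentation) online from easy-to-measure process
variables. `cigbls` implements a wide, backprop-free network trained by a
single closed-form solve:

- **Channel independence** (`ci_mapping`): every process variable gets its
  own isolated random feature map; cross-variable coupling is recovered only
  by the shared linear readout.
- **Anchor RBF enhancement** (`ci_mapping`): enhancement nodes are RBF
  similarities to per-channel K-Means anchors instead of random projections.
- **Anchor-graph manifold regularization** (`graph_reg`): the anchors double
  as graph anchors; a reduced-rank, row-stochastic similarity
  `S = H̄ Δ⁻¹ H̄ᵀ` lets the Laplacian penalty be solved analytically with
  only N×m products — no N×N matrix is ever formed. A dense k-NN Laplacian
  oracle is included for small-N equivalence testing.
- **Fully connected baseline** (`bls_core`): standard broad network and the
  shared ridge solver.
- **Multi-rate preprocessing** (`pipeline`): assay-delay alignment, label
  interpolation, sliding windows, stratified batch splitting, train-only
  min-max scaling, metrics, grid search, ablation and sensitivity drivers.
- **Synthetic data** (`synthetic_data`): a seeded fed-batch generator
  (Monod-type latent kinetics, multi-rate sampling, assay delay, control-mode
  strata, batch-to-batch variability) so everything runs offline.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests with independent oracles (loop
implementations, dense-inverse solves, enumeration K-Means, numerical
optimizers), hypothesis property tests, and `tests/test_acceptance.py` with
the headline analytic equivalences and desk-scale empirical trend checks.

## CLI

```bash
cigbls simulate --out data.csv --seed 0 --n-batches 12
cigbls fit      --data data.csv --seed 0 --out run/
cigbls predict  --model run/model.pkl --data data.csv --out preds.csv
cigbls ablate   --data data.csv --seed 0 --out ablation.csv
cigbls sensitivity --data data.csv --beta-grid 1e-6,1e-2,0.1,1,10 --out sens.csv
```

`fit` writes `metrics.json`, `predictions.csv`, a diagnostic plot and a
pickled model. Model hyperparameters can be supplied as YAML via
`--config` (field names mirror `CIGBLSConfig`).

## Library quick start

```python
from cigbls.experiments import make_benchmark, default_model_config
from cigbls.pipeline import fit_cigbls, predict_cigbls, compute_metrics

train, test = make_benchmark(seed=0)
result = fit_cigbls(train, default_model_config(seed=0))
print(compute_metrics(test.Y, predict_cigbls(result, test.X)))
```

## Notes on scale

Experiment drivers in `cigbls.experiments` run at desk scale (a dozen to
sixty simulated batches, reduced node budgets) so ablation, sensitivity and
complexity-trend studies finish in minutes on one CPU; all sizes are
configurable upward.
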