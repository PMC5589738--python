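# anfiswo

Sugeno neuro-fuzzy regression trained by the whale optimization algorithm
(WOA), with fuzzy c-means rule initialization, PSO/GA baseline optimizers,
repeated-split and k-fold evaluation protocols, and a seeded synthetic data
generator for a seasonal composition-to-concentration prediction task.

The model is a five-layer adaptive neuro-fuzzy inference system (ANFIS):
Gaussian membership functions `exp(-((x-rho)/sigma)^2)` per (rule, input),
product firing strengths, normalized rule weights, linear consequents, and a
weighted-sum output. All free parameters — premise centers/widths and
consequent coefficients/biases, `c*(3d+1)` in total — are optimized jointly
by a bound-constrained metaheuristic minimizing the sum of squared errors on
min-max normalized data. Rule count and initial premise parameters come from
fuzzy c-means clustering of the normalized inputs.

## Layout

| module | role |
| --- | --- |
| `anfiswo.data_model` | tabular container, CSV IO, min-max normalization, splits, k-fold |
| `anfiswo.fcm` | fuzzy c-means, rule-count selection, premise initialization |
| `anfiswo.anfis` | five-layer forward pass, flat parameter encoding, model files |
| `anfiswo.optimizer` | WOA plus PSO and GA behind one interface |
| `anfiswo.training` | fitness, search-space bounds, end-to-end training |
| `anfiswo.evaluation` | RMSE / AAPRE, repeated 70/30 splits, k-fold CV, comparisons |
| `anfiswo.synthetic_data` | seeded fixture generator (seasonal temperature cycle) |
| `anfiswo.cli` | `anfiswo` command-line entry point |

## CLI

```sh
# generate a 120-sample synthetic dataset
anfiswo simulate --n 120 --seed 1 --out data.csv

# train one model per target (WOA, population 25, 100 iterations)
anfiswo train --data data.csv --rules auto --pop 25 --iters 100 \
    --seed 1 --out model.json -v

# predict and evaluate
anfiswo predict --model model.json --data data.csv --out pred.csv
anfiswo evaluate --data data.csv --repeats 10 --seed 1 --out report.csv
anfiswo cv --data data.csv --k 10 --seed 1 --out cv_report.csv

# compare optimizers under identical splits
anfiswo compare --data data.csv --algorithms woa,pso,ga --seed 1 --out cmp.csv
```

All outputs are plain CSV or versioned JSON text files; every command is
deterministic for a fixed `--seed`.

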