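# qsarforge

Tools for building and rigorously validating small-molecule QSAR
(quantitative structure–activity relationship) regression models, aimed at
the classic medicinal-chemistry setting: a few dozen compounds (e.g. enzyme
inhibitors with measured pIC50 = −log₁₀ IC50 [M]) described by a large pool
of computed molecular descriptors, from which a handful must be selected to
build an interpretable model.

The package implements the full workflow as composable stages:

1. **Descriptor reduction** — remove constant and near-constant columns
   (mode frequency ≥ 0.95 by default) and resolve collinear pairs
   (|Pearson r| > 0.9), keeping the member better correlated with activity.
2. **Cluster-based splitting** — hierarchical clustering (Euclidean distance
   on autoscaled descriptors) partitions compounds into a training and a
   test set, one test compound per cluster, with the activity extremes
   reserved for training so the test set lies inside the training range.
3. **Genetic-algorithm descriptor selection** — fixed-size subsets evolved
   by tournament selection, uniform crossover and swap mutation, scored by
   the leave-one-out cross-validated Q² of an OLS model on the subset.
   Repeated runs yield a ranked table of alternative models.
4. **Models** — ordinary least-squares MLR with coefficient standard errors,
   and RBF ε-SVR tuned by leave-one-out RMSE over a (C, ε, γ) grid, both on
   the same selected subset.
5. **Validation battery** — R², RMSE, Fisher F, adjusted R²,
   Q²_LOO = 1 − PRESS/SS_tot, bootstrap Q², Y-randomization, Lin's
   concordance correlation coefficient (CCC), Roy's modified R² (rm²),
   the Golbraikh–Tropsha external-predictivity conditions, and variance
   inflation factors.
6. **Applicability domain** — leverage (Williams plot, h* = 3p′/n,
   ±3 standardized-residual bounds) and Euclidean normalized mean-distance
   scores anchored to [0, 1] on the training set.

Because real descriptor matrices of this kind are rarely published, the
package ships a synthetic-data generator that plants known structure
(informative subset, constant/near-constant columns, collinear pairs,
Gaussian activity noise) so every stage can be tested against ground truth.

## Worked example

```python
from qsarforge import GaConfig, PipelineConfig, run
from qsarforge.synth import SynthConfig

config = PipelineConfig(
    synth=SynthConfig(seed=3),            # 35 compounds, 200-descriptor pool
    ga=GaConfig(subset_size=5, n_runs=10, seed=1),
    split_seed=2, n_boot=5000, validation_seed=4,
)
report = run(config)
print(report["mlr"]["equation"])
```

prints the fitted five-descriptor equation with standard errors:

```
pIC50 = 6.226 (± 0.072) + 0.212 (± 0.069) D0086 - 0.397 (± 0.071) D0100
      + 0.605 (± 0.061) D0118 + 0.306 (± 0.069) D0129 - 0.324 (± 0.059) D0143
```

and the validation block reports (`report["validation"]["mlr"]`):

```
train R² = 0.917, RMSE = 0.290, F = 48.758, R²_adj = 0.898
Q²_LOO = 0.865, Q²_BOOT = 0.846 (5000 resamples)
Y-randomization (10 shuffles): max R² = 0.437
test R² = 0.298, rm² = 0.231, CCC = 0.520
Golbraikh–Tropsha: condition I passed, II–IV failed
```

This run is deliberately instructive: the GA recovered four of the five
descriptors that truly generate the activity (`report["truth"]`), the
internal statistics look excellent, and Y-randomization confirms the signal
is not chance — yet the 7-compound external test set exposes the overfitted
fifth descriptor, and the Golbraikh–Tropsha conditions reject the model's
external predictivity. With `noise_sd=0.0` the same pipeline recovers the
exact generating subset with R² = Q² = 1 and all conditions passing. The
leverage threshold for this 28-compound, five-descriptor training set is
h* = 3·6/28 ≈ 0.64; all training compounds fall below it (max h = 0.54).

Every stage is also available on its own (`qsarforge.preprocess`,
`qsarforge.split`, `qsarforge.gaselect`, `qsarforge.models`,
`qsarforge.validate`, `qsarforge.domain`), and from the shell:

```sh
qsarforge simulate --out data.csv --truth truth.json
qsarforge prepare  --in data.csv --out reduced.csv
qsarforge split    --in reduced.csv --seed 7 --out split.json
qsarforge select   --in reduced.csv --split split.json --k 5 --out ga.json
qsarforge fit      --in reduced.csv --split split.json --subset ga.json --model mlr --out mlr.json
qsarforge validate --in reduced.csv --split split.json --subset ga.json --out report.json
qsarforge domain   --in reduced.csv --split split.json --subset ga.json --out domain.json
qsarforge run      --config run.yaml --outdir out/
```

## Layout

```
src/qsarforge/
  table.py       DescriptorTable container (CSV I/O, autoscaling)
  synth.py       synthetic descriptor/activity generator with ground truth
  preprocess.py  constant/near-constant and collinearity filters
  split.py       dendrogram + cluster-based train/test split
  gaselect.py    GA subset search and exhaustive-search cross-check
  models.py      MLR and RBF ε-SVR model/results classes
  validate.py    the statistics battery
  domain.py      leverage and Euclidean applicability domains
  pipeline.py    end-to-end orchestration from a single config
  cli.py         click-based command-line interface
docs/methods.md  modelling and design notes
```
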