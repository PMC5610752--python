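# Methods and design notes

## Setting and model

The package targets congeneric-series QSAR: n ≈ 35 compounds with activity
y = pIC50 (−log₁₀ IC50 in molar units, typically spanning ~4–8) and a pool of
p ≫ n computed molecular descriptors. The working model is linear,

    y = β₀ + Σⱼ βⱼ xⱼ + ε,   ε ~ N(0, σ²),

over a small selected subset (five descriptors by default), with an RBF
ε-support-vector regression fitted on the same subset as the nonlinear
comparator. The scientific burden in this regime is not the fit itself but
the selection and validation: with dozens of compounds and hundreds of
candidate descriptors, chance correlation is the dominant failure mode, so
the package treats the validation battery and the applicability domain as
first-class outputs.

## Synthetic data generator

Real Dragon-style descriptor matrices are rarely published, so all tests run
on synthetic tables with planted, recoverable structure. Descriptor
marginals are standard normal — the scale-free form in which descriptors are
consumed downstream (distances and kernels operate on autoscaled data, and
OLS is scale-equivariant). Planted features:

* `n_constant` exactly constant columns and `n_near_constant` columns whose
  mode occupies 97% of rows (just above the 95% filter default);
* `n_collinear_pairs` pairs x₂ = x₁ + N(0, σ²) with σ² = 1/0.95² − 1, giving
  population correlation ≈ 0.95;
* `k_informative` columns generating the activity linearly. Coefficients are
  drawn uniformly from ±[0.5, 2.0] — a 4:1 relative spread, so subsets mix
  strong and marginal descriptors as real models do — and the noiseless
  signal is mapped affinely onto the target window (default [4, 8] pIC50)
  before N(0, noise_sd²) noise is added. Only the relative spread matters:
  the affine map normalizes the absolute scale. Default noise_sd = 0.2 is a
  typical inter-laboratory reproducibility for IC50 measurements on the log
  scale.
* the optional nonlinear variant adds one interaction term γ·xᵢxⱼ with γ set
  so the interaction carries 20% of the linear signal variance — enough for
  a kernel method to gain a measurable edge over OLS without drowning the
  linear part.

What the generator does **not** emulate: heavy-tailed and discrete
descriptor distributions, block-correlation structure across descriptor
families, and activity cliffs. Passing recovery tests on this generator
therefore shows the machinery is correct under its stated assumptions, not
that any particular real dataset is well modelled.

## Preprocessing

Constant/near-constant removal uses exact zero range or a mode-frequency
rule (default 0.95; 1.0 restricts to exactly-constant). Collinear pairs with
|Pearson r| > 0.9 are resolved greedily in descending |r| (name-ordered on
ties), keeping the member with the larger |r| to the activity; columns
already dropped are skipped, which makes chained collinearity (A~B~C)
deterministic. Both passes preserve column order and are idempotent.

## Train/test split

Compounds are clustered agglomeratively (SciPy linkage) on autoscaled
descriptors with Euclidean distance; complete linkage is the default because
it yields compact, balanced clusters, with ward/average/single selectable.
The tree is cut into as many clusters as test compounds
(round(test_fraction·n); 7 for the canonical 35-compound, 0.2-fraction
setting, giving the 28/7 split) and one test compound is drawn per cluster.
The compounds carrying the global activity minimum and maximum are always
kept in training, which guarantees the test activities lie inside the
training range; if those reserved compounds monopolize whole clusters the
cut is deepened until enough selectable clusters exist. Selection is seeded
and retried (bounded, default 100) until the range-coverage invariant holds.

## GA descriptor selection

Chromosomes are fixed-size index sets (all reference models have exactly
five descriptors; variable-length encodings trade interpretability for
nothing here). Operators: tournament selection (size 3), uniform crossover
repaired to fixed size (shared genes kept, remainder drawn from the
symmetric difference), single-gene swap mutation, elitism (default 2, which
makes the best-so-far fitness non-decreasing). Defaults — population 50,
100 generations, crossover 0.8, mutation 0.1 — are conventional values for
pools of a few hundred descriptors and are fully exposed. Fitness defaults
to Q²_LOO of the candidate OLS model, computed through the closed-form PRESS
identity PRESS = Σ(eᵢ/(1 − hᵢ))², which makes a fitness evaluation one QR
decomposition; PRESS and training R² are selectable. Rank-deficient subsets
score −∞. Equal-fitness subsets are ordered lexicographically by descriptor
name so results are reproducible. `n_runs` independent seeded runs (spawned
from one seed sequence) give the ranked alternative-model table; the best
run is the reported model.

On small pools the GA is verified against exhaustive enumeration with the
same fitness; at the reference recovery conditions (n = 35, p = 100, k = 5,
noise 0.2) it recovers ≥ 4 of 5 true descriptors in ~85% of seeded runs.
With fewer training rows and larger pools (e.g. a 28-compound training set
against ~190 reduced descriptors, the paper-shaped pipeline default)
best-of-many-runs selection visibly inflates internal statistics relative to
external test performance — the motivating case for the battery below, and
visible in the README's worked example.

## Models

MLR is OLS with intercept (statsmodels backend); standard errors come from
the unbiased residual variance and the inverted normal matrix, and the
results object renders the conventional `b (± se) NAME` equation. Rank
deficiency is a hard error, not a pseudo-inverse fallback.

The SVR autoscales descriptors and activity on the training rows (RBF
kernels need commensurate scales; ε is therefore expressed in SD units of
the training activity) and back-transforms predictions. Hyperparameters are
tuned by leave-one-out RMSE — the training-set scaling is computed once, and
each fold refits on n−1 scaled rows — over a default grid
C ∈ {1, 10, 50, 100}, γ ∈ {0.1, 1, 5, 10}, ε ∈ {0.001, 0.01, 0.1}; ties
break toward the smallest C, then γ, then ε. Predictions are verified
against an independently solved ε-SVR dual quadratic program on small
problems (agreement ≤ 1e-4).

## Validation battery

* R² = 1 − SS_res/SS_tot for model fits; the squared Pearson correlation is
  used for external test R², matching the convention of published external
  tables. Both are exposed.
* F = (R²/p)/((1 − R²)/(n − p − 1)) and R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1).
* Q²_LOO by explicit one-compound-out refitting (any model factory), with
  PRESS summed over deleted predictions and SS_tot about the full-set mean.
  The OLS closed form used inside the GA is tested to agree to 1e-10.
* Q²_BOOT: seeded bootstrap resamples of training rows, refit on the
  resample, predict out-of-bag rows; squared errors and squared deviations
  from each resample's mean are **pooled** across replicates (the estimator
  is otherwise undefined for replicates with tiny out-of-bag sets). Empty
  out-of-bag resamples are redrawn. Default 5000 replicates.
* Y-randomization: permute the activity (seeded), refit, record (R², Q²);
  default 10 shuffles. A sound model shows all shuffled R² far below the
  unshuffled one.
* CCC (Lin) with biased 1/n moments: 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²).
* rm² = r²(1 − √(r² − r0²)) with r² the squared correlation and r0² the
  origin-constrained determination coefficient, predicted values on the
  y-axis by default (the transposed convention is a switch); r² − r0² is
  floored at zero.
* Golbraikh–Tropsha: k = Σ(obs·pred)/Σpred², k′ = Σ(obs·pred)/Σobs², r0² and
  r0′² from the corresponding origin-constrained fits; conditions
  I: Q² > 0.5, II: R² > 0.6, III: (r² − r0²)/r² < 0.1 with 0.85 < k < 1.15
  (or the primed variant), IV: |r0² − r0′²| < 0.3.
* VIFs are the diagonal of the inverse correlation matrix (printed lower
  triangles are mirrored first); this equals 1/(1 − Rᵢ²) per descriptor and
  is cross-checked against the per-descriptor regression route to 1e-9.

## Applicability domain

Leverage: hᵢ = xᵢᵀ(XᵀX)⁻¹xᵢ with an intercept column, threshold h* = 3p′/n
(p′ = descriptors + 1; 3·6/28 ≈ 0.64 for the canonical five-descriptor,
28-compound training set). Standardized residuals divide by the training
regression SD √(RSS/(n − p′)) for training and query rows alike; the
in-domain region is h ≤ h*, |standardized residual| ≤ 3. Euclidean scores:
mean distance of each compound to all training compounds on autoscaled
descriptors (self-distance excluded for training rows — including it would
systematically deflate training scores), min-max normalized over training so
training scores span exactly [0, 1]; query compounds reuse the training
normalization and are flagged outside [0, 1].

## Determinism and numerical choices

Every stochastic step (generator, split sampling, GA, bootstrap,
Y-randomization) takes an explicit seed recorded in its report; the pipeline
reproduces its consolidated JSON bit for bit under a fixed config. Exact
fitness ties in the GA and identical activity correlations in the collinear
filter break lexicographically by descriptor name. Degenerate inputs raise
typed errors (zero-variance activity, rank-deficient designs, leverage of 1
in LOO, all-identical mean distances) rather than returning NaNs.

## Known limitations

* The generator's independence assumptions make selection easier than on
  real descriptor families with block correlation; recovery rates here are
  an upper bound on real-data behaviour.
* With very small training sets and large pools, Q²-driven best-of-many GA
  selection inflates internal statistics; external statistics on a
  7-compound test set are themselves high-variance, so single-split external
  R² should be read qualitatively.
* The SVR tuning scales once on the full training set rather than per LOO
  fold; with n ≈ 28 the difference is negligible but the choice is stated.
* F statistics for test sets and kernel-model F values are not defined here;
  the F reported is the training-set regression F.
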