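# survforest

Survival forests for right-censored time-to-event data, built to compare
the three classic splitting strategies head-to-head on equal machinery:

* **RSF** (`RandomSurvivalForest`) — log-rank splitting. At each node the
  candidate variable *X<sub>j</sub>* and cutpoint *c* maximising the
  standardized two-sample log-rank statistic

  L(X_j, c) = Σ_k (d_kl − Y_kl·d_k/Y_k) / √( Σ_k (Y_kl/Y_k)(1 − Y_kl/Y_k)·((Y_k − d_k)/(Y_k − 1))·d_k )

  are chosen jointly over all candidates and cutpoints.
* **CIF** (`ConditionalInferenceForest`) — conditional-inference (two-step
  permutation-test) splitting. Step 1 standardizes the linear rank
  statistic T_j = Σ_i g(x_ji)·h_i (h = log-rank scores) by its exact
  conditional permutation moments and picks the smallest-p variable,
  stopping at level α (Bonferroni over the drawn candidates); step 2
  maximises the standardized two-sample statistic over that variable's
  cutpoints.
* **MSR-RF** (`MaxstatSurvivalForest`) — maximally selected rank
  statistics. One scan over log-rank scores gives each candidate its best
  cutpoint *and* a multiplicity-adjusted p-value
  (Lausen–Schumacher-type approximation over the admissible quantile
  band); the smallest-p candidate splits the node, subject to the same
  α-stop.

All three share bootstrap resampling (`≈ 36.8%` of subjects out-of-bag
per tree), `mtry = ⌊√M⌋` candidate draws, Nelson–Aalen / Kaplan–Meier
leaf estimates and CHF-averaging aggregation, so any performance
difference is attributable to the split rule alone.

Around the estimators the package ships, as first-class tested code:

* `survforest.simgen` — nine synthetic generating models (linear,
  interaction, equicorrelated-normal and high-dimensional
  continuous/binary designs) with survival times
  `T = −log(U)·exp(0.5 + βᵀX)` and exponential censoring calibrated to
  target marginal rates {0, 25, 50, 75}%; exactly two covariates carry
  signal in every model.
* `survforest.importance` — out-of-bag permutation variable importance
  (increase in `1 − C` of the OOB ensemble risk) and the selection
  frequency of both causal covariates ranking in the VIM top 2.
* `survforest.metrics` — IPCW Brier score BS(t), integrated Brier score
  IBS = ∫₀^τ BS(t)dt / τ, Harrell's c-index and the censoring-time
  Kaplan–Meier estimator Ĝ.
* `survforest.experiments` — a deterministic Monte-Carlo driver over
  (model × N × censoring × ρ × M/N) grid cells plus a repeated-split
  real-data path for `time,status,covariates` CSV tables, exposed on the
  command line as `survforest simulate | realdata | report`.

Estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`/`set_params`, fitted attributes with trailing underscores),
where `predict` returns the ensemble-mortality risk score (ensemble CHF
summed over the training event-time grid; larger = shorter predicted
survival).

## Worked example

```python
import numpy as np
from survforest import MaxstatSurvivalForest, evaluate_predictions, permutation_importance
from survforest.simgen import GeneratorSpec, make_replicate

spec = GeneratorSpec("C", n_train=200, target_censoring=0.25, rho=0.0, seed=7)
train, test = make_replicate(spec)   # model C: eta = x1 + 1.5*x2, 8 noise covariates

forest = MaxstatSurvivalForest(n_trees=200, random_state=0).fit(train.X, train.y)
vim = permutation_importance(forest, random_state=1)
print(vim.sort_values("rank").head(4).to_string(index=False))
ev = evaluate_predictions(forest, test.X, test.y)
print(f"test IBS = {ev['ibs']:.3f}   test c-index = {ev['cindex']:.3f}")
```

Output:

```
 variable      vim  rank
        1 0.272733     1
        0 0.067430     2
        8 0.001240     3
        9 0.001181     4
test IBS = 0.087   test c-index = 0.795
```

The two truly prognostic covariates (columns 0 and 1; column 1 carries
the larger coefficient, 1.5 vs 1.0) take VIM ranks 1–2, with an order of
magnitude gap to the best noise covariate. The integrated Brier score of
0.087 on the held-out 20% (0 would be perfect, 0.25 is the uninformative
constant-½ prediction) and a c-index of 0.795 summarise test-set
prediction accuracy.

The same study runs from the shell:

```bash
survforest simulate --model C --n-train 200 --censoring 0.25 --rho 0.0 \
    --reps 100 --seed 1 --out results/
```

which writes one tidy row per (replicate, method) and an aggregated
table with selection frequencies, mean IBS/c-index and Monte-Carlo
standard errors.

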