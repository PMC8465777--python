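# Methods

## Model and scope

The package studies ensembles of binary survival trees for right-censored
data `(t_i, δ_i, X_i)` under the random-forest recipe: each of `B` trees
is grown on a bootstrap multiset of the training sample (so on average
`(1 − 1/n)^n → e⁻¹ ≈ 36.8%` of subjects are out-of-bag per tree), each
node draws `mtry` candidate covariates without replacement, and tree
predictions are aggregated by arithmetic averaging of leaf estimates.
Three node-splitting rules are implemented on this shared engine; they
are the object of comparison.

**Log-rank splitting (RSF).** Over the node's distinct event times
`t_1 < … < t_K` with event/at-risk counts `d_k`, `Y_k` (left-child
counts `d_kl`, `Y_kl`), the rule maximises the absolute standardized
log-rank statistic

```
L(X_j, c) = Σ_k (d_kl − Y_kl d_k/Y_k)
            / sqrt( Σ_k (Y_kl/Y_k)(1 − Y_kl/Y_k) ((Y_k − d_k)/(Y_k − 1)) d_k )
```

jointly over candidate variables and cutpoints. Variance terms with
`Y_k = 1` are skipped (they are undefined and carry no information).
This rule attaches no hypothesis test: depth is limited only by the
node-size constraints below.

**Conditional-inference splitting (CIF).** Log-rank scores

```
a_i = δ_i − Ĥ(t_i),   Ĥ = Nelson–Aalen cumulative hazard of the node
```

serve as the influence values `h`. For distinct times this equals the
textbook per-observation sum `δ_i − Σ_{k ≤ Γ_i} δ_k/(n − Γ_k + 1)`; with
tied event times the Nelson–Aalen form shares the hazard increment
across the tie, which is what makes `Σ a_i = 0` hold exactly for every
censoring pattern (the per-observation sum double-counts tied events and
loses this invariant). Step 1 computes, per candidate, the linear
statistic `T_j = Σ g(x_ji) h_i` with `g` the identity for
numeric/ordered covariates, standardized by its exact conditional
permutation moments

```
μ = (Σg)(Σh)/n,    σ² = n/(n−1)·V_h·Σg² − 1/(n−1)·V_h·(Σg)² ,
```

(`V_h` the mean-square deviation of `h`; this reduces to the classical
`Σ(g−ḡ)² Σ(h−h̄)²/(n−1)`), with a two-sided standard-normal reference.
p-values are Bonferroni-adjusted over the candidates actually tested; if
the smallest adjusted p is ≥ α the node stops. Step 2 maximises the
absolute standardized two-sample statistic `Σ_{x ≤ c} h_i` (the
`g = I(x ≤ c)` special case of the same moments) over the selected
variable's cutpoints. The normal reference is asymptotic; the test suite
verifies both moments and tail probabilities against explicit Monte-
Carlo permutation at small n.

**Maximally-selected-rank splitting (MSR-RF).** With the same log-rank
scores, the standardized statistic at cutpoint `c` is

```
S(X_j, c) = (Σ_{x ≤ c} a_i − n_l ā) / sqrt(n_l n_r S_a²/n)
```

where `S_a²` is the (n−1)-denominator sample variance — exactly the
permutation SD of the left-child score sum, so `S` and the CIF step-2
statistic coincide at a fixed cutpoint. One pass over the admissible
band `minprop ≤ n_l/n ≤ 1 − minprop` records each candidate's maximum
`M_j` and a p-value for that maximum; the smallest-p candidate splits at
its recorded cutpoint if its Bonferroni-adjusted p beats α.

The p-value of the maximum uses an improved-Bonferroni scheme: the
Lausen–Schumacher large-sample approximation

```
P(max |S| > b) ≈ 4φ(b)/b + φ(b)(b − 1/b)·log( (1−ε₁)ε₂ / ((1−ε₂)ε₁) )
```

over the realised band `[ε₁, ε₂]`, capped by the plain Bonferroni bound
`n_cut · p_pointwise`, floored at the pointwise two-sided normal p (the
maximum over one cutpoint cannot be less significant than that cutpoint
alone), and clipped to [0, 1]. A single admissible cutpoint gets the
exact pointwise p. Under the global null the realised root-split rate is
verified to stay at or below α.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_trees` | 200 | benchmark convention for all forests |
| `mtry` | ⌊√M⌋ | candidate covariates per node |
| `alpha` | 0.05 | α-stop for the two test-based rules |
| `min_node_size` | 5 | members below which a node is a leaf |
| `min_node_events` | 3 | events below which a node is a leaf |
| `minprop` | 0.1 | admissible quantile band for maximally selected statistics (reference-implementation default) |
| `random_state` | None | seeds bootstrap + candidate draws via one spawned seed sequence per tree |

Node-size defaults are deliberate round numbers in the range spanned by
the reference R implementations (which disagree among themselves: 3–15
depending on package); selection-frequency results proved insensitive to
this choice across that whole range.

## Numerical and structural conventions

* **Leaf estimates.** Nelson–Aalen CHF and Kaplan–Meier survival of the
  node's in-bag members, precomputed on the forest-wide grid of distinct
  training event times; between knots, last value carried forward;
  survival clipped to [0, 1] after averaging. The risk score
  (`predict`) is the ensemble CHF summed over the grid ("ensemble
  mortality").
* **Aggregation.** All three rules share CHF averaging. The
  observation-weight aggregation sometimes used with conditional
  inference trees is deliberately not implemented, so that the split
  rule is the only moving part; this is a simplification, flagged, not
  assumed immaterial.
* **Unordered factors** (integer codes `1..k`). The log-rank rule
  enumerates all `2^(k−1) − 1` binary level partitions for `k ≤ 8`
  (≤ 127 partitions); above 8 levels — and always for the two rank-based
  rules, whose statistics need a univariate ordering — levels are
  ordered by their within-node mean log-rank score and the ordering is
  scanned as monotone cutpoints. Splits store the left level set as a
  bitmask. A level unseen at the node during training routes to the
  child that received more training members (ties left), so prediction
  never fails.
* **Tie-breaking.** Split statistics: smallest variable index, then
  smallest cutpoint. p-value ties: smallest variable index. VIM rank
  ties: smallest variable index (relevant only at exact ties, e.g.
  variables used by no tree, whose importance is exactly 0).
* **Degenerate nodes.** No events, constant candidates, or zero score
  variance ⇒ leaf. All-censored training data yields single-leaf trees
  with CHF ≡ 0, survival ≡ 1.
* **Determinism.** `(data, params, random_state)` fixes the forest
  bit-for-bit; per-tree generators are spawned from one seed sequence,
  and experiment replicates are seeded by `(master seed, cell id,
  replicate index)` so any grid cell is independently re-runnable.

## Variable importance and selection frequency

Baseline error is `1 − C` (Harrell) of the out-of-bag ensemble risk:
each training subject's risk is averaged over the trees in which it is
OOB (subjects in-bag everywhere are excluded and flagged). For each
covariate, its column is permuted with a fixed per-variable sub-seed,
OOB predictions are recomputed — only trees whose split set contains the
variable are re-routed, so a variable used by no split has importance
exactly 0 — and `VIM = permuted error − baseline error` (averaged over
`n_perm` permutations, default 1). Ranks are 1..M by descending VIM.
The selection frequency of a simulation cell is the fraction of
replicates in which **both** causal covariates occupy ranks 1–2.

## Prediction-error metrics

The IPCW Brier score at time t is

```
BS(t) = 1/N Σ_i [ Ŝ(t|X_i)² I(t_i ≤ t, δ_i = 1)/Ĝ(t_i⁻)
                + (1 − Ŝ(t|X_i))² I(t_i > t)/Ĝ(t) ]
```

with `Ĝ` the Kaplan–Meier estimator of the censoring-time survival,
estimated marginally on the evaluation (test) sample itself. The event
term uses the left limit `Ĝ(t_i⁻)` so the weight at the largest event
time stays positive. The evaluation grid is the distinct observed test
times truncated at the last time with `Ĝ > 0`; IBS is the trapezoidal
integral divided by the upper integration limit, with the first curve
value carried back to 0 (so a constant curve integrates to its
constant, and the uninformative Ŝ ≡ ½ prediction scores exactly 0.25
without censoring). Harrell's c-index counts pairs whose shorter
observed time is an event (or an event tied with a censored time);
risk-score ties count ½. Without censoring BS(t) reduces exactly to the
mean squared difference between `I(t_i > t)` and `Ŝ(t|X_i)`.

## Synthetic-data generator

Nine generating models produce covariates (uniform, standard normal,
equiprobable discrete-uniform factors with 2/4/8 levels, equicorrelated
MVN with off-diagonal ρ, or M iid normal/binary columns), a linear
predictor η with exactly two signal covariates, survival times by
inverse transform `T = −log(U)·exp(0.5 + η)` (U sampled in the open
interval, so T is strictly positive and finite; `T|X` is exponential
with mean `exp(0.5 + η)`), and exponential censoring `C ~ Exp(λ)` with
observed time `min(T, C)` and `δ = I(T ≤ C)`. λ solves the marginal
equation `E_X[λ/(λ + μ(X))] = target` (`μ(X) = exp(−(0.5 + η))`) by
monotone root finding on log λ over a fixed 10⁵-subject covariate sample
with a fixed calibration seed — calibration is marginal, not conditional
on X, and the indicator cutoffs of the categorical models are placed so
half the subjects score 1. Subjects are generated at `n_train/0.8` and
split 80/20 uniformly at random (generation before splitting; no
stratification by event). Tied observed times are legal and handled
downstream; nothing is jittered.

What the generator does **not** emulate: non-exponential baseline
hazards, covariate-dependent or informative censoring, nonlinear or
higher-order signal beyond the one product-interaction family, and
measurement error. Passing tests therefore demonstrate correct recovery
under a proportional-hazards exponential world with noninformative
censoring — not robustness on arbitrary real data.

## Problem sizes used by the tests and the acceptance script

Monte-Carlo checks run at reduced replication chosen to keep the whole
suite at desk scale while leaving binomial standard errors small
relative to the margins tested: 100–150 replicates for the
selection-frequency cells (N = 40–100), 10 replicates for the
near-complete-selection check at N = 800, 6 replicates per cell for the
directional IBS-vs-dimension trend, 10⁴ draws for the bootstrap OOB
fraction, and 2·10⁴–10⁵ random permutations for the permutation-moment
oracles. Every reported frequency or mean carries its replicate count.

## Design choices that were genuinely open

* **Influence function** for both rank-based rules: log-rank scores
  (rather than Savage or Wilcoxon variants), for comparability across
  the three methods — the two-sample standardizations then agree
  exactly at a fixed cutpoint.
* **Multiplicity adjustment** across candidates: Bonferroni over the
  candidates actually tested, applied identically to CIF and MSR-RF.
* **CIF factor transformation**: score-ordered level rank (keeps the
  statistic univariate) instead of a one-hot multivariate statistic.
* **VIM error functional**: ensemble-level `1 − C` on OOB risk. A
  per-tree (Breiman-style) error-difference variant was evaluated and
  produced materially identical selection rankings, so the simpler
  ensemble convention was kept; it remains the documented convention in
  all outputs.
* **Real-data benchmark**: the proportional-hazards comparator delegates
  to lifelines' Cox implementation; it is a benchmark, not part of the
  forest machinery.

## Known limitations

* Trees are grown depth-first in Python with compiled inner kernels;
  very large training sets (N in the thousands) are outside the design
  envelope.
* The maximally-selected p-value approximation is asymptotic; at very
  small nodes it is conservative (verified empirically), which can only
  make the α-stop stricter.
* Selection frequencies at small samples are sensitive to the VIM
  convention only through ties at zero importance; ties are broken by
  variable index and documented as such.
* The CIF aggregation simplification above means this package's CIF is
  a conditional-inference *split rule* inside a common engine, not a
  re-implementation of any particular R package's forest.
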