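# phosvote

Weighted-voting meta-prediction of protein phosphorylation sites.

## The problem

Phosphorylation of serine, threonine and tyrosine residues is the most
common post-translational modification, and dozens of sequence-based
programs predict whether a given S/T/Y site is phosphorylated. Individual
predictors are trained on different organisms and kinase families, so on
any one proteome their accuracy varies widely — but they are partly
complementary, which makes a *meta-predictor* that combines their calls
attractive. `phosvote` implements such a meta-predictor for users who have
binary calls from N element predictors on a common set of candidate sites
and want a single, better, combined call.

## The model

Each element predictor j contributes a binary call P_j ∈ {0, 1} per site.
The meta-predictor is a linear vote: a site is called positive iff

    Σ_j P_j · w_j  ≥  T

with non-negative weights w_j and threshold T (a tie at T is positive).
For a plain vote T defaults to half the total weight, T = (Σ_j w_j)/2.
Weights can be set four ways, all exposed as scikit-learn estimators:

* **unweighted** — w_j = 1 (majority vote);
* **metric-weighted** — w_j = predictor j's ACC or MCC on training data;
* **reduced** — metric weights over the best rank-prefix subset of
  predictors;
* **restricted grid search** — exhaustive search over all weight vectors
  with entries from {0, 1, 3, 5, 7, 9, 11, 13, 15} summing to 15, jointly
  with integer thresholds T ∈ {0..15}, maximizing MCC (≈2.7M weight
  vectors × 16 thresholds, evaluated by vectorized score accumulation);
  followed optionally by a **conditional random search** that redraws each
  weight uniformly from the interval bracketing its grid value and sets
  T = u·Σw_j with u ~ U[0,1), stopping at the first draw that beats the
  grid-search MCC.

Performance is measured by sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP), accuracy ACC = (TP+TN)/n and the Matthews correlation
coefficient

    MCC = (TP·TN − FN·FP) / √((TP+FN)(TN+FP)(TP+FP)(TN+FN)),

plus ROC curves/AUC over the continuous voting score, under label-stratified
10-fold cross-validation with pooled test-fold predictions.

Because real element predictors are external services, the package ships a
synthetic-ensemble generator (one-factor Gaussian copula over binary calls
with exact per-predictor Sn/Sp and tunable redundancy ρ) and a
planted-proteome generator, so the whole pipeline runs self-contained.

## Worked example

```python
import numpy as np
from phosvote import (GridSpec, default_scenario, evaluate_elements,
                      restricted_grid_search, conditional_random_search)

matrix, labels = default_scenario()          # 15 predictors, 2000 sites
best = max(evaluate_elements(matrix, labels), key=lambda r: r.mcc)
print(f"best element predictor: {best.name}  "
      f"ACC={100*best.acc:.1f}%  MCC={best.mcc:.3f}  AUC={best.auc:.3f}")

spec = GridSpec(allowed_weights=(0, 1, 3, 5), weight_sum=5, n_predictors=15)
grid = restricted_grid_search(matrix, labels, spec)
print(f"grid search:  MCC={grid.best_mcc:.3f}  ACC={100*grid.best_acc:.1f}%  "
      f"T={grid.best.threshold:g}  ({grid.n_evaluated} candidates)")
print("weights:", np.asarray(grid.best.weights, dtype=int))

refined = conditional_random_search(matrix, labels, grid, spec,
                                    rng_seed=101, max_iter=2000)
print(f"random search: MCC={refined.best_mcc:.3f}  "
      f"ACC={100*refined.best_acc:.1f}%  T={refined.best.threshold:.2f}  "
      f"converged after {refined.n_evaluated} draws")
```

prints

```
best element predictor: ep10  ACC=71.2%  MCC=0.436  AUC=0.713
grid search:  MCC=0.569  ACC=78.4%  T=3  (26298 candidates)
weights: [1 1 0 1 0 0 0 0 0 1 1 0 0 0 0]
random search: MCC=0.572  ACC=78.5%  T=5.55  converged after 61 draws
```

The grid search concentrates weight on the four most informative
predictors and lifts MCC from 0.436 (best single predictor) to 0.569; the
conditional random search nudges it further to 0.572. The same operations
are available from the shell:

```sh
phosvote simulate ensemble --out-calls calls.tsv --out-labels labels.tsv
phosvote grid-search --matrix calls.tsv --labels labels.tsv \
    --allowed 0,1,3,5 --sum 5 --out grid.json
phosvote random-search --matrix calls.tsv --labels labels.tsv \
    --seed-model grid.json --rng-seed 101 --max-iter 2000 --out refined.json
phosvote predict --model refined.json --matrix calls.tsv
```

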