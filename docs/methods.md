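# Methods

## The voting meta-classifier

Given binary calls P_ij ∈ {0,1} of N element predictors j on n candidate
phosphorylation sites i, the meta-predictor calls site i positive iff
Σ_j P_ij·w_j ≥ T. Two conventions are fixed throughout:

* the tie at score = T is **positive** (the decision rule uses ≥);
* weights are non-negative, so adding a positive call can only move a site
  toward the positive class (monotonicity), and scaling (w, T) by a common
  positive constant never changes any decision.

The canonical threshold of a plain vote is half the total weight,
T = (Σ_j w_j)/2. Optimized strategies treat T as a searched parameter
instead, since the best operating point of an ensemble with heterogeneous
specificities generally lies away from the half-weight point; constructors
accept an explicit threshold override for the same reason.

## Strategy constructors

* **Unweighted**: w_j = 1. Needs no labels.
* **Metric-weighted**: w_j is predictor j's ACC or MCC measured on the
  training data. MCC weights are floored at 0 — a predictor anticorrelated
  with the labels would otherwise receive a negative vote, which the rule's
  non-negativity assumption excludes; such predictors are silenced rather
  than inverted.
* **Reduced**: predictors are ranked by the chosen metric (descending,
  stable in input order) and each prefix top-k (k = 1..N) is evaluated as a
  metric-weighted half-threshold vote; the prefix with the highest MCC wins
  (ties: higher ACC, then smaller k). Restricting to rank prefixes keeps the
  selection O(N) evaluations rather than 2^N subsets; excluded predictors
  keep weight 0 so fitted models always consume full-width call matrices.

## Restricted grid search

Weights are confined to the lattice {0, 1, 3, 5, 7, 9, 11, 13, 15} with
Σ_j w_j = 15 (both constraints configurable), and T ranges over the
integers 0..15. With integer weights and the ≥ rule, any threshold strictly
between two achievable integer scores decides identically to the integer
above it, so the integer T grid loses nothing. Every (w, T) pair is
evaluated; the maximizer of MCC is returned with ties broken by ACC, then
the lexicographically smallest weight vector, then the smallest T, making
the search fully deterministic.

Candidate evaluation is vectorized: compositions are generated in
lexicographic order (with a reachable-sum feasibility table pruning the
recursion), blocked into chunks, scored against all sites in one matrix
product, and reduced to confusion counts per threshold by class-wise
column sums. MCC with any zero marginal is defined as 0. At the default
N = 15 lattice this is ≈2.66M compositions × 16 thresholds; the analytic
grid size is computed as a sum of multinomial coefficients
n!/(m_0!·Π m_v!) over the partitions of the weight budget, never by
enumeration, and the tests verify enumeration = counting on reduced
lattices.

## Conditional random search

The grid optimum seeds a randomized refinement. Each weight is redrawn
uniformly from the half-open interval between the lattice values adjacent
to its grid value — e.g. on the default lattice 0 → [0,1), 1 → [0,3),
3 → [1,5) — with the boundary cases bracketed below by 0 and above by
w_max + 2 (one lattice spacing past the end). The threshold is
T = u·Σ_j w_j with u ~ Uniform[0,1). Draws stop at the first candidate
whose MCC **strictly** exceeds the grid-search MCC, or after `max_iter`
draws (the stopping rule alone need not terminate); the incumbent starts at
the grid solution and is replaced only on (MCC, ACC) improvement, so the
returned result is never worse than the seed. The entire draw sequence is
reproducible from one integer seed.

## Evaluation protocol

Folds are a label-stratified random k-fold partition (default k = 10),
reproducible from a seed; stratification is the finite-sample analogue of
evaluating on a globally class-balanced dataset, and fold sizes differ by
at most one site. Reported numbers are **pooled**: each strategy is refit
on the training folds of every rotation, its test-fold binary calls and
continuous voting scores are pooled across rotations (every site predicted
exactly once), and Sn/Sp/ACC/MCC are computed on the pooled calls with AUC
from the trapezoidal ROC of the pooled scores. Pooling was chosen over
per-fold averaging because it keeps the confusion counts interpretable
(they sum to n) and is well-defined even when a fold lacks a class.

A fixed (w, T) candidate has no trainable state, so its pooled-CV
predictions coincide with direct evaluation on the full data; the searches
therefore score candidates directly, and cross-validation is applied where
it matters — to strategies whose weights are estimated from training data,
and to the hill-climb protocol below.

Weight updates can also follow a hill-climbing acceptance rule: a candidate
replaces the incumbent only if its pooled-CV MCC strictly increases and its
pooled-CV ACC does not decrease. Requiring strict improvement in both
measures would stall on ACC plateaus that MCC can still climb; the
asymmetric reading keeps the accepted trajectory strictly increasing in MCC
and non-decreasing in ACC.

## Dataset construction

Site universes are built from protein sequences plus a positive-site
annotation table. Every S/T/Y residue not annotated positive becomes a
candidate negative. Each site carries its 25-mer window (±12 residues),
'X'-padded at protein termini so window geometry is invariant; positions
are 1-based in all files (Swiss-Prot feature-table convention) and 0-based
internally. Classes are balanced by seeded uniform undersampling of the
majority class without replacement; undersampling is random across residue
types by default because observed negative-set compositions are not
proportional to residue frequencies, so forcing per-residue proportionality
is offered only as a caller-side choice (sample per residue type and
concatenate).

## Synthetic data

The ensemble generator draws labels i.i.d. Bernoulli(positive fraction)
and element calls through a one-factor Gaussian copula: the latent variable
of predictor j on site i is z_ij = √ρ·f_i + √(1−ρ)·ε_ij with f, ε standard
normal, thresholded at Φ⁻¹(Sn_j) on positives and Φ⁻¹(1−Sp_j) on
negatives. Marginal Sn/Sp are therefore **exact** by construction for every
ρ, while ρ tunes predictor redundancy — the single property that most
limits what voting can gain over the best element. A one-factor copula is
the simplest dependence mechanism with that dial; it cannot represent
predictor-pair-specific correlation structure, negatively correlated
predictors, or class-asymmetric dependence, and its calls carry no sequence
information at all. Passing tests on synthetic ensembles therefore
demonstrate the correctness and the qualitative behaviour of the machinery
(complementary predictors → meta gain; redundant ones → little gain), not
the MCC a particular real predictor panel would reach.

Default scenario: 15 predictors whose (Sn, Sp) targets span the spread
observed among real phosphorylation-site predictors benchmarked on plant
proteins (from Sn 0.96/Sp 0.14 to Sn 0.13/Sp 0.97), n = 2000 sites at 50%
positives, ρ = 0.3, seed 20120203. The proteome generator plants positive
sites at rate 0.15 among S/T/Y residues drawn at rates 0.080/0.055/0.030
(near natural amino-acid frequencies) in Poisson-length random sequences
(mean 300, floor 30).

## Problem sizes and numerical choices

The benchmark-scenario tests and the worked example run the grid search on
the reduced lattice {0, 1, 3, 5} with weight sum 5 (4383 compositions × 6
thresholds on 15 predictors), which exercises every code path of the full
search at interactive speed; the full 15-budget lattice is available
through the same interface. Planted-predictor recovery is tested over 100
seeded simulations of 400 sites each. Scores are accumulated in float64;
confusion counts in integers; MCC's zero-denominator case returns 0; Sn/Sp
are reported as absent (None) when their class is missing. All RNGs are
NumPy `default_rng` instances seeded explicitly; no global seeding is used.

## Known limitations

* The reduction strategy searches rank prefixes only, not arbitrary
  predictor subsets; a complementary pair ranked far apart can be missed.
* The conditional random search refines within one lattice cell around the
  grid optimum; it cannot escape a poor grid basin.
* ROC curves from binary element calls have a single interior operating
  point; their AUC is accordingly coarse ((Sn+Sp)/2).
* Statistical significance of MCC differences between strategies is not
  computed.
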