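# Methods

## Model and inference

The model class is the hierarchical latent class model: a rooted tree whose
internal nodes are discrete latent variables (cardinality ≥ 2; binary by
default) and whose leaves are binary observed symptoms. Regularity is
enforced throughout: the root is latent with at least two children, every
latent node has at least two children (no trivial chains), and during state
introduction a latent's cardinality may not exceed the product of its
neighbours' cardinalities divided by the largest — the standard guard
against unidentifiable parameterizations when the BIC penalty uses the
standard dimension d = Σ_nodes (card − 1) × card(parent).

Likelihood and posteriors are exact, by scaled sum-product message passing:
one upward pass per record gives the log-likelihood; an additional downward
pass gives every latent's posterior and every parent–child pairwise
posterior. Messages are rescaled per record by their maximum, with the log
scale accumulated, so 30-leaf records cannot underflow. Missing cells (and
leaves absent from a cohort) are treated as unobserved and marginalized by
the same machinery at no extra cost. Records with probability zero yield
−∞ with a diagnostic naming the record; posterior queries on
zero-probability evidence raise.

Pairwise latent–leaf distributions used in interpretation (mutual
information, class-conditional tables) are computed by composing transition
matrices along the unique tree path, Bayes-inverting CPTs on upward edges
with the node marginals from a single root-to-leaf sweep; no sampling or
approximation anywhere.

## Parameter estimation

Parameters are fit by EM with expected sufficient statistics from the
pairwise posteriors. M-steps add a Dirichlet pseudocount of 0.5 per CPT
cell (default), keeping estimates off the 0/1 boundary; this makes the
procedure MAP-EM under a Dirichlet(1.5) row prior, and the provably
monotone objective is the penalized log-likelihood
logL + 0.5·Σ log θ. Convergence is declared when the relative change of
that objective falls below `tol` (default 1e-6) or after `max_iters`
(default 500); the best of `restarts` (default 8) random initializations is
returned, each CPT cell drawn uniformly from (0.1, 0.9) and rows
renormalized, with per-restart seeds spawned from the master seed. With
pseudocount 0 the tracked per-iteration log-likelihood sequence is the
plain EM sequence and is nondecreasing; the property suite checks this.

A note on tolerances: "relative" is relative to the objective's magnitude,
so on large cohorts (|logL| ~ 10⁵) the default is a loose absolute
threshold. The saturated three-symptom block fits used for the headline
recovery quantities sit on a flat likelihood ridge (prior up / conditionals
down leaves the fitted marginals unchanged), so those fits use tol = 1e-9
with up to 5000 iterations — cheap, because a 3-column binary cohort
collapses to at most 8 weighted patterns. All EM runs collapse the cohort
to unique row patterns with counts before iterating.

## Structure search

Double hill climbing starts from the canonical latent class start — one
binary latent over all selected symptoms — and repeatedly enumerates all
one-operator neighbours: NI introduces a binary latent mediating a sibling
pair (only where the parent keeps ≥ 2 other children), ND deletes a
non-root latent reattaching its children, SI/SD adjust a latent's
cardinality within [2, max_card] (max_card defaults to 2, matching the
all-binary target models), NR relocates any non-root node under another
latent outside its own subtree. Candidates are deduplicated and ordered by
a leaf-labelled canonical structure signature, which also seeds each
candidate's EM deterministically — so the search result is invariant to
cohort column order and reproducible from the master seed.

The two levels of the climb: every candidate is screened with a short EM
(default 20 iterations, warm-started from the incumbent's parameters where
the local structure is unchanged, plus random restarts); only the
best-screened candidate is refit at the full budget, and it replaces the
incumbent only if its full-budget BIC strictly exceeds the incumbent's.
Large neighbourhoods (the 30-leaf start has 435 sibling pairs alone) are
first ranked by an even cheaper pass — 3 warm-started EM iterations — and
only the top `prescreen_keep` (default 48) candidates enter real
screening; this keeps a full 30-symptom search in the minutes range
without changing which moves win in practice.
The climb stops at the first non-improvement. Warm starts rebuild CPTs on
changed edges from the old node marginals with a deterministic tilt across
parent states to break symmetry. Ties among equal-BIC candidates go to
fewer parameters, then fewer latents, then signature order.

## Synthetic cohorts

The generator emulates the restricted study cohort: 587 patients by
default, 30 binary symptoms in the published catalog order, four binary
latent blocks carrying the published class-conditional probabilities
(including the exact 0.00 rows), and seven symptoms that appear in no
published block generated as marginal-only Bernoulli variables at their
published frequencies. Latent priors are unpublished; they are recovered by
solving m = p·p1 + (1−p)·p0 per block symptom and averaging (clipped to
[0.01, 0.99]), giving ≈ 0.34, 0.27, 0.38, 0.051 for the four blocks — the
per-symptom solutions agree within each block to ~0.02, which supports the
approximation. Latents are independent by default (no inter-latent CPTs are
published); star and chain couplings exist for robustness experiments.
Sampling is latent-first, then symptoms independently given the block
state; everything is deterministic given the seed.

What the generator does **not** emulate: demographics, missing answers,
inter-latent dependence, and any ordinal symptom severity. Tests passing on
these cohorts therefore show correctness of the machinery and
recoverability under the published parameter regime — not robustness to
real-data artefacts.

### Known statistical limitation

Two blocks have exactly three symptoms, making their 2-class mixture
exactly saturated (7 parameters, 7 degrees of freedom): the MLE
interpolates the empirical three-way table, and sampling noise in the
cells propagates into parameters with amplification, plus a finite-sample
bias near boundaries. With the qi-deficiency block's marginal-matched prior
of ≈ 0.051, n = 20000 leaves only ~1000 patients in the S1 class, and the
seed-averaged S1 conditionals deviate from truth by up to ≈ 0.05 even
though the optimizer verifiably reaches the global optimum (the fitted
model reproduces the empirical cells to 1e-6 and beats the generating
parameters' likelihood on every seed; at n = 10⁶ the estimates converge to
truth within 0.01). The recovery test asserts a ±0.02 bound and documents
that the small-class saturated entries can exceed it; the over-identified
blocks (11 and 6 symptoms) recover well within it.

## Problem sizes and defaults

* Screening: percentages half-up at 2 decimals (the printed convention);
  variable selection by mean of frequency rank and expert-score rank
  (descending, average ranks over ties), k = 30 by default, ties to the
  higher-frequency symptom then lexicographic id.
* Mutual information in bits (log2); information coverage normalizes by the
  latent's total MI over all leaves (a config switch away from
  entropy-normalization, which is not used by default), threshold 0.95.
* Hard pattern assignment: S1 iff posterior > 0.5; ties go to S0
  ("pattern absent" is the conservative default).
* Structure-recovery runs use n = 5000 cohorts with screening budgets of
  12 EM iterations / 1 random restart + warm start, full refits at 300
  iterations / 2 restarts; parameter-recovery runs use n = 20000 and 5
  seeds. These sizes keep each experiment in the minutes range while
  leaving the conclusions unchanged at larger budgets.
* Reported tables round half-up to 2 decimals; model JSON stores full
  precision with a versioned schema.
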