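# Methods

## Problem and model

Signalling pathways curated from databases are directed graphs over
genes whose edges carry an interaction class (activation, inhibition,
binding, expression, state transition) and whose nodes can be annotated
with a cellular compartment along the signalling axis
extracellular < membrane < cytoplasm < nucleus.  These graphs are
usually cyclic (negative feedback, mutual phosphorylation), while a
Bayesian network requires a DAG, so a reconstruction step must decide
which edges to remove.  `pathbn` implements five such strategies and
everything needed to compare their downstream consequences.

Given a DAG, each pathway is modelled as a linear-Gaussian Bayesian
network: node `Y` with parents `X_1..X_k` follows
`Y = β₀ + Σ βᵢXᵢ + ε`, `ε ~ N(0, σ²)`.  The joint density factorizes
over nodes, so the per-sample pathway score is the sum of conditional
Gaussian log-densities (natural log throughout), identical to the
log-density of the multivariate normal with mean `(I−B)⁻¹b` and
covariance `(I−B)⁻¹D(I−B)⁻ᵀ` — the identity the test suite checks to
1e-8 against an independent matrix-algebra oracle.

## The five reconstruction strategies

Every strategy first removes self-loops (logged separately under reason
`self_loop`) and returns, besides the DAG, a complete ledger of removed
edges with reason codes and per-edge evidence.  An invariant checked on
every result: removed ∪ kept partitions the self-loop-free input, and
only the cyclegroup strategy may add edges.

**Random insertion (`props`).**  Edges are visited in a seed-determined
uniform permutation and inserted unless insertion would close a cycle
(path target→source already present).  Rejection is monotone in the
growing graph, so every removed edge re-creates a cycle if re-added to
the final DAG — a maximality property the suite asserts on hundreds of
random graphs.

**Evidence ranking (`clipper`).**  Each edge's strength is the two-sided
slope-test p-value of a simple linear regression of child on parent,
fitted on control (non-tumor) training samples; edges are inserted in
ascending-p order with the same cycle guard.  Ties (the p-value of a
simple regression is symmetric in the two genes, so a 2-cycle always
ties exactly) are broken by stable input edge order.  A zero-variance
gene makes the test undefined; such edges get p = 1 with a warning.

**Biological rules + LASSO (`bnrich`).**  Stage 1 applies three ordered
rules, restricted to edges inside a nontrivial SCC: R1 removes edges
whose source compartment is strictly deeper than the target's
(anti-flux feedback such as nucleus→cytoplasm); R2 removes
expression/state-transition edges sourced at a nucleus node inside a
cycle (transcriptional feedback — SCC membership already certifies the
"feedback" character, so no extra upstream test is imposed); R3 removes
inhibition edges that still close a cycle after R1–R2 (negative
feedback).  Residual cycles either raise an error (default) or are
delegated to the evidence-ranking strategy (`fallback="clipper"`).
Stage 2 prunes edges of the now-acyclic graph whose LASSO coefficient is
exactly zero in **both** the tumor and non-tumor fit (one LASSO per
child and condition, all parents as predictors).  The penalty grid is
log-spaced over [1e-4·λmax, λmax]; 5-fold cross-validated mean squared
error anchors the selection, taken at the largest penalty within one
standard error of the CV minimum.  The 1-SE rule matters: the raw CV
minimizer keeps spurious ~0.03–0.1 coefficients on independent parents
in roughly half of replicates, whereas the 1-SE penalty shrinks them to
exact zeros while never (empirically, ≥ 95% over seeds) discarding
edges whose true coefficient magnitude exceeds 1 at n=500.

**Cyclegroup rebuild (`bpa`).**  Cyclegroups are realized as nontrivial
SCCs.  All intra-group edges are deleted (deterministically — the seed
affects only what follows), members are numbered by a random
permutation, and an edge is added for every ordered pair
(k(k−1)/2 per group, a complete acyclic tournament), plus an edge from
every external parent of any member to every member not already its
child.  The expansive reading (complete tournament, fan-out to all
members) is a deliberate design choice: the prose description admits a
narrower Hamiltonian-chain reading, but the removed-vs-added magnitudes
reported for this strategy at database scale (thousands added against
hundreds removed) are only consistent with the expansive one.

**Hierarchy voting (`ensemble`).**  Two node rankings are computed on
the whole self-loop-free graph: (a) a Gaussian skill rating — every
node a player with belief N(25, (25/3)²), every edge u→v a match won by
v, updated in one seed-shuffled pass by the standard two-player
truncated-normal rule with β = σ₀/2 and no draws; (b) the integer
ranking minimizing social agony Σ max(0, r(u) − r(v) + 1).  Agony
minimization is solved exactly as a linear program: its constraint
matrix is a totally unimodular difference system, so the LP vertex is
integral at any graph size (the exhaustive integer search survives in
the tests as the oracle).  Rankings are global rather than per-SCC
because a 2-cycle's SCC subgraph is perfectly symmetric — only context
outside the SCC (upstream/downstream attachments) can orient it.  Per
nontrivial SCC, each ranking is combined with three removal heuristics
over hierarchy-violating edges (r(source) ≥ r(target)): *forward* scans
by descending rank gap and removes edges still on a cycle; *backward*
removes the minimal largest-gap suffix of the ascending list;
*greedy* repeatedly removes the current largest-gap on-cycle edge.
An edge's vote (0–6) counts the methods that removed it; the final DAG
inserts edges in ascending vote (ties: input order), skipping
cycle-closers.  On a DAG the result is the identity with all votes 0.

## Parameter learning, scoring, BIC

Per-node ordinary least squares (intercept-only for roots) on control
training samples; the residual variance is the maximum-likelihood
estimate (SSR/n, not SSR/(n−p), matching the stated ML principle),
floored at 1e-8 so degenerate noiseless fits keep finite densities.
Fitting requires at least (max in-degree + 2) samples; rank-deficient
designs fall back to the pseudo-inverse with a warning.
BIC = k·ln(n) − 2·logL with k = Σ(|parents| + 2) per node; lower is
better.  Cross-strategy BIC comparison averages within-pathway ranks.

## Classification and enrichment

Features are per-sample pathway log-likelihoods.  Hyperparameters
(ntree ∈ {200, 500, 1000}, mtry ∈ {√p, p/3, p}) are chosen by
out-of-bag AUC on training rows (ties prefer the smaller forest).  The
headline evaluator `train_eval_rf_refit` redraws the paired 75/25 split
each of 10 repeats and **refits every pathway BN on that repeat's
control training samples** before computing features, so no test sample
ever touches parameter learning.  This matters quantitatively: at desk
scale a pathway BN has ~60 parameters against ~45 control training
samples, and in-sample likelihood inflation is large enough to push a
no-signal scenario to AUC ≈ 0.68 if BNs fitted on one split are scored
across re-splits; with per-repeat refitting the null sits at ≈ 0.5.
The fixed-table variant `train_eval_rf` (re-split and refit the forest
only) is kept for feature tables whose provenance already guarantees
independence.  Thresholds for accuracy-type metrics maximize the
Matthews correlation coefficient over midpoints of sorted unique test
scores; AUC is threshold-free.  Pathway importance is the forest's
impurity importance (normalized mean decrease in Gini — rank-equivalent
to the unnormalized convention), averaged over repeats; rankings use
dense ranks of descending importance, compared across strategies by
Spearman correlation.

## Synthetic data

The generator emulates the study design the pipeline expects, not
RNA-seq physics.  A random DAG (topological order fixed by seed,
~1.8 parents per node) gets compartments by topological depth
(membrane → cytoplasm → nucleus thirds) and activation/binding forward
edges; cycles are created by adding back-edges from a node to one of its
ancestors in a strictly shallower compartment, typed inhibition or
expression.  By construction the biology rules remove exactly the
back-edges, so rules-only reconstruction recovers the truth DAG — the
calibration that makes ground-truth-based tests possible.  Expression is
sampled ancestrally from the truth: coefficients uniform ±[0.5, 2.0],
noise sd 1, and intercepts chosen as β₀ = 6(1 − Σβᵢ) so every gene's
mean sits at ~6 on a log2-FPKM-like scale regardless of topology.  The
tumor condition adds a constant delta to selected coefficients.  Paired
samples are independent draws per condition sharing a pair id (adjacent
tissue as biological replicate, not identical tissue), pairs split
75/25 with both members on the same side, re-randomizable per repeat
from derived seeds.

Not emulated, hence out of the evidence a passing suite provides:
negative-binomial count noise, library-size/batch effects, nonlinear
regulation, shared patient effects within pairs, and gene overlap
between pathways (namespaces are disjoint).  Variance grows along deep
coefficient chains (|β| up to 2), which is accepted as-is; means stay
at the baseline.

## Determinism and numerics

Every random draw flows from one master seed through named SHA-256
derivations (`derive_seed(master, *labels)`, < 2³¹); identical
config + seed gives byte-identical pipeline outputs.  Stable input edge
order defines all tie-breaks (p-value ties, equal votes, equal grid
AUC).  Simple cycles are reported rotated to start at their
lexicographically smallest node.  σ² floor 1e-8; skill-rating variances
floored at a relative 1e-12 per update; LP solved by HiGHS.

## Problem sizes

The shipped experiments use: 200 random cyclic graphs of 5–40 nodes at
density 0.1–0.4 for the DAG-guarantee suite; 6-node DAGs at
n ∈ {100, 1000, 5000} × 20 seeds for OLS consistency; and a study of
12 pathways × 15 nodes, 60 sample pairs, one pathway perturbed by
delta 1.5 on 3 edges, 10 repeats (10 seeds for the signal rate, one
study per strategy for the five-way comparison).  These sizes were
chosen as the smallest at which the qualitative phenomena of interest
(perfect-vs-null separation, strategy disagreement, shuffle divergence)
are stable across seeds.

## Known limitations

The rules inventory R1–R3 is a reconstruction of prose-level biological
principles; rule ids are logged per removal precisely so alternative
inventories can be swapped in.  The skill-rating pass processes each
edge once (no convergence iteration), so very unbalanced match counts
can leave near-ties that the vote then settles by input order.  The
evidence-ranking strategy inherits the linearity assumption of its
regressions, and LASSO simplification shares it.  Classification
metrics at desk scale saturate near 1.0, so strategy comparison rests
on rankings, overlap and BIC rather than on AUC differences.
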