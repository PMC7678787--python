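# Methods

## Problem and model

The package infers functional associations between gene pairs of one
species from six categories of indirect evidence, and then uses the
resulting network for two downstream analyses: benchmarking by
neighbor-based function prediction, and gene set linkage analysis
(GSLA).  The classifier is a binary discriminator over unordered gene
pairs: positives are experimentally curated interactions, negatives
are random pairs, and the feature vector summarizes the evidence
layers.  Random pairs are overwhelmingly non-interacting, so the
negative pool is only weakly contaminated; the 100:1
negative-to-positive training ratio keeps that contamination
immaterial while still exposing the classifier to a realistic
background.

## Gold-standard curation

An interaction qualifies as a training positive when it has more than
one independent study (distinct publication identifier) and at least
one study was low-throughput.  The throughput flag is taken as given
per evidence row; no detection-method ontology is consulted.  The
filter is monotone: adding a qualifying study never removes a pair.

## Pair features

Eighteen features by default, in six categories.  All features are
symmetric in the pair, finite, and deterministic.

- **Shared annotation (3)** — Jaccard index of the is_a-propagated GO
  term sets per aspect (BP, MF, CC).  Propagation uses `is_a` edges
  only; `part_of` is out of scope of the minimal OBO reader.
- **Co-expression (2)** — Pearson correlation of the expression
  vectors, and the mutual-rank similarity `1/sqrt(r_ab * r_ba)` where
  `r_ab` is the rank of b among a's correlations against the whole
  universe (1 = best, ties averaged).
- **Co-localization (4)** — shared-compartment indicator, Jaccard of
  compartment sets, shared count, and a specificity score `max(-log
  f)` over shared compartments, `f` being the compartment's frequency
  among localized genes (sharing a rare compartment is stronger
  evidence than sharing the cytosol).
- **Domain interaction (5 per score source)** — over all cross domain
  pairs of the two genes: count of scored pairs, scored fraction,
  max, mean (over scored pairs) and sum of scores.  Repeating the
  aggregates per score source is the extension point toward larger
  domain-feature families.
- **Phylogenetic profile (3)** — phi correlation of the binary
  presence vectors, Jaccard of the presence sets, and the plug-in
  mutual information of the 2×2 presence table in nats.
- **Interolog (1)** — the number of reference species in which any
  orthologs of the two genes are reported to interact; a species
  counts once regardless of paralog fan-out.

**Missing-data rule.**  When a pair lacks the data a category needs —
either gene absent from the layer, a zero-variance expression vector,
a constant phylogenetic profile — every feature of that category is
set to exactly 0 and a per-category mask records the imputation.  The
rule is applied per category, the coarsest consistent reading: a
category is either computed from real data or fully imputed, never
half of each.  One refinement: for shared annotation, a gene
unannotated in a single aspect scores 0 in that aspect (an empty set
has Jaccard 0 against anything) and the category is masked only when
a gene carries no annotation in any aspect.

## Feature screening

Each feature is scored by the ROC AUC with which it alone separates
curated positives from sampled negatives (same sampler and default
1:100 ratio as classifier training).  The AUC is computed as the
Mann–Whitney statistic with the half-tie convention, via average
ranks; a constant column scores exactly 0.5.  Selection keeps
features with AUC strictly above 0.6.

## Classifier

Soft-margin Gaussian-kernel SVM (`K(x,y) = exp(-γ‖x−y‖²)`, σ =
1/√(2γ)).  Features are standardized to zero mean / unit scale with
statistics from the training data only; during cross-validation each
fold's scaler is fit on that fold's training part, so no information
leaks from validation folds (a property the tests assert by injecting
an outlier into a validation fold and checking the fold's training
statistics are unchanged).

Hyperparameters are tuned on a log-spaced grid, C over [2⁻⁵, 2¹⁵] and
γ over [2⁻¹⁵, 2³] (4×4 points by default), by stratified 5-fold
cross-validation with mean fold ROC AUC as the selection metric —
accuracy is useless at 100:1 imbalance.  **Near-tie handling:** grid
points within 5×10⁻³ of the best mean AUC are treated as equivalent,
because differences that small are fold noise at these sample sizes;
among them the model with the highest mean fold sensitivity at the
decision-value-0 operating point is preferred, then smaller C, then
larger σ.  Without this rule, on cleanly separable data the literal
argmax regularly lands on a heavily regularized model whose decision
value never crosses zero — perfect ranking, but a classifier that
predicts nothing, which is useless for building a network.  The final
model is refit on all training data at the chosen point.

A pair is called a functional association when its decision value
exceeds 0; no class weighting and no probability calibration.  With
100:1 training imbalance this operating point is naturally
conservative (very high specificity, modest sensitivity), which is
the regime a genome-scale sweep needs.  Genome-wide scoring streams
pairs in bounded batches; genes absent from every layer are legally
scored through the all-zero row.  Validation uses held-out positives
(the time-split stand-in) plus freshly sampled negatives at 1:100.

## Interactome size and reliability

With `n_p` predicted associations, sensitivity `se`, specificity
`sp`, and `n_all` total pairs, the expected number of true
interactions N solves `N·se + (n_all − N)·(1 − sp) = n_p`, i.e.
`N = (n_p − n_all(1 − sp)) / (se − (1 − sp))`.  The equation is
identifiable only when `se > 1 − sp`; a negative or super-universe
solution is rejected with a diagnostic.  When training and validation
sensitivities differ, the smaller is used (conservative convention).
Derived quantities: expected true predictions `N·se`, reliability
`N·se/n_p`, coverage `se`.  All arithmetic is done at full precision;
rounding happens only in display.

## Function-prediction benchmarking

For every target gene (one that gained annotations after the cutoff
date) with at least one network neighbor, the neighbor set is tested
for term over-representation with a one-sided hypergeometric test on
is_a-propagated annotations (background: all annotated genes).  This
in-package test stands in for the external enrichment service the
protocol historically used; it is the same statistic those services
compute.  Raw p-values are swept over cutoffs (no multiple-testing
correction, matching the cutoff-sweep protocol; a correction can be
applied by filtering the returned (term, p) lists).  Per cutoff,
micro-aggregated over genes:

- N — predicted terms; X — predicted terms equal to one of the
  gene's *direct* known annotations or a more specific descendant of
  one (matching against the propagated closure would trivially accept
  every term through the aspect root);
- Y — new annotations whose term, or a descendant of it, was
  predicted.

Precision = X/N; recall = Y over the fixed total count of new
annotations, never a per-cutoff denominator.  AUPR is the trapezoid
over the (recall, precision) sweep; cutoffs with N = 0 are dropped.
The default aspect is BP.  Interactome comparison runs the same sweep
per network and ranks by AUPR.

## GSLA

The inter-set density between gene sets A and B is the number of
ordered occurrences (a, b), a∈A, b∈B, a≠b, joined by a network edge,
over |A|·|B| − |A∩B|.  It is symmetric, lies in [0, 1], and genes
absent from the network count as degree-0 members (they dilute the
density but are not dropped).

- **Q1** passes when density > 0.01 (strict).  An optional
  Monte-Carlo diagnostic compares the observed density against random
  same-size gene-set pairs.
- **Q2** compares the observed density against densities on
  degree-preserving rewirings of the full network (double edge swaps,
  10·|E| swap attempts per rewiring, no self-loops or multi-edges;
  each gene keeps its neighbor count — the reading of "same genes and
  same neighbors but different interactions" that yields a
  non-degenerate null).  The empirical p uses the add-one estimator
  (1 + #{rewired ≥ observed})/(1 + n_perm), so p ≥ 1/(n_perm+1) and
  the default n_perm = 1999 makes the 0.001 cutoff reachable.
  Networks admitting no valid swap are returned unchanged with a
  warning and p = 1.

A process is reported when it passes both tests; reports are sorted
by (p, −density) and carry the connecting SCG–process edges plus a
parameter header.  `GSLA.fit` evaluates all library processes against
one shared pool of n_perm independent rewirings — permutations are
independent of each other, and sharing them across processes leaves
each process's marginal null unchanged while avoiding an
n_processes-fold rewiring cost.  The process library is built from
is_a-propagated BP annotations restricted to the network namespace,
with 5–500 genes per set after propagation.  SCG sizes outside the
recommended 50–200 window trigger a warning, not an error.

## Synthetic study conditions

The generator plants disjoint functional modules in a gene universe;
all within-module pairs are ground-truth interactions, 30% withheld
from training as a publication-date-split stand-in.  Per layer:

- expression: module genes mix a shared latent sample profile so that
  within-module Pearson correlation targets ρ (default 0.7);
  background genes are pure noise;
- annotations: a balanced is_a tree per aspect (branching 3, depth
  grown to cover the requested term count); each module owns one leaf
  term per aspect, annotated to its genes with probability 0.8, over
  a background of random leaf annotations (rate 0.6);
- localization: each module has a home compartment (probability 0.7)
  over 1–2 random background compartments per gene;
- domains: each module owns a scored domain pair (member probability
  0.7, score U(0.6, 1)) over random background domains and sparse
  background DDI scores;
- profiles: genes copy their module's presence/absence profile per
  species with probability 0.85, else draw fresh;
- interologs: orthologs exist with 80% coverage in 3 reference
  species; each planted pair's orthologs interact per species with
  probability 0.5, over a thin random background.

Defaults (200 genes, 6 modules of 4–6 genes, 10% per-layer
missingness) were chosen once so that every feature of a signal-carrying
layer is clearly informative (single-feature AUC above the 0.6
screening threshold) while background pairs stay near chance; setting
a layer's signal to zero makes planted and background pairs
statistically indistinguishable in that layer.  Sizes are deliberately
small — a few hundred genes, tens of positives — so full pipelines
(including 5-fold CV over the hyperparameter grid and 1999-permutation
GSLA) run in seconds to minutes; the acceptance script uses a 200-gene
universe for the classifier stages and a denser 150-gene, 4-module
fixture for the network benchmarking and GSLA stages.

What the fixtures do *not* emulate: scale-free degree distributions,
overlapping or hierarchical modules, correlated missingness between
layers, study-level biases in curated interactions, and realistic GO
DAG shape (the synthetic ontology is a balanced tree).  Passing tests
therefore demonstrate correctness of the machinery and the expected
qualitative operating regimes, not real-data performance levels: the
near-perfect AUCs on fixtures reflect planted signal strength, not a
claim about any organism's data.

## Numerical choices

- AUC via average ranks (exact Mann–Whitney with half ties).
- Hypergeometric p as the survival function at k−1 (P(X ≥ k)).
- Mutual information with 0·log 0 = 0, clipped at 0.
- Size equation in closed form; validated against root-finding to
  relative 1e−9 in tests.
- Empirical p-values always use the add-one estimator.
- All stochastic steps (generation, negative sampling, CV folds,
  rewiring) consume explicit integer seeds; igraph's rewiring RNG is
  seeded per call, so every result is reproducible bit-for-bit.

## Known limitations

- The domain category ships one score source (5 aggregates); larger
  families require additional score tables.
- `part_of` and regulates edges are ignored throughout.
- The enrichment stand-in reports raw hypergeometric p-values; tools
  it replaces may apply their own corrections, so absolute cutoff
  positions are not comparable across tools (curve shapes are).
- Q2 permutes the full network; permuting only the subgraph touching
  the two sets would be cheaper but tests a different null.
- ID mapping is file-based only; no live lookup services.
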