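# Methods

`autoannot` automates multi-label annotation of scientific articles with
controlled-vocabulary metadata. An article is represented by one of two
text variants (abstract-only or full text), reduced to one of two
feature spaces, and annotated by an independent binary classifier per
label. This note records the model, its assumptions, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Label model

Labels live in named *dimensions* (e.g. Behavioral Domain, Paradigm
Class, Diagnosis) and may be hierarchical. Hierarchy is encoded in
dot-delimited paths (`Cognition.Memory.Working`) or, for variants whose
names do not nest lexically (e.g. *Covert Word Generation* under *Word
Generation*), through explicit parent edges in the schema file.
Internally every label is dimension-qualified
(`BehavioralDomain:Cognition.Memory`) so identical names in different
dimensions cannot collide.

Per-contrast annotations are collapsed to one label set per article
(set union), then closed under the hierarchy: an article annotated
`Cognition.Memory.Working` also receives `Cognition.Memory` and
`Cognition`. Expansion happens **before** frequency filtering, so
parent labels benefit from their descendants' counts. Labels appearing
in fewer than `min_instances` articles (default **80**) are dropped;
rows are kept even when they become all-zero, because articles without
scorable labels still occupy test folds.

Descriptive statistics follow standard multi-label usage: label
cardinality LC_avg/LC_min/LC_max summarize row sums; P_uniq is the
fraction of articles with a unique label combination; P_min (P_max) is
the fraction of articles carrying exactly LC_min (LC_max) labels. All
proportions are reported as raw fractions in [0, 1]; scaling to percent
is left to presentation.

## Text preprocessing

The normalization pipeline is deterministic and its order is part of
the contract:

1. **Abbreviation expansion.** A parenthesized token of 2–10 characters
   containing at least one letter is accepted as an abbreviation when
   the i-th of its letters begins, case-insensitively, the i-th of the
   k words immediately preceding the parentheses (k = number of
   letters). The definition is removed and every later standalone
   occurrence is replaced by the full term. This is the simplest
   faithful initial-letter rule; definition spans that skip function
   words ("analysis of variance (ANOVA)") are not matched, a known
   limitation.
2. **Character filtering and spelling.** Lowercase; every character
   that is not alphanumeric, hyphen or whitespace is removed; whole
   words (hyphens bound words) found in the shipped British→American
   dictionary are replaced.
3. **Tokenization** on whitespace runs.
4. **Stop-word removal** against the standard English list shipped as
   package data, plus a minimum raw-token length of 3 letters.
   Stop-word removal precedes stemming deliberately: stems such as
   "veri" (from "very") no longer match a raw stop list, and a property
   test pins the order.
5. **Stemming** with the English Snowball (Porter2) algorithm,
   implemented in `autoannot._stem` and verified against hand-traced
   reference stems ("viewing/viewed/views" → "view", "memory" →
   "memori"). Stems need not be words.
6. **n-gram extraction**: contiguous unigrams, bigrams and trigrams of
   stems, joined with single spaces, counted with multiplicity. The
   3-letter minimum applies to unigram constituents, not to joined
   n-grams.

## Feature spaces

**Bag-of-words** features are the stemmed 1–3-grams harvested from the
*training* documents of each cross-validation fold; the vocabulary is
refitted per fold so test text never influences it.

**Ontology** features are occurrence counts of controlled-vocabulary
terms (concepts/tasks/disorders with curated aliases). Alternate
surface forms are generated by removing hyphens and possessive
apostrophes, fronting parenthetical statements ("memory (working)" →
"working memory"), and splitting slash-separated alternatives; all
forms pass through the same normalization pipeline as document text.
Matching over the stemmed token stream is greedy
longest-match-first and non-overlapping, so a bigram term is never
additionally counted as its unigram substring. Ties between equally
long forms resolve to the lexicographically smaller term id.

Counts are then propagated up the is-a hierarchy (Concept–Concept
assertions only): in reverse topological order each term's final count
is its own count plus the final counts of its is-a children, added
once per edge. Under this default a diamond double-counts at the apex;
an alternative `per_descendant` mode adds each raw count once per
ancestor. Cycles in the input ontology are broken by dropping the edge
that closes the cycle, scanning edges in input order, with a warning
and a report of the pruned edges.

## Vectorization and reduction

tf-idf uses sublinear term frequency and add-one-smoothed inverse
document frequency, both with natural logarithms:

    weight(t, d) = (1 + ln tf(t, d)) · idf(t),  tf > 0
    idf(t) = ln((1 + n) / (1 + df(t))) + 1

This standard smoothed form keeps idf strictly positive and equals 1
for a feature present in every training document. No row (L2)
normalization is applied — common tf-idf implementations default to it,
so this is stated explicitly. The implementation is cross-checked in
tests against both an explicit-loop oracle and scikit-learn's
`TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=True)`.

A feature must appear in at least `min_feature_instances` (default
**80**) training documents, mirroring the 80-article label floor. The
floor is interpreted as document frequency; a `count_mode="total"` flag
switches to summed raw counts.

For the bag-of-words space only, when more than `max_features`
(default **1,754**, the size of the ontology space, chosen so the two
spaces are comparable) candidates survive, features are ranked per
label by the chi-square statistic of dependence between feature values
and the binary label, and the top `max_features` retained. Ties,
including all-zero features whose statistic is 0, break on ascending
feature name for determinism. Selection is per label, so the selected
sets differ across labels — this is what the similarity analysis later
exploits.

## Classifiers and tuning

Four families, each with the grid actually searched:

| family | grid |
|---|---|
| Bernoulli naive Bayes | smoothing α ∈ {0.01, 0.1, 1, 10} |
| SVC (RBF kernel) | C ∈ {1, 10, 100} × γ ∈ {0.01, 0.1, 1} |
| logistic regression (liblinear) | C ∈ {0.01, 0.1, 1, 10, 100} × {L1, L2} |
| k-nearest neighbors | k ∈ {1, 3, 5, 7, 9} × {Manhattan, Euclidean} × {uniform, inverse-distance} |

Naive Bayes binarizes features at zero (presence/absence), so it is
invariant to tf magnitude. Logistic-regression C is the *inverse*
regularization constant of the liblinear coordinate-descent solver
(larger = weaker penalty); the L1/L2 choice is expressed through
`l1_ratio`. Probabilistic families threshold the positive-class
probability at 0.5; the SVC decides by margin sign. kNN with
inverse-distance weighting gives exact matches (zero distance)
dominating weight; brute-force neighbor search keeps results equal to
the exhaustive oracle.

Tuning is an exhaustive grid search inside the training fold under
3-fold stratified CV, scored by F1 of the positive class, ties going to
the first point in canonical (row-major) grid order. When the training
fold has fewer positives than inner folds, scoring falls back to the
training data itself rather than failing the cell.

## Cross-validation engine

The default plan is 100 iterations of stratified 5-fold CV. With 2
corpus variants × 2 feature spaces × 4 classifiers = 16 cells, each
label is fitted and predicted 100 × 5 × 16 = 8,000 times, yielding 500
performance estimates per label per cell.

Stratification is *iterative multi-label stratification*: labels are
processed from rarest to most frequent and each document goes to the
fold with the greatest remaining demand for that label, under a hard
fold-size cap (sizes differ by at most one). Single-label-at-a-time
stratification would conflict across labels. Folds are shared across
cells within an iteration so cell comparisons are paired.

Randomness is governed by one master seed; per-(iteration, fold, label)
seeds are derived through `numpy.random.SeedSequence` spawn keys, so
any cell is independently reproducible. Two runs with the same seed
produce byte-identical prediction CSVs (asserted in tests). Folds whose
training side lacks a positive example for a label are skipped and
logged; skipped runs are excluded from score averaging.

## Evaluation

Precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic mean,
with the convention F1 = 0 (flagged) when precision + recall = 0.
Macro F1 is computed per label per iteration with the iteration's five
folds pooled (each document scored exactly once per iteration); a
per-fold mode exists behind a flag. Dimension-level macro is the
unweighted mean over the dimension's labels. Micro F1 pools confusion
counts over the dimension's labels before computing F1, then averages
over iterations.

The baseline pseudo-prediction assigns every article the dimension's m
most frequent labels, where m is the rounded (half away from zero, to
avoid banker's-rounding surprises) average label cardinality of the
dimension. It is invariant to document and label order.

Hierarchical precision/recall use ancestor augmentation: both the
predicted and the true label set of a document are closed under the
hierarchy, then hP = |aug(pred) ∩ aug(true)|/|aug(pred)| and hR =
|aug(pred) ∩ aug(true)|/|aug(true)|, averaged over documents and then
iterations. For a flat hierarchy this reduces to ordinary set
precision/recall. The augmentation formulation is an interpretation:
the intent — credit for predicting the parent when a child is
annotated — admits several formalizations, and this is the standard
one.

## Label similarity analysis

For each label, the selection-frequency distribution assigns every
feature the fraction of (iteration, fold) runs in which chi-square
selection retained it. Distributions are aligned on the union of
ever-selected features, with 0 for non-selection (whether to use the
union or the intersection was open; union-with-zeros is the recorded
choice). Pairwise Spearman rank correlation (average ranks on ties) is
computed between labels; label co-occurrence, measured by the Dice
index over document sets, is regressed out by OLS with intercept on
the upper-triangle pairs, and the residuals refilled symmetrically
(zero-variance Dice degenerates to centering). Residual similarity is
clustered by WPGMA ("weighted") linkage on distance 1 − similarity,
with labels pre-sorted by name so equal-distance merges are
deterministic; weighted linkage can produce height inversions, and
heights are recorded as computed. The cluster count for a flat cut is
a user parameter — no automatic threshold is imposed. Word-cloud
exports list, per cluster, the top 10 % of features by mean selection
frequency across the cluster's labels (ceiling rule, name tie-break),
as term–weight TSV rather than rendered images.

## Synthetic corpus generator

The generator emulates a manually annotated article collection at a
desk scale: 400 documents, two dimensions, seven labels with one
three-level chain, abstracts of ~150 tokens and full texts of ~1,500
tokens (Poisson lengths). Each label owns a disjoint pool of invented
signal words; a document's token slots draw from its (expanded)
labels' pools with probability θ (default 0.5) and otherwise from a
Zipf-distributed background vocabulary of 2,000 words, which gives the
document-frequency thresholds non-trivial work. Label assignments
follow configured prevalences (0.15–0.35) with a sibling co-occurrence
boost (default 0.3) inside a dimension, so the Dice residualization
has real co-occurrence signal to remove. Full text extends the
abstract with more tokens from the same process, making the full-text
vs abstract comparison meaningful. Parenthetical abbreviation
definitions and British spellings are injected at low rates to
exercise normalization. A toy ontology places every signal word under
a per-label head concept, with head-to-head is-a edges mirroring the
label hierarchy, so is-a propagation aggregates exactly the planted
structure.

What the generator does *not* emulate: scientific prose and syntax,
section structure, citation/reference text (extra token mass only),
realistic vocabulary sizes (tens of thousands of types), label sets in
the hundreds, and annotation noise. Passing recovery tests therefore
demonstrate that the machinery is correct and sensitive to planted
signal, not that any particular F1 level would be attained on real
articles.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced designs chosen as
realistic desk-scale experiments: recovery uses 400 documents with 10
iterations × 5 folds of the single best-performing cell pair
(full-text and abstract, bag-of-words, logistic regression); oracle
equivalence uses 1,000 randomized instances of size ≤ 20×50 per
operation at tolerance 1e-10. Degenerate inputs are defined rather
than left to chance: empty matrices error, zero-denominator F1 is 0
with a flag, constant Spearman inputs get rho 0, zero-variance Dice
regressors center, single-label trees are single-leaf dendrograms.

## Known limitations

- The abbreviation matcher requires strict initial-letter alignment
  and handles neither skipped function words nor nested parentheses.
- The per-edge is-a propagation double-counts diamond apexes by
  design; the once-per-descendant mode is available but not default.
- Hierarchical P/R is one formalization among several.
- The stemmer implements the published Snowball English algorithm;
  behavior on tokens containing digits or hyphens (which the algorithm
  treats as consonants) is deterministic but not specified by the
  algorithm's authors.
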