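# Methods

## Data model

A `SymptomDataset` holds a patients × symptoms matrix with one binary
syndrome label per patient (1 = syndrome present; the positive class is the
majority in the reference cohort). Raw data are strictly binary; fractional
values in [0, 1] appear only downstream of sample mergence. The reader
rejects non-binary cells, duplicate symptom names and missing label
columns; delimiters follow the file extension (`.csv` comma, otherwise
tab). The first column of a table is the sample identifier.

Four published reference tables are packaged verbatim as TSV resources:
class counts (120/46/166, 102 symptoms), the sorted 62-symptom information
gain table, the core-symptom → phenotype-term map (24 symptoms, 43 distinct
terms, five pulse/fur symptoms unmapped), and the 24-rule pathway pattern
(13/6/4/1 itemsets by size, minimum supporting count 9). They are replay
fixtures, not inputs to any computation on user data. The gain table
contains the symptom name "Pale tongue" twice, exactly as published; the
fixture loader preserves it (the dataset reader would reject such a
duplicate in an actual symptom table).

## Level 1: diagnostic model

**Information gain.** IG(C|X) = H(C) − H(C|X) in bits (base-2 logs), with
plug-in empirical probabilities and 0·log 0 = 0. No smoothing: the
estimator is intentionally the raw-frequency one. Negative floating-point
residue is clamped to 0.

**Severely imbalanced symptom filter.** A symptom whose minority value
count is below `min_minority = 5` is removed before ranking. Such symptoms
can reach high gains from a handful of patients — e.g. three minority
instances that happen to align with the label — and in an extreme split all
of them could land in the test set; they carry no generalisable signal.

**Core-symptom selection.** Symptoms with gain *strictly above* a threshold
are selected; the strict inequality reproduces the published count of 24 on
the packaged gain table at threshold 0.004. Gains are computed once on the
full dataset (as the reference analysis computed its table) and reused
across the repeated splits of the threshold sweep; the sweep picks the
accuracy-maximising threshold, ties broken toward fewer symptoms. Ranking
ties break lexicographically by symptom name for determinism.

**Pairwise undersampling.** Over the majority-class training samples,
restricted to the core symptoms, all n(n−1)/2 pairs are ranked ascending by
distance; equal distances are permuted by a seeded RNG. A single greedy
pass admits a pair iff its distance is within the threshold and neither
member was already merged (each sample merges at most once, bounding
information loss). Admitted pairs are replaced by their coordinate-wise
mean; the output size is exactly n − (number of merged pairs). The pass
uses one static ranking — pairs are not re-ranked after a mergence — and
merged (fractional) samples are never re-merged.

*Distance metric.* The default is the squared Euclidean distance, which on
binary vectors equals the number of differing coordinates. The published
account used integer thresholds of 8 and 10 over 24 binary core symptoms,
values unreachable by the plain Euclidean distance (bounded by √24 ≈ 4.9);
the squared form is the reading under which those thresholds are
meaningful. Plain `euclidean` is selectable by flag, and every run report
records the metric in use. Threshold comparison is inclusive (≤): with
integer-valued squared distances a strict < would make an integer
threshold behave as threshold − 1; a strict variant is available.

**Classifier and evaluation.** The diagnostic model is a soft-margin RBF
SVM (scikit-learn `SVC`), cost 1 and kernel width 1/n_features by default —
the common library convention, since only the kernel family is fixed by the
method — both exposed in configuration and recorded. Fractional merged
features are fed as-is; they are the defined output of mergence, not noise
to re-binarize. Evaluation repeatedly (default 100×) draws a balanced test
set of 10 positives + 10 negatives, trains on the remaining imbalanced
patients (undersampling, when enabled, touches only the training majority
class; the test set is never resampled), and reports sensitivity,
specificity, accuracy and G-mean = √(sen·spe) per repeat and in aggregate.
Accuracy drives threshold selection in both sweeps; G-mean is reported
alongside as the balanced metric. A test rate with a zero denominator is
reported as NaN with a warning (never silently 0), except the G-mean,
which is 0 when either rate is 0 or undefined. Per-repeat seeds are
spawned deterministically from one master seed; both the split and the
undersampling tie-ranking are refreshed each repeat.

## Level 2: molecular mechanism

**Phenotype mapping.** The original term assignment was a manual synonym
search; here it is reproducible: a YAML file maps each symptom to keyword
strings, matched case-insensitively as substrings against ontology term
names and synonyms (OBO parsing via obonet; obsolete terms excluded).
Matches de-duplicate and sort by term id. Symptoms with no match (pulse and
fur observations typically) are carried as unmapped with a warning — a
known annotation-coverage limitation, not an error. Only directly matched
terms are used; no ancestor/descendant propagation or semantic similarity.

**Relevant genes.** Gene occurrence = number of *distinct* mapped terms
(duplicates across symptoms collapsed first) whose association set contains
the gene. Genes with occurrence < 3 are treated as occasional and dropped.
Genes are keyed by the association file's gene id, with the symbol kept as
a display label. Ordering is (−occurrence, gene id) throughout.

**Pathway Pattern.** Each relevant gene with pathway annotation contributes
one record (its pathway set); unannotated genes are excluded and counted.
Frequent itemsets are mined level-wise (apriori with downward-closure
pruning, authored in-package) at the support floor
ceil(min_support · n_records), default support 0.055. "Bidirectional"
rules: a size ≥ 2 itemset is retained iff some bipartition (A, B) has
confidence(A→B) = count(A∪B)/count(A) ≥ 0.800 in both directions; a strict
variant requires every bipartition to pass. Size-1 itemsets are
support-only entries — confidence is undefined for them, and the published
pattern lists single pathways as rules. Output order is (size, −count,
lexicographic items); symbols 1a, 1b, … 2a, … follow that order.

**Multilayer network.** Tripartite: symptom, gene and *itemset* nodes (the
third layer is the pattern's association rules, labelled by symbol, not
individual pathways). Gene–itemset edge iff the gene's record ⊇ itemset;
symptom–gene edge iff the gene is associated with any of the symptom's
mapped terms. Pruning removes gene nodes lacking a symptom edge or an
itemset edge together with their edges, then isolated symptom/itemset
nodes, iterating to a fixed point — the conservative closure of the two
removal rules, since symptom isolation can cascade. The ambiguous removal
clause "an edge terminating at the gene node" is read as: edges incident to
a disqualified gene go with it. Exports: GraphML (lossless attributes) and
SIF with relations `associates`/`covers` plus a node-attribute TSV sidecar.

**Over-representation.** Upper-tail hypergeometric P(X ≥ k) for a pathway
with K members, list size n, universe N (scipy's survival function; exact).
Ranking by −log₁₀ P, ties by pathway id; no multiple-testing correction by
default since the ranking statistic is the raw −log P (Benjamini–Hochberg
q-values by flag). The universe defaults to all genes in the gene→pathway
mapping and is overridable. This is a generic ORA, deliberately not an
emulation of any proprietary platform scoring; platform network scores
(Z/G-scores) are out of scope.

## Synthetic data

The generator emulates the reference cohort's shape: 120/46 patients
(≈2.61 : 1), 102 binary symptoms of which 24 are informative —
Bernoulli(0.8) in positives vs Bernoulli(0.2) in negatives by default, so
planted gains dominate sampling noise at n = 166 — and the rest
class-independent Bernoulli(0.5) noise; optional "severely imbalanced"
columns (minority < 5) exercise the minority filter. Symptoms are
class-conditionally independent: real symptom co-occurrence structure is
*not* modelled, so passing tests demonstrate pipeline correctness and
direction of effects, not clinical performance. For the weak-signal
experiments (undersampling benefit, non-saturated classifiers) the rates
0.65/0.35 are used: a plausible weak-but-present effect at this sample
size, chosen once.

The annotation generator builds a flat synthetic ontology, term→gene and
gene→pathway tables sized like the reference molecular layer (43 terms, 159
annotated genes, 30 pathways) with a planted cluster of 11 genes sharing
one 4-pathway itemset, so mining at support 0.055 must recover that itemset
with count 11 by construction. Planted genes are boosted into three terms
so they always clear the occurrence filter.

## Numerical and design notes

- All randomness flows from explicit seeds (`numpy.random.default_rng` /
  `SeedSequence`); identical configurations reproduce byte-identical run
  reports (no timestamps are stored in them).
- Duplicating every training sample is *not* decision-invariant for a
  soft-margin SVM at fixed cost (it doubles the hinge-loss weight); the
  invariance holds, and is tested, with the cost halved.
- `min_support_count` computes ceil(s·n) with a 1e-9 guard against
  floating-point round-up on exact multiples.
- The evaluation protocol at the default shape trains on 110 + 36; with
  undersampling at generous thresholds the majority shrinks to ~55–58,
  roughly balancing the classes — the mechanism by which specificity
  improves.
- Problem sizes in the test suite and acceptance script (100 replicates for
  rank recovery, 100 repeated splits for the undersampling comparison,
  reduced repeats in end-to-end runs) were chosen as the smallest studies
  that make the directional claims statistically stable.

## Known limitations

- Binary symptoms only; how multi-valued clinical observations are
  binarized upstream is out of scope, as is missing-data handling.
- Keyword substring matching cannot capture semantic similarity; term
  coverage gaps (pulse/fur symptoms) propagate as unmapped symptoms.
- The published clinical accuracies and G-means are not reproducible
  without the undeposited patient data and are not targets of this
  package's tests.
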