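# Methods

## Fingerprint model

A peptide's monomer composition is an ordered list of opaque, case-sensitive
monomer codes. The fingerprint is the occurrence-count vector of that list
over a fixed monomer alphabet; it is permutation-invariant by construction
and carries no bond or neighborhood information. Two consequences shape the
API:

- fingerprints are only comparable when built against the same alphabet, and
  every similarity operation enforces this;
- the alphabet's element *order* is immaterial to every statistic computed
  here (similarity, diversity, classification), so when an alphabet is
  derived from a dataset we fix it lexicographically purely for
  reproducibility, and when one is supplied explicitly we keep its order.

Real registries run to ~526 monomer codes while peptides contain ~3–18
monomers, so fingerprints are stored sparsely (position → count) with dense
export on demand. Unknown composition codes raise by default
(`unknown_policy="error"`); `"extend"` appends them to a copy of the
alphabet for incrementally growing databases, `"ignore"` drops them (used
when scoring held-out peptides against a fixed training alphabet, at the
cost of the count-conservation invariant).

## Similarity

The continuous Tanimoto coefficient on count vectors,
`S = Σab / (Σa² + Σb² − Σab)`, is computed directly on the sparse maps
(scalar path) or vectorized via one matrix product (pairwise path); both
paths are tested against a loop-based oracle at 1e-12 absolute tolerance —
raw integer counts make the formula exactly representable, square-root
weighting does not. The sqrt variant replaces each count by its square
root, after which the squared sums reduce to plain count sums. Raw
weighting is the default; the sqrt scheme is exposed behind a flag because
occurrence-damping is known to help screening recall in some collections
but is not uniformly better.

Degenerate input: two all-zero vectors make the score 0/0. Empty
compositions are rejected upstream, so this can only arise from manual
construction; the score is defined as 0 with a `RuntimeWarning`.

Ranked search sorts by descending score with ties broken by ascending
peptide id — any deterministic rule would do; this one is stable across
platforms and database orderings. The query is excluded from its own
ranking by default, since the trivial self-hit inflates recall. The top-k%
cutoff is `ceil(k · n)` so a nonempty list always yields a nonempty top
slice (top-1% of 605 peptides keeps 7). Batch recall draws a seeded random
sample of query peptides per class (default 20, the full class with a
warning if smaller) and averages the per-query recall of the remaining
class members.

## Curation

The three rules run in a fixed order — class-size threshold (default 20),
distinct-monomer-set dedup within each class, single-activity restriction —
because the outcome depends on that order: class sizes are counted before
dedup shrinks them. Dedup compares *sets* of distinct monomers, not count
vectors, so `[A,A,B]` and `[A,B]` collapse; the representative is the
lexicographically smallest id (any fixed choice preserves class counts).
The surfactant label is excluded from activity classes by default, being a
physico-chemical property rather than a biological activity; a flag
retains it. Peptides with ≥ 2 remaining labels form the evaluation set —
the exact complement of the single-activity stage, so the two partition the
deduplicated records.

Monomer overlap between classes is row-normalized: `common[i][j]` is the
share of class *i*'s monomer union also present in class *j*, hence
generally asymmetric; `specific[i]` is the share found in no other class
and occupies the diagonal of the exported table.

## Prediction

Per-class metrics and the confusion matrix come from one protocol: each
fold's model produces per-class scores, the multiclass prediction is the
argmax (ties broken by label order), pooled out-of-fold predictions give
the confusion matrix and overall accuracy (trace over total), and their
one-vs-rest binarization gives per-class precision, recall and F. AUC uses
the pooled out-of-fold scores per class, computed as the tie-aware
Mann–Whitney statistic (midranks; ties count ½) — equivalent to exhaustive
positive–negative pair counting, which the tests verify by enumeration.

Classifier choices: the naive Bayes event model is multinomial with
Laplace (+1) smoothing — the natural likelihood for occurrence counts; a
Gaussian-per-feature variant is available via
`hyperparams={"event_model": "gaussian"}` for comparison with numeric-
attribute toolkits. The linear model is L2-regularized logistic regression
(liblinear solver, C = 1.0, the conventional default) wrapped in an
explicit one-vs-rest scheme. The classifier interface is pluggable by
design; kernel SVMs are deliberately out of scope since the linear model
covers the linear-kernel case. Folds are stratified and seeded; classes
smaller than the fold count trigger a warning but are still evaluated.

On a multi-label evaluation set, a single predicted activity is counted
correct when it belongs to the record's known activity set — peptides that
genuinely carry two activities should not penalize a model for naming
either one.

## Synthetic data

The generator emulates the structure of a curated NRP collection: five
activity classes with sizes 319/157/82/25/22 (a `scale` factor shrinks
them proportionally, floor 2, for fast tests), lengths uniform per class
within ~3–18, and per-monomer draws from a mixture of a shared pool (20
proteogenic-style codes), a class pool (partially shared between
biologically related classes — antibiotic and toxin pools overlap), and a
class-specific pool (disjoint across classes, enforced). With enrichment
`e`, the shared pool is drawn with probability `1/(1+e)` and the specific
pool with `(e/(1+e))²`: `e = 0` removes all class signal (a null dataset),
`e = ∞` makes class supports disjoint. The default `e = 4` represents
strong but not degenerate class structure (80% of draws leave the shared
pool). A quarter of the peptides in the antibiotic/toxin/antitumor classes
receive a second label from a crossing table defaulting to the pairings
those activities actually exhibit; iron chelation (siderophores) and
protease inhibition do not cross. All draws flow from a single
`numpy.random.default_rng(seed)`, so identical seeds give byte-identical
tables.

What the generator does **not** emulate: the real ~526-monomer frequency
distribution, within-class substructure (peptaibols vs glycopeptides),
correlations between composition length and class beyond the length
ranges, and any bond structure. Passing pipeline tests on this data shows
the machinery is correct and that class-conditional monomer usage is
recoverable; it does not certify recall or accuracy figures on any real
collection.

Five published peptides (coelichelin, hypomurocin A1, orfamide A,
pyoverdin PSEN, TVB I) ship as a small fixture with their printed
compositions and literature activities; they carry synthetic ids
(`TAB5-01`…) because they predate any database accession.

## Numerical and testing choices

Scores are compared at 1e-12 absolute tolerance in tests. Cross-validation
tests run at scale 0.15–0.2 (~90–120 peptides) with 5–10 folds; the
null-AUC check averages 20 seeds and accepts 0.5 ± 0.1, a Monte-Carlo band
wide enough for classes of 3–5 members. At desk scale the class-size
threshold is scaled with the dataset (4 at scale 0.2, matching 20 at full
scale) so all five classes survive curation.

## Known limitations

- Fingerprints cannot distinguish isomeric peptides with equal monomer
  counts; that is a property of the representation, not a bug.
- `unknown_policy="ignore"` silently shortens the effective composition;
  it is restricted to held-out prediction.
- The multiclass accuracy is the plain trace of the confusion matrix;
  per-class one-vs-rest "accuracies" are not reported separately.
- No probability calibration, hyperparameter search, or kernel methods.
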