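# Methods

## Problem and model

Literature triage for biocuration is cast as one binary classification
problem per experimental data type (one-versus-rest): a paper is a positive
example for a data type if curators annotated that type in it, whether or not
other types are also present. The negative set for a data type combines
papers labeled as containing no curatable data with papers positive only for
other data types — an approximation to the ideal "all papers minus this
type's positives" that matches how curated collections are actually labeled.

Documents are bags of case-folded alphanumeric tokens. Tokenization keeps
maximal runs of `[a-z0-9]`, drops single characters, and applies no stemming
or stop-word removal: author surnames, gene names, years and method acronyms
are exactly the features the ranking is expected to surface, and stemming or
stop lists would erase some of them. Reference lists and supplementary text
are retained when present in the input file, since evidence is sometimes
mentioned only there. The tokenizer is one consistent choice among several
defensible ones; its effect on downstream behaviour is limited because
feature selection operates on presence counts.

## Feature scoring

For every token a 2×2 contingency table against the class is tallied over
the training set (document presence only). The chi-square statistic is
computed without continuity correction, in exact integer arithmetic with a
single final division, which makes the score exactly invariant under
swapping the class labels and bit-reproducible across platforms. Tables with
a zero marginal score 0 instead of raising, so vocabulary edge cases never
abort a run. Ties in the ranking are broken by larger positive-class
presence (N11), then lexicographic token order, making the ranking total and
reproducible. Mutual information (bits) is computed for inspection only;
chi-square separates informative from background tokens much more sharply
and is the sole ranking criterion.

The ensemble consumes nested prefixes of one ranking: top 10, 25, 50, 75,
100, 150, 200, 300, 400 by default. When the vocabulary is smaller than a
requested size the truncated list is used and the affected components become
duplicates; they still contribute votes, which changes the effective
confidence banding and is reported as such.

## Vectors

Production vectors are Boolean presence indicators over the ranked list.
TF-IDF variants exist for the comparison experiments: raw term frequency ×
natural-log IDF, min-max scaled per feature to [0, 1] on the training set
(the analogue of libsvm's data-scaling utility; Boolean vectors are already
in [0, 1] and skip scaling). All statistics — document frequencies, scaling
ranges — come from training documents only; test tokens unseen in training
are ignored. The exact TF-IDF variant (raw vs log TF, normalization) is an
open choice; conclusions drawn from the comparison are qualitative
directions, not exact values.

## Ensemble training

Components are RBF-kernel SVMs (scikit-learn's libsvm binding). Per
component, (C, γ) are selected by maximizing mean accuracy over seeded,
class-stratified 5-fold cross-validation (folds clamp to the minority-class
count on tiny sets, falling back to training accuracy below two folds), with
first-best tie-breaking in grid scan order; the component is then refit on
the full training set. The default grid is the log2 lattice C ∈ 2^(−5..15),
γ ∈ 2^(−15..3) (step 2²) from the libsvm practical guide. The replicated
experiments and the acceptance script use a fixed 3×3 sub-lattice
(C ∈ {2⁻¹, 2³, 2⁷}, γ ∈ {2⁻⁷, 2⁻³, 2¹}) so that the ~130 ensemble trainings
they perform stay cheap; on the synthetic corpora the coarse grid selects
models indistinguishable in recall from the full grid's.

Components whose inputs are identical (truncation duplicates) share one
deterministic fit — equivalent to retraining on identical data. Under
`tfidf_all` there is no feature selection, so all nine members would be
identical and a single component is trained; union recall and precision are
unaffected, and the vote count degenerates to 0 or the component count.

Prediction is the union rule: positive iff ≥ 1 component votes positive.
Vote counts are banded none/low/medium/high (0, 1–3, 4–6, 7–9 for nine
components; thirds of the range generally). A confidence cutoff is a
post-filter, off by default: it reclassifies positives below the cutoff band
as negative, never touching the reported count or band. Recall is therefore
non-increasing and the positive set non-growing in the cutoff by
construction; the precision gain is empirical.

## Evaluation

Undefined metrics (zero denominators) propagate as NaN with a warning and
are excluded from aggregates with a logged count. Batch evaluation reports
unweighted means and sample (n−1) SDs across batches, mirroring periodic
validation of incoming-paper batches of varying size. An optional
subsampled-recall estimator extrapolates the false-negative rate from a
random audit of predicted negatives; its variance is not characterized and
it is not used by any default path.

The PN-ratio sweep draws, per replicate, one positive train/test split and
one held-out negative test set; every ratio reuses the same positive
training set while taking a nested random subsample of training negatives
(sampling without replacement), so ratios differ only in negative-set size.
The selected ratio maximizes mean recall among ratios whose mean FT is at or
below a ceiling (default 25%, bracketing the FT range typical of production
use); if none qualify, all ratios compete, with a warning.

## Synthetic study conditions

The generator emulates the statistical skeleton of curated full-text
collections: a Zipf-weighted background vocabulary (exponent 1.1) over
Poisson-length documents, planted discriminative tokens present in a
positive document with probability `p_feat_in_pos` and in a negative with
`p_feat_in_neg`, optional corpus-specific tokens (the analogue of an
organism literature's pet citations), a share of negatives labeled with a
different data type (exercising the negative-set rule), and evaluation
streams with configurable positive occurrence down to 1%. Documents are
emitted as actual text and re-tokenized, so the pipeline is exercised end to
end, including the on-disk corpus layout.

What the generator does *not* emulate: English syntax, section structure,
topical correlation between background tokens, vocabulary drift over time,
and multi-token phrases. Passing tests therefore demonstrate that the
pipeline recovers planted structure under realistic dimensionality and
noise, not that any particular recall level will be attained on a real
curated corpus.

Frozen study presets (chosen as plausible desk-scale analogues of the
production regimes, then left alone):

- **Separable ensemble corpus** — 80 positives / 160 negatives, vocabulary
  800, 15 planted features at 0.8 vs 0.02. Used for union-dominance and
  confidence-monotonicity runs (20 seeds, odd/even chronological split).
- **Low-occurrence sweep corpus** — 60 positives / 600 negatives, vocabulary
  1200, 8 features at 0.5 vs 0.12, 5% stream occurrence. The deliberate
  class overlap makes training-set composition matter: recall falls and FT
  improves as the negative share grows, reproducing the ratio trade-off.
- **Cross-corpus pair** — two corpora of 80/240, 8 shared features (0.5) plus
  6 corpus-specific features (0.75) each. Training on one corpus alone leans
  on its specific features and generalizes poorly to the other; pooling
  demotes specific features in the chi-square ranking (~9 rank positions on
  average) and restores recall.
- **Weighting corpus** — balanced 100/100 training set, vocabulary 6000, 10
  weak features at 0.45 vs 0.05, evaluation sets at 1:1 and 2:1
  negative:positive. The weak-signal/large-vocabulary regime is where
  selection matters: chi-square-selected schemes hold recall ≥ 0.9 while
  no-selection TF-IDF trails them. An early, more separable draft of this
  preset let every scheme reach recall 1.0 and was replaced for that reason.

Experiment problem sizes (20 seeds for replicated comparisons, 10 replicate
splits per sweep ratio, the coarse hyperparameter grid) were chosen so the
full replicated battery runs in minutes on one CPU as the package's standard
verification scale.

## Numerical and design choices

- Seeding: every stochastic step derives from `numpy.random.SeedSequence`
  over (user seed, replicate index), so replicate lists are bit-identical
  across runs and machines; iteration orders are sorted wherever they could
  otherwise depend on hash randomization, making pipeline outputs
  byte-reproducible across processes.
- Chronological odd/even splitting uses 1-based ranks after sorting by
  (order_key, doc_id); odd ranks train. Applied to each class independently.
- Negative subsampling is always without replacement; infeasible sweep
  ratios are skipped with a warning rather than failing the sweep.
- Model archives are joblib files with a format tag and version; loading
  validates both and round-trips predictions exactly.
- Serialization, corpus files and reports are plain text (TSV/JSON) except
  the model archive.

## Known limitations

- Single tokens only: no n-grams, positional or section features, and no
  synonym/concept expansion, so vocabulary drift between training era and
  incoming papers degrades precision for drift-prone data types.
- The negative-set rule inherits the labeled collection's blind spots: truly
  unlabeled negatives outside the curated pool are invisible to training.
- CV selects on accuracy, which under strong imbalance can favor
  majority-class components — part of why the PN ratio needs tuning rather
  than a flaw the sweep hides.
- The subsampled-recall estimator is high-variance at small audit sizes and
  should be treated as a screening number.
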