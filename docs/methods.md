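# Methods

## Problem and model

The package predicts self-identified ethnicity (ten categories: Ab, Ch,
En, Fr, Ir, It, Jp, Ru, Sc, Others, plus First Nations / Métis / Inuit
subgroups under Ab) from two widely collected text fields: the personal
name and the census location string. The classifiers are standard linear
models over sparse token-count features; the scientific content is in the
feature engineering, the benchmark-anchored selection protocol, and the
evaluation conventions, all of which this note documents.

The approach assumes that (i) naming practices are ethnoculturally
distinctive enough that character-level name features carry signal, and
(ii) residential geography is ethnically clustered enough that census
district/subdistrict labels add signal beyond names. Both assumptions are
encoded as explicit knobs of the synthetic generator (below), so the
pipeline's sensitivity to them is testable.

## Cleaning and labels

Names are lowercased; personal titles (editable lexicon in
`data/titles.txt`), tokens containing digits, single-letter tokens and
punctuation are stripped. Apostrophes and hyphens are removed fusing the
token ("o'neil" → "oneil") by default — punctuation stripping admits no
exception — with a flag to preserve them for sensitivity analyses.
Diacritics and non-ASCII letters are kept as-is after lowercasing. The
cleaned name splits positionally: first token → first name, last token →
last name, interior → middle name. A single-token name goes to the
last-name slot, since surnames carry the dominant ethnicity signal and the
positional rule is undefined at one entity.

Free-text ethnicity responses are normalized (lowercase, trimmed, NFC) and
looked up in an editable alias map (`data/ethnicity_aliases.csv`); unmapped
non-empty responses fall back to Others and are counted. A record is
incomplete when the cleaned name, the location, or (in training mode) the
ethnicity is missing; duplicates are exact matches on the cleaned
(name, location, sex, ethnicity) tuple, keeping the first occurrence. The
audit reports initial/incomplete/duplicate/kept counts and the retention
percentage at one decimal.

Location strings are split on commas; a trailing country token (default
stopword set {"canada"}) is dropped; the remainder is lowercased and
assigned right-to-left as province, district, subdistrict, surplus leading
components joining the subdistrict. Apostrophes are preserved here
(unlike names, whose cleaning must survive free-text noise, location
values are controlled vocabulary where "l'assomption" is the canonical
form); Unicode apostrophe variants are normalized to ASCII.

## Features and encoding

Tokens are namespaced `group:slot[:n]:value`, so the same substring in
different slots is a distinct vocabulary entry — pooling across slots
would erase positional signal. Within a slot/n cell, duplicate substrings
are collapsed before counting (per-record values are then 0/1); a
`dedup_tokens=False` flag switches to multiset counts. Vowels are
{a,e,i,o,u}; "y" is not counted. The mean entity length is carried at full
precision and rounded only for display. Phoneme codes are computed per
entity (primary and secondary double-metaphone), pooled over the full
name, with empty secondaries dropped.

Double metaphone is implemented in-package from the published algorithm
(Philips 2000), untruncated, and pinned by a frozen table of canonical
test vectors.

Vocabularies are fitted on the training partition only, in lexicographic
order; out-of-vocabulary tokens at predict time contribute nothing.
Single-valued categoricals (four location features, sex) are one-hot
encoded with unknown categories mapping to all-zeros, which keeps the
column count fixed at fit time. Numeric statistics are scaled to zero mean
and unit variance using population variance — the exact reading of the
unit-variance contract; the sample/population difference is immaterial at
the sample sizes involved — and constant columns map to zero. The dummy
benchmark is two label-independent columns (a random token id from a
1,000-token universe, hashed to a single column, and a Uniform(0,1) draw),
regenerated deterministically from the seed.

## Pipelines

Records split 80/20 into train/test with half-up rounding of the test
size; the dev set is a 12.5% subsample of the training partition (so dev ⊆
train and final training legitimately includes the dev rows). Feature-set
selection runs 5-fold stratified CV with regularized logistic regression
on each candidate set: the four name groups individually, the benchmarks
(dummy, sex), "All name features", "All location features" and their
union. A name group is admitted when its CV F1 exceeds the dummy
benchmark's by at least 10% relative. The combined name+location set is
formed regardless of whether it confirms a ≥ 10% gain over names alone;
the confirmation outcome is reported.

Hyperparameter search is randomized: candidates drawn from log-uniform
C ∈ [1e-3, 1e3] with penalty ∈ {L1, L2} for logistic regression, the same
cost grid for the linear SVC, log-uniform additive smoothing [1e-3, 10]
for naive Bayes; 20 candidates by default, each scored by 5-fold CV
repeated three times, ties broken by earliest draw. These distributions are the package's
own defaults — the selection/tuning protocol fixes the CV structure, not
the search space.

Naive Bayes is the Bernoulli variant: the design matrix mixes 0/1 token
indicators with signed z-scaled numerics, which multinomial/complement NB
reject and which Gaussian NB would require densifying. Class weighting and
resampling are off by default despite the heavy class imbalance (a
`class_weight` flag exists for research use). Decision trees and random
forests are implemented but excluded from default reports. Prediction ties
resolve to the lexicographically smallest label (classes are sorted and
argmax takes the first maximum).

Evaluation collapses the multiclass confusion matrix one-vs-rest per
class. Undefined ratios (zero denominators, e.g. PPV of a never-predicted
class) propagate as NaN — never 0 — and are excluded from the
support-weighted overall together with their support. Overall accuracy is
therefore the support-weighted one-vs-rest accuracy, which on imbalanced
data sits well above the micro accuracy (trace/total); support-weighted
sensitivity, by contrast, equals trace/total exactly. "Average PPV" is
average precision (precision averaged over recall steps), paired with
AUC-ROC as threshold-sweep summaries; for margin classifiers the signed
decision score is used.

One consequence of the NaN-exclusion convention worth knowing: a
degenerate predictor that only ever emits the majority class has a defined
F1 for that class alone, so its weighted overall F1 equals the majority
class's F1 (≈ 2p/(1+p) at majority share p), not a near-zero value.
Benchmark comparisons in the tests therefore anchor on balanced synthetic
priors or on micro accuracy, where chance is unambiguous.

## Synthetic census

The generator emulates the structure of early-1900s Canadian census
microdata with no real personal data. Defaults define the study
conditions:

* **Priors** shaped like turn-of-century Canada: Fr .31, En .24, Ir .18,
  Sc .15, Others .085, Ab .025, Ru .004, Ch .003, It .002, Jp .001;
  Aboriginal subgroups .70/.20/.05/.05 (Fn/Mé/In/other). The known
  frequency ranking and heavy imbalance are reproduced without claiming
  exact historical frequencies.
* **Names** drawn from per-category lexicons (120 surnames, 80 given
  names) generated by first-order character chains with Dirichlet-skewed
  rows (concentration 0.25); category lexicons are disjoint by
  construction, and a shared lexicon replaces the category draw with
  probability `lexicon_overlap` (default 0.2) — at 1.0 names carry no
  signal.
* **Numeric signal**: with probability `numeric_signal` (default 0.5) a
  word's length is drawn around a category-specific centre spread over
  3–9 characters, making the numeric name statistics informative; at 0
  they are label-independent.
* **Geography**: a gazetteer of 1901-era provinces/districts; each
  category receives a disjoint home-district set, used with probability
  `segregation` (default 0.7), else a uniform district — at 0 location
  carries no signal.
* **Sex** is Bernoulli(0.5) independent of category; **label noise**
  (default 0.01) resamples the gold label from the priors, which leaves
  the marginal label distribution unchanged.

What the generator does not emulate: transcription/OCR noise, real
phonology or orthography of any language, family structure (shared
surnames within households), within-category naming heterogeneity, or
historical migration patterns. Passing tests therefore demonstrate that
the pipeline recovers planted signal of the stated kinds and strengths,
not that any particular real-data accuracy is attainable.

## Problem sizes and numerics

Pipeline-level tests run at n ≈ 400–4,000 records (monotonicity sweeps at
n = 1,200 over five seeds; distributional checks at n = 50,000, generation
only), chosen so the full suite completes in minutes on one CPU while
leaving the tested properties far from their noise floors. The acceptance
script's synthetic run uses n = 20,000 with 4 search candidates per model.
Regularized logistic regression uses liblinear coordinate descent,
wrapped one-vs-rest for multiclass problems: liblinear handles both L1
and L2 penalties on sparse input efficiently at any regularization
strength, where stochastic-gradient solvers stall at weak regularization.
Reproducibility is exact for fixed seeds (all randomness flows from numpy
`default_rng` or scikit-learn `random_state`).

Known limitations: the alias map and title lexicon are illustrative
fixtures, not curated historical resources; single-column hashing of the
dummy string feature is a deliberate 2-column benchmark rather than a
faithful one-hot of 1,000 random tokens; metric values on tiny test folds
are quantized, so fold-mean F1 comparisons at very small n should be read
with that granularity in mind.
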