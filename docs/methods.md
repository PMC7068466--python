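# Methods

`lbpnlp` classifies free-text primary-care notes as describing an *acute low
back pain* (acute LBP) episode or not. Acute and chronic low back pain share
a single billing code (ICD-10 M54.5, no acuity modifier), so acuity lives
only in the narrative text. The package implements five scoring strategies
over a common preprocessing pipeline, the cross-validated protocol that
compares them under manual versus silver (ICD-code-derived) training labels,
and a synthetic-note generator that stands in for private clinical corpora.

## Preprocessing

Raw note text is cleaned (URLs, emails and numeric dates excised by the
regexes at the top of `text_processing.py`), split into sentences on terminal
punctuation and newlines, lowercased and tokenized to alphabetic tokens
(numbers, dose strings and punctuation drop out). Tokens pass through a small
rule-based English noun-plural lemmatizer (`lemmatize=False` falls back to
lowercasing only); verb forms are left untouched, which matches how a
POS-blind noun lemmatizer behaves.

A vocabulary keeps every token with training-corpus frequency ≥ 5 (indices
sorted by descending frequency, ties lexicographic). Out-of-vocabulary
tokens are corrected to the vocabulary term with minimum Levenshtein distance
(edlib), ties broken by higher corpus frequency then lexicographic order. A
correction cap of `max_distance=2` is applied by default: an uncapped
nearest-term rule would map arbitrary junk onto real words;
`max_distance=inf` restores the uncapped behaviour. Correction runs after
lemmatization. Vocabularies are fitted per cross-validation fold on the
fold's training portion (a whole-corpus mode exists for exploration).

## The five scorers

**WordSearch** counts non-negated occurrences of four acuity keyword phrases
("acute low back pain", "acute lbp", "acute low bp", "acute back pain") with
longest-match-first, non-overlapping matching on the processed tokens. A
NegEx-style rule resolves each mention: a pre-trigger ("no", "denies",
"without", "negative for", ...) within a 5-token scope window before the
mention negates it unless a scope terminator ("but", "however", "although")
intervenes; post-triggers ("ruled out", "unlikely") act within the window
after the mention. Trigger lexicon and keyword list ship as editable
plain-text config. The mention count `c` is squashed to a score
`1 − exp(−c)` so it is comparable to the probabilistic scorers; any strictly
monotone map yields identical rankings and hence identical ROC/PR areas.

**TopicModel** fits latent Dirichlet allocation (scikit-learn's variational
implementation; symmetric priors α = 1/K, β = 0.01) on the training notes,
ranks topics by `relevance(k) = Σ_w p(topic k | w)` over the acuity keywords
(acute, low, back, pain, lbp, bp) with `p(k|w)` obtained by Bayes' rule from
the topic-word distributions and the empirical topic prior (mean training
doc-topic mass; a uniform-prior mode exists), and retains a reviewed subset
of topics. The manual review step is externalized: retained-id files can be
supplied per fold, and a non-interactive top-`m` fallback supports automated
runs. A note's score is the maximum inferred probability among retained
topics; empty notes score 0. The full-scale default is K = 200 topics; the
desk-scale experiments here use K = 40 with m = 2, chosen on a held-out
probe of the synthetic corpus before the benchmark runs.

**BoN-LR / FeatEng-LR** represent a note as TF-IDF-weighted counts of
within-sentence n-grams (n = 1..5) after removing a fixed English stop-word
list, with `idf(g) = ln((1+N)/(1+df(g))) + 1` and L2 document normalization
(the common smoothed-idf convention, pinned exactly so tests can be exact).
N-grams do not cross sentence boundaries. BoN-LR indexes every training
n-gram; FeatEng-LR restricts to a curated lexicon (the original ~5k-entry
guideline lexicon is unpublished, so a small illustrative lexicon of
diagnosis/medication/recommendation phrases ships with the package; any
lexicon file is accepted). Classification is L1-penalized (LASSO) logistic
regression via liblinear; the inverse-regularization strength is selected on
the validation split from the grid {4, 16, 64} by AUC-ROC unless fixed.

**ConvNet** feeds word embeddings to parallel 1-D convolutions with kernel
sizes 1..5 (emulating n-grams), each ReLU-activated and global-max-pooled
over the whole note, concatenated (|kernels| × filters), then two fully
connected layers with batch normalization and ReLU and a sigmoid output.
Embeddings are initialized by skip-gram word2vec trained on the note corpus
only (dynamic window 5, 5 negative samples from the unigram^0.75
distribution, frequent-word subsampling at 10⁻³, 5 epochs, linearly decaying
learning rate) and fine-tuned during supervised training. Training is binary
cross-entropy with Adam for exactly 5 epochs, batch size 32, learning rate
0.001, dropout 0.5 on the pooled concatenation and after each FC layer; no
early stopping. The output bias starts at the training-prior log-odds so the
short schedule refines ranking rather than relearning the base rate.
Minibatches are length-bucketed (notes sorted by length, batch order
shuffled per epoch) to bound padding waste; padding uses a frozen all-zero
embedding row, benign under ReLU + max-pool. The whole network is a compact
vectorized numpy implementation (batched matmul convolutions, manual
backprop, Adam, batch norm) — small enough to train on one CPU core.

Full-scale defaults are embedding 300, 200 filters per kernel, two FC
layers of 600 and learning rate 0.001. `ConvNetConfig.scaled()` (embedding
32, 32 filters, FC 64) keeps the architecture shape and the epoch/batch
schedule at sizes matched to corpora of a few thousand short notes, with the
step size raised to 0.003: desk-scale corpora provide roughly an order of
magnitude fewer optimizer steps than the full-scale schedule assumes, and at
the full-scale step size the sigmoid outputs stay compressed near the class
prior (well-ranked but poorly calibrated). All experiments here use the
scaled preset.

*Attribution.* Each max-pool unit is produced by exactly one input window —
an n-gram of that kernel's size. A unit's contribution to a note's score is
the log-odds change when its pooled activation is occluded (set to zero),
computed through the FC head in evaluation mode; contributions are summed
per distinct n-gram and ranked. Occlusion in log-odds was chosen because it
is exact, cheap (only the head is re-evaluated) and model-faithful; summed
unit contributions track the total logit shift closely whenever the head is
near-linear over the occlusion range.

## Evaluation protocol

k-fold cross-validation (default k = 10) with every note tested exactly
once; folds are stratified by the manual label because 5% prevalence makes
unstratified folds unstable. Within each training portion a seeded 90/10
train/validation split is made; the decision threshold is tuned per fold on
the validation split over the grid 0.1..1.0 (step 0.1) by F score, ties
toward the smallest threshold. Supervised models train either on manual
labels or on ICD-10 silver labels (M54.5 ∈ code set); threshold tuning uses
the same label source as training; evaluation is always against manual
labels, with never-reviewed notes counting as negatives (a strict mode
restricts evaluation to reviewed notes). AUC-ROC (rank statistic with tie
correction) and AUC-PRC (step-integrated precision-recall, i.e. average
precision) are computed threshold-free from the scores. The ICD-10 baseline
scores each note with its silver label directly.

The annotation-subsampling experiment keeps a fraction of the positive
training annotations and **removes** the rest from the training set (rather
than flipping them to negative — both readings are defensible; removal was
chosen and is switchable), leaving evaluation unchanged.

Skip-gram pretraining is unsupervised and uses note text only, so the
benchmark pretrains embeddings once on the whole corpus and slices each
fold's vocabulary from them; per-fold pretraining is available on the model
class but changes nothing about label hygiene.

## Synthetic corpus

The generator emulates the documented shape of a primary-care note corpus:
lognormal note lengths (median ≈ 120 words) clipped to [7, 2000] words
(the upper clip is configurable up to real-corpus maxima; 2000 keeps
experiments tractable); 5% prevalence; positives carry 1–3 planted signal
insertions — a direct keyword sentence (plus, usually, a
medication/recommendation support sentence) with probability
1 − `paraphrase_rate`, otherwise paraphrase and support sentences only
("shooting pain down into the lower extremities", "prescribed muscle
relaxant", ...). 10% of controls contain a *negated* keyword mention; 5%
carry a stray support phrase as a distractor; 1% of tokens (length ≥ 4)
receive a random single-character misspelling. ICD-10 M54.5 codes are
assigned by Bernoulli draws calibrated so that, in expectation, the code has
precision 0.32 and recall 0.68 against ground truth (the solver rejects
infeasible precision/recall/prevalence combinations); falsely coded controls
additionally carry chronic-low-back-pain text, mimicking the real failure
mode of the acuity-blind code. Background text is template-sampled clinical
filler from an editable JSON phrase bank, with occasional dates and URLs to
exercise the cleaning patterns.

What the generator does **not** emulate: provider writing style, discourse
structure, realistic co-morbidity distributions, abbreviation noise beyond
single-character edits, or any protected health information. Passing tests
on this corpus therefore demonstrate that the machinery recovers planted
signal under calibrated label noise and paraphrase/negation confounds — not
clinical-grade performance on real notes.

## Numerical choices and degenerate inputs

- Ties in vocabulary indexing, OOV correction, threshold tuning, fold
  assignment and topic ranking are all broken deterministically
  (frequency then lexicographic order, or smallest grid value), making every
  stage bit-reproducible from (input file, config, seed).
- Empty processed notes are legal everywhere: they score 0 under WordSearch
  and TopicModel and are padded to the largest kernel for the ConvNet (with
  a logged warning).
- Batched skip-gram updates rely on frequent-word subsampling to keep
  repeated-row accumulation stable; on tiny corpora where subsampling would
  drop everything the pretrainer returns its initialization with a warning
  (pass `sample=0` there).
- LDA document-topic vectors are renormalized to sum to one; topic scores of
  notes with no in-vocabulary tokens are 0 rather than the prior mass.
- Experiment sizes used by the test suite and the reproduction script
  (n = 2000 notes, 10- or 5-fold CV with the subsampling curve run on the
  same fold plan, K = 40 topics, the scaled ConvNet) are the package's
  desk-scale study conditions; all are parameters, and the full-scale
  defaults (K = 200, 300-d embeddings, 200 filters) remain the documented
  defaults of the respective classes.

## Known limitations

- The NegEx implementation covers trigger/terminator scope logic only; no
  temporality or experiencer attributes, and no dependency-parse scoping.
- The lemmatizer is intentionally minimal; clinical abbreviation expansion
  and subword tokenization are out of scope.
- Edit-distance correction can still canonicalize a rare real word onto a
  frequent neighbour at distance ≤ 2; the cap and the min-count threshold
  are the only guards.
- The curated FeatEng lexicon shipped here is illustrative, not the original
  guideline-derived list, so FeatEng-LR results characterize the mechanism,
  not the original feature set.
- LDA topic quality (and hence TopicModel scores) varies noticeably with K
  and the random seed at desk scale; per-fold averaging in the benchmark
  smooths but does not remove this.
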