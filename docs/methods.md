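# Methods

This note documents the models, conventions and design choices behind
`adr_speech`, including the points where the procedure admitted more than
one reading and a choice had to be fixed.

## Inputs and preprocessing

The package consumes, per participant: a CHAT-style transcript
(participant tier only), a word-level alignment table (token, start, end,
optional lemma/POS), and a per-token acoustic descriptor table whose rows
align 1:1 with the alignment. Forced alignment and acoustic extraction are
upstream of the package; their outputs are its inputs.

Transcript cleaning handles exactly the DementiaBank constructs relevant
to surface-word recovery: `w [x n]` repetition markers expand to n copies
of w (non-integer n is a parse error naming the line); bracketed comments,
the pause marks `(.) (..) (...)`, the symbols `< > /`, the
unintelligible-speech mark `xxx`, and all punctuation are removed; case is
preserved. Words enclosed in `<…>` are kept — the *symbols* are removed,
not their content. All other CHAT codes are stripped conservatively.
Cleaning is idempotent.

Pause encoding maps pause durations to punctuation-like symbols: below
50 ms dropped, [0.05, 0.5) s → `,`, [0.5, 2] s → `.`, above 2 s → `…`. The
band edges are half-open with 2 s belonging to the medium band; the
specific glyphs are a convention (the bands are what carries information)
chosen to mirror the punctuation-style encodings used in pause-aware
transcript modelling.

## Token fusion

Acoustic descriptors whose absolute Pearson correlation with token
duration exceeds 0.2 are removed — strictly `>`, so |R| = 0.2 is retained.
The criterion is the correlation magnitude alone; no p-value gate.
Zero-variance columns have undefined correlation and are retained with a
logged warning. Both the retained-column set and the per-coordinate
min-max ranges (fitted separately for the acoustic and embedding blocks)
are estimated on the **training population only** and applied frozen to
held-out data; held-out values outside the fitted range clip into [0, 1]
rather than extrapolate, and constant coordinates map to 0. Fitting before
or after the train/test split is a genuine leakage decision; train-only
fitting is the defensible choice and is what the pipeline does.

Word embeddings are looked up lowercased in a GloVe-format lexicon;
pauses and out-of-lexicon words map to the zero vector — the only
embedding defined for a non-lookup. The retained-column count is
data-dependent: 72 on data whose duration-correlated subset matches the
canonical layout (giving 122 = 72 + 50 fused dimensions), but the package
does not hard-code 72.

## ADR features

k-means (k-means++ init, 10 restarts, 300-iteration cap, seed-controlled)
clusters the pooled training tokens of the active modality. Centroids are
canonically reordered by descending assigned-token count with ties broken
by first-coordinate value, so feature indices are stable across runs.
Held-out tokens are assigned to frozen centroids; equidistant assignments
break toward the lower cluster index.

Six participant-level features:

- **cluster counts** — tokens per cluster; sums to the token count.
- **duration** — per-cluster summed token duration over total duration;
  sums to 1. The underlying description ("histogram of utterance
  duration") is ambiguous between duration-value bins and cluster bins;
  the cluster-bin reading is implemented because it keeps a single
  k-indexed geometry consistent with the counts histogram and the ADR
  lineage.
- **word/pause embedding sequence** — a 1-component PCA fitted on the
  participant's own token sequence projects each token to a scalar;
  truncated to the **first** 128 entries or zero-padded. Participants with
  fewer than 2 tokens (or a constant sequence) yield zeros with a warning.
- **centroid embedding** — the 1-component reduction is fitted on the
  participant's per-token centroid sequence; entry j is the projection of
  centroid j for visited clusters and 0 for unvisited ones (length k).
  The source description of this feature is underspecified; this
  interpretation — PCA on the centroid sequence, reported per cluster
  index — is the one implemented and should be kept in mind when comparing
  against other implementations.
- **embedding velocity** and **centroid velocity** — cosine similarity of
  consecutive token embeddings / consecutive tokens' centroids; n tokens
  yield n−1 similarities, truncated/padded to 128. cos(x, 0) ≔ 0 (zero
  vectors arise for pauses in the text modality); 0 encodes "no
  directional continuity".

PCA is sign-ambiguous in 1-D; the component's largest-magnitude loading is
made positive, a deterministic convention required for reproducibility.

Configurations: *Temporal* = {counts, duration, both velocities};
*Embedding* = {counts, duration, embedding seq, centroid embedding};
*Centroid* = {counts, duration, centroid embedding, centroid velocity};
*New* = {embedding seq, centroid embedding, both velocities}; *All* = all
six. The printed source list for *New* names the centroid embedding twice
while announcing four new features; the set implemented here is the
self-consistent reading (the four features absent from the original ADR).
The text modality has no duration feature (no audio timing). Assembly
order is fixed: counts, duration, embedding seq, centroid embedding,
embedding velocity, centroid velocity.

## Lexical features

Word-bound char 4-grams: each word padded with one leading and one
trailing space, 4-character windows never crossing word boundaries; padded
forms shorter than 4 emit themselves as a single gram. TF-IDF uses the
de-facto standard dialect — smoothed idf ln((1+N)/(1+df)) + 1 and L2 row
normalisation — since no specific dialect is canonical for this feature
family; the vectorizer is fitted on training transcripts only.

Positional bag-of-words: a transcript of w words splits into c = 3
contiguous chunks, the first (w mod c) chunks receiving ⌈w/c⌉ words. Each
vocabulary lemma is counted per chunk (suffixes `_1.._3`); matching is on
lemmas by default (the noun vocabulary is lemmatised), with raw-surface
matching available. 20 nouns × 3 chunks = 60 features.

## Temporal analysis

Noun positions are 1-based word indices **within the participant's own
transcript** (pauses not counted, positions not length-normalised). The
profile averages positions per class, drops nouns below a frequency
threshold (default 20 corpus occurrences) and nouns attested in only one
class, and sorts by descending absolute contrast. Importance aggregation
averages the per-forest normalised impurity-decrease importances across
the seed ensemble; per-lemma scores sum the lemma's chunk features. The
correlation between importance sums and position contrasts is a standard
Pearson r with a two-sided t-test p-value.

## Classification

Learners and frozen hyperparameters: random forest (50 trees, depth 5),
gradient-boosted trees (50 trees, depth 10), linear-kernel SVM (C = 10),
logistic regression (C = 10), LDA. Unprinted hyperparameters follow
library defaults. Labels are encoded with AD as the positive class.

The seed-ensemble reading implemented: for each of n_members seeds a
**full LOOCV pass** produces one held-out prediction per instance, and
each instance's final label is the majority over its seed-wise
predictions (the alternative — LOOCV over one 50-member ensemble — is
available by composing `train_ensemble`/`predict_majority` inside a manual
fold loop). An even ensemble can tie 25–25; ties resolve to non-AD,
favouring specificity. Folds that lose a class entirely predict the fold
majority with a warning. Grid search scores each (learner, k) combination
by the mean of five single-model LOOCV repetitions with distinct seeds.
Late fusion takes exactly three configurations' final votes, so no ties
are possible.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
real English: transcripts are filler-word sequences (~90 words,
SD 15) into which up to 20 scene nouns are placed at Gaussian positions
around noun-specific base positions (spread over word indices 8–60), with
inter-word pauses (rate 0.25, log-normal durations, median ≈ 0.3 s) and
log-normal word durations. Class effects are additive and independent so
each feature family is testable in isolation: AD adds a temporal shift δ
(default 10 words) to noun positions, a mean offset Δa (default 0.5 SD) to
30 acoustic columns, and a 1.5× sampling-odds multiplier on five filler
words. 16 of the 88 acoustic columns are constructed from token duration
(R ≈ 0.9) to exercise the duration filter, leaving 72 retained — the
canonical layout. Transcript length is lower-truncated so the latest noun
remains placeable under the injected shift; without this the injected
shift would be silently attenuated by boundary clipping. The default
cohort is 54 + 54 train and 24 + 24 test, mirroring the canonical
challenge proportions.

What the generator does **not** emulate: grammar and discourse coherence,
realistic embedding geometry (vectors are isotropic Gaussians), acoustic
covariance structure, speaker-level heterogeneity beyond the class
effects, or MMSE-style severity gradients. Passing tests therefore
demonstrate that the pipeline recovers the effects it is designed for
under its own assumptions — not clinical validity on real cohorts, which
requires access-controlled corpora.

## Verification scales

The test suite and `scripts/acceptance.py` run everything at desk scale:
shift-recovery uses 20 replicate cohorts of 15 participants per class;
classification checks use cohorts of 10–15 per class with ensembles of
11–15 seeds and k = 5–10 clusters. These sizes keep every stochastic check
inside a few minutes while leaving the binomial/replicate confidence
intervals tight enough to be informative; all of them are configuration
parameters, and the defaults for real use (k = 30, 50 seeds, 54 + 54
cohorts) are the package-level constants.

## Known limitations

- The centroid-embedding feature follows one of several defensible
  readings of an underspecified description (see above).
- LOOCV majority accuracy on null data sits slightly below 0.5 on
  average — the familiar pessimistic bias of leave-one-out with class
  re-balancing — which the calibration checks absorb inside the binomial
  interval.
- Headline accuracies reported for the restricted clinical corpus are not
  reproducible here by construction; the package validates structure,
  oracle equivalence and parameter recovery instead.
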