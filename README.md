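# adr-speech

Multimodal **Active Data Representation (ADR)** features for detecting
Alzheimer's dementia from spontaneous speech.

Picture-description speech (e.g., the Cookie Theft task) carries both
paralinguistic signal — pitch, loudness, voice quality, pausing — and
linguistic signal — which words are used and, crucially, *when* in the
description they occur. This package fuses the two modalities at the token
level and aggregates them to the participant level for classification of
AD vs. non-AD speakers. It is aimed at researchers in clinical speech and
language biomarkers who already have word-level alignments, per-token
acoustic descriptors and transcripts, and want a reproducible feature and
evaluation pipeline.

## What it computes

**Token fusion.** Each word or inter-word pause gets an audio-textual
embedding: eGeMAPS-style acoustic descriptors with duration-correlated
columns removed (|Pearson R| > 0.2 against token duration), concatenated
with a 50-dimensional word embedding (zeros for pauses), each block min-max
normalised to [0, 1] on the training population. With the canonical 88 → 72
retained descriptors this yields 122-dimensional fused tokens.

**ADR features.** Pooled training tokens are clustered with k-means
(k = 30 by default, selected by grid search over k ∈ {10, …, 80}). Each
participant is summarised by six features: cluster counts; per-cluster
duration shares; the token-embedding sequence reduced to 1-D by PCA
(length 128, zero-padded); the visited-cluster centroids projected the same
way (length k); and two velocity sequences, the cosine similarity

&nbsp;&nbsp;cos(t, e) = t·e / (‖t‖‖e‖)

between consecutive token embeddings and between consecutive tokens'
cluster centroids (length 128 each). Named configurations (*Temporal*,
*Embedding*, *Centroid*, *New*, *All*) select subsets, crossed with three
input modalities (audio, text, text+audio) and optionally combined with
TF-IDF-weighted word-bound character 4-grams.

**Classification.** 50 identically configured learners (random forest with
50 trees of depth 5 by default) differing only in random seed vote per
instance; leave-one-out cross-validation gives training-set scores;
accuracy is (TP+TN)/(TP+FP+TN+FN) with AD positive. The final votes of the
top three configurations can be late-fused.

**Temporal analysis.** A per-noun profile of average 1-based transcript
position per class, and a positional bag-of-words (each noun counted
separately per transcript third, 20 nouns × 3 chunks = 60 features) whose
ensemble-averaged impurity-decrease importances are correlated against the
position contrasts.

A synthetic-cohort generator produces labeled corpora with injectable
class effects (acoustic mean shift, lexical preference, temporal noun
shift) in exactly the file formats the readers consume, so the whole
pipeline is testable without any restricted clinical data.

## Worked example

```bash
python examples/noun_position_analysis.py
```

```
noun-position profile (top 5 by position contrast):
  lemma    AD  non-AD  Difference  Freq
curtain 34.46   19.40       15.06    23
    boy 53.09   39.70       13.39    21
 sister 67.78   55.15       12.62    22
  stool 24.75   12.25       12.50    20
 action 29.20   16.73       12.47    21

temporal BoW LOOCV majority accuracy (10 seeds): 0.9667
(chance is 0.5; the injected 10-word shift makes the classes separable)

most important nouns (summed over chunks):
lemma
curtain    0.1667
thing      0.1271
cookie     0.1068
sister     0.0989
mother     0.0981

Pearson r(importance sums, position contrasts) = 0.22 (p = 0.34)
```

The cohort here injects a 10-word positional shift for AD speakers: the
profile's *Difference* column recovers contrasts around 10–15 words, the
positional bag-of-words classifier separates the classes far above chance,
and the weak importance/position correlation shows the forests exploit
finer positional structure than per-noun averages capture.

Other examples: `simulate_and_inspect.py` (cohort anatomy and pause
encoding), `fuse_and_cluster.py` (the 122-dimensional fusion and the six
ADR features), `classify_configurations.py` (configuration comparison and
late fusion).

A thin CLI wraps the same library calls:

```bash
adr-speech simulate --seed 5 --out bundle/
adr-speech featurize --bundle bundle/ --configuration Temporal --k 30 \
    --evaluate --out features/
```

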