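"""Temporal analysis: where in a transcript does each scene noun appear?

Computes the per-noun average 1-based transcript position per class, trains
a seed-ensemble of random forests on positional bag-of-words features
(noun × transcript-third), aggregates impurity-decrease importances, and
correlates the per-noun importance sums with the position contrasts.
"""

import numpy as np

from adr_speech import (
    EnsembleSpec,
    SyntheticConfig,
    generate_cohort,
    importance_position_correlation,
    loocv_majority,
    noun_position_profile,
    train_ensemble,
)
from adr_speech import pipeline
from adr_speech.lexical import TemporalBowSpec, temporal_bow
from adr_speech.synthetic_data import SCENE_NOUNS
from adr_speech.temporal_analysis import (
    aggregate_importance,
    lemma_importance_sums,
    profile_to_frame,
)

# AD speakers mention scene nouns ~10 words later in this cohort
cohort = generate_cohort(
    SyntheticConfig(n_train_per_class=15, n_test_per_class=0,
                    temporal_shift=10.0, acoustic_shift=0.0, lexical_odds=1.0, seed=4)
)
rows = noun_position_profile(cohort.train, min_frequency=15)
print("noun-position profile (top 5 by position contrast):")
print(profile_to_frame(rows).head().round(2).to_string(index=False))

# positional bag-of-words: 20 nouns x 3 transcript thirds = 60 features
spec = TemporalBowSpec(vocabulary=list(SCENE_NOUNS), n_chunks=3)
X = np.vstack([temporal_bow(r.lemmas, spec) for r in cohort.train])
y = pipeline.labels_of(cohort.train)
ens = EnsembleSpec(seeds=tuple(range(10)))
_, acc = loocv_majority(X, y, ens)
print(f"\ntemporal BoW LOOCV majority accuracy ({ens.n_members} seeds): {acc:.4f}")
print("(chance is 0.5; the injected 10-word shift makes the classes separable)")

forests = train_ensemble(X, y, ens)
table = aggregate_importance(forests, spec.feature_names())
sums = lemma_importance_sums(table)
print("\nmost important nouns (summed over chunks):")
print(sums.head().round(4).to_string())

by_lemma = {r.lemma: r.abs_difference for r in rows}
common = [lem for lem in sums.index if lem in by_lemma]
r, p = importance_position_correlation(
    sums[common].to_numpy(), np.array([by_lemma[lem] for lem in common])
)
print(f"\nPearson r(importance sums, position contrasts) = {r:.2f} (p = {p:.2f})")
# A weak correlation means the forests pick up finer-grained positional
# structure than the per-noun average position captures.
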