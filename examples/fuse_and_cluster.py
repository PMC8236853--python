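"""Token fusion and the six ADR features for one participant.

Pipeline: drop acoustic descriptors correlated with token duration
(|R| > 0.2), min-max normalise the acoustic and embedding blocks
separately, concatenate per token, cluster the pooled training tokens with
k-means, then summarise each participant with the six ADR features.
"""

import numpy as np

from adr_speech import (
    FeatureConfiguration,
    SyntheticConfig,
    fuse_tokens,
    generate_cohort,
)
from adr_speech import pipeline
from adr_speech.adr import adr_features, assemble

cohort = generate_cohort(SyntheticConfig(n_train_per_class=5, n_test_per_class=0, seed=2))
configuration = FeatureConfiguration("All", "text+audio")

featurizer = pipeline.fit_featurizer(
    cohort.train, cohort.acoustic, cohort.lexicon, configuration, k=10, seed=0
)
print(f"retained acoustic descriptors: {len(featurizer.retained_columns)} of 88")
print(f"fused token dimensionality: {featurizer.model.dim} "
      f"({len(featurizer.retained_columns)} audio + {cohort.lexicon.dim} text)")

record = cohort.train[0]
emb = fuse_tokens(
    record, cohort.acoustic[record.participant_id], cohort.lexicon,
    featurizer.retained_columns, featurizer.ranges,
)
feats = adr_features(emb.fused, record.durations(), featurizer.model)
print(f"\nADR features for {record.participant_id} (k=10):")
for name, vec in feats.items():
    print(f"  {name:20s} length {len(vec):3d}  "
          f"nonzero prefix {int(np.max(np.nonzero(vec)[0])) + 1 if vec.any() else 0}")
print(f"  cluster_counts sums to token count: {int(feats['counts'].sum())} "
      f"== {len(record.tokens)}")
print(f"  duration feature sums to {feats['duration'].sum():.6f} (always 1)")
print(f"\n'All' configuration vector length: {len(assemble(feats, configuration))}")
# With k=30 this would be 30+30+128+30+128+128 = 474 features.
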