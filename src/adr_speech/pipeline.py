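"""End-to-end featurization: corpus -> participant-level design matrices.

Glues the stages together under train/test discipline: the
duration-correlation filter, the min-max normalisation ranges, the k-means
token clustering and the char-4-gram TF-IDF vocabulary are all fit on the
training participants only and applied frozen to held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from adr_speech import adr, token_fusion
from adr_speech.adr import ADRModel, FeatureConfiguration
from adr_speech.corpus_io import EmbeddingLexicon, ParticipantRecord
from adr_speech.lexical import Char4GramVectorizer, fit_tfidf
from adr_speech.token_fusion import NormalizationRanges, TokenEmbeddings


@dataclass
class FittedFeaturizer:
    """Frozen training-population fit state of the featurization pipeline."""

    retained_columns: list[str]
    ranges: NormalizationRanges
    model: ADRModel
    configuration: FeatureConfiguration
    vectorizer: Char4GramVectorizer | None = None

    @property
    def k(self) -> int:
        return self.model.k


def _participant_embeddings(
    record: ParticipantRecord,
    acoustic: pd.DataFrame,
    lexicon: EmbeddingLexicon,
    retained_columns: list[str],
    ranges: NormalizationRanges,
) -> TokenEmbeddings:
    return token_fusion.fuse_tokens(record, acoustic, lexicon, retained_columns, ranges)


def fit_featurizer(
    train_records: list[ParticipantRecord],
    acoustic: dict[str, pd.DataFrame],
    lexicon: EmbeddingLexicon,
    configuration: FeatureConfiguration,
    k: int = adr.DEFAULT_K,
    seed: int = 0,
) -> FittedFeaturizer:
    """Fit filter, normalisation, clustering and TF-IDF on the training set."""
    if configuration.modality == "text":
        retained: list[str] = []  # acoustic block unused in the text modality
    else:
        pooled_acoustic = pd.concat(
            [acoustic[r.participant_id] for r in train_records], ignore_index=True
        )
        pooled_durations = np.concatenate([r.durations() for r in train_records])
        retained = token_fusion.filter_duration_correlated(
            pooled_acoustic, pooled_durations
        )

    raw = [
        token_fusion.raw_blocks(r, acoustic[r.participant_id], lexicon, retained)
        for r in train_records
    ]
    ranges = token_fusion.fit_normalization(
        np.vstack([a for a, _ in raw]),
        np.vstack([t for _, t in raw]),
        fit_population="train",
    )
    pooled_modality = np.vstack(
        [
            _participant_embeddings(r, acoustic[r.participant_id], lexicon, retained, ranges)
            .for_modality(configuration.modality)
            for r in train_records
        ]
    )
    model = adr.fit_adr(pooled_modality, k=k, seed=seed, modality=configuration.modality)
    vectorizer = None
    if configuration.with_char4grams:
        vectorizer = fit_tfidf([r.transcript for r in train_records])
    return FittedFeaturizer(
        retained_columns=retained,
        ranges=ranges,
        model=model,
        configuration=configuration,
        vectorizer=vectorizer,
    )


def transform(
    featurizer: FittedFeaturizer,
    records: list[ParticipantRecord],
    acoustic: dict[str, pd.DataFrame],
    lexicon: EmbeddingLexicon,
) -> np.ndarray:
    """Participant-level design matrix under the frozen fit state."""
    cfg = featurizer.configuration
    rows = []
    for record in records:
        emb = _participant_embeddings(
            record, acoustic[record.participant_id], lexicon,
            featurizer.retained_columns, featurizer.ranges,
        )
        mat = emb.for_modality(cfg.modality)
        durations = None if cfg.modality == "text" else record.durations()
        feats = adr.adr_features(mat, durations, featurizer.model)
        rows.append(adr.assemble(feats, cfg))
    X = np.vstack(rows)
    if featurizer.vectorizer is not None:
        X = np.hstack(
            [X, featurizer.vectorizer.transform([r.transcript for r in records])]
        )
    return X


def feature_names(featurizer: FittedFeaturizer) -> list[str]:
    names = adr.feature_names(featurizer.configuration, k=featurizer.k)
    if featurizer.vectorizer is not None:
        names.extend(f"c4g:{g}" for g in featurizer.vectorizer.feature_names())
    return names


def featurize(
    train_records: list[ParticipantRecord],
    test_records: list[ParticipantRecord],
    acoustic: dict[str, pd.DataFrame],
    lexicon: EmbeddingLexicon,
    configuration: FeatureConfiguration,
    k: int = adr.DEFAULT_K,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, FittedFeaturizer]:
    """Fit on train, transform both splits; returns (X_train, X_test, fit)."""
    featurizer = fit_featurizer(train_records, acoustic, lexicon, configuration, k, seed)
    X_train = transform(featurizer, train_records, acoustic, lexicon)
    X_test = (
        transform(featurizer, test_records, acoustic, lexicon)
        if test_records
        else np.empty((0, X_train.shape[1]))
    )
    return X_train, X_test, featurizer


def labels_of(records: list[ParticipantRecord]) -> np.ndarray:
    return np.array([r.label for r in records], dtype=object)
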