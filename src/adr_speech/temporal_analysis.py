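"""Temporal-order analysis of picture-description transcripts.

Two instruments: a per-noun position profile contrasting where in their
transcripts AD and non-AD speakers mention each noun, and an aggregation of
random-forest impurity-decrease importances over the positional
bag-of-words features, with a Pearson correlation linking the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from adr_speech.corpus_io import ParticipantRecord

#: Corpus frequency below which a noun is dropped from the profile.
DEFAULT_MIN_FREQUENCY = 20

#: POS tags counted as nouns (universal-dependency style plus Penn fallbacks).
NOUN_TAGS = {"NOUN", "NN", "NNS", "NNP", "NNPS", "PROPN"}


@dataclass
class NounPositionRow:
    """Per-noun class-mean transcript positions and their contrast."""

    lemma: str
    mean_position_ad: float
    mean_position_nonad: float
    abs_difference: float
    frequency: int


def _noun_positions(record: ParticipantRecord) -> list[tuple[str, int]]:
    """(lemma, 1-based word index) for each noun occurrence in one record.

    Positions index words only (pauses are not counted) within the
    participant's own transcript: the first word has position 1.
    """
    out = []
    pos_counter = 0
    for tok in record.tokens:
        if tok.is_pause:
            continue
        pos_counter += 1
        if tok.pos in NOUN_TAGS:
            out.append((tok.lemma or tok.surface, pos_counter))
    return out


def noun_position_profile(
    records: list[ParticipantRecord],
    min_frequency: int = DEFAULT_MIN_FREQUENCY,
) -> list[NounPositionRow]:
    """Average transcript position of each noun, per class.

    Nouns below ``min_frequency`` total occurrences, and nouns present in
    only one class's transcripts, are excluded.  Rows are sorted by
    descending absolute difference of the class means, ties by lemma.
    """
    labels = {r.label for r in records}
    if not {"AD", "NONAD"} <= labels:
        raise ValueError(
            f"corpus must contain both AD and NONAD records; found {sorted(labels)}"
        )
    positions: dict[str, dict[str, list[int]]] = {}
    for record in records:
        if record.label not in ("AD", "NONAD"):
            continue
        for lemma, pos in _noun_positions(record):
            positions.setdefault(lemma, {"AD": [], "NONAD": []})[record.label].append(pos)
    rows = []
    for lemma, by_class in positions.items():
        freq = len(by_class["AD"]) + len(by_class["NONAD"])
        if freq < min_frequency:
            continue
        if not by_class["AD"] or not by_class["NONAD"]:
            continue  # noun seen in one class only
        mean_ad = float(np.mean(by_class["AD"]))
        mean_nonad = float(np.mean(by_class["NONAD"]))
        rows.append(
            NounPositionRow(
                lemma=lemma,
                mean_position_ad=mean_ad,
                mean_position_nonad=mean_nonad,
                abs_difference=abs(mean_ad - mean_nonad),
                frequency=freq,
            )
        )
    rows.sort(key=lambda r: (-r.abs_difference, r.lemma))
    return rows


def profile_to_frame(rows: list[NounPositionRow]) -> pd.DataFrame:
    """Profile as a table with columns lemma, AD, non-AD, Difference, Freq."""
    return pd.DataFrame(
        {
            "lemma": [r.lemma for r in rows],
            "AD": [r.mean_position_ad for r in rows],
            "non-AD": [r.mean_position_nonad for r in rows],
            "Difference": [r.abs_difference for r in rows],
            "Freq": [r.frequency for r in rows],
        }
    )


def aggregate_importance(forests, feature_names: list[str]) -> pd.DataFrame:
    """Mean impurity-decrease importance per feature over an ensemble.

    Each forest's importances are already normalised (sum to 1); the
    ensemble aggregate is their arithmetic mean.  Features following the
    ``<lemma>_<chunk>`` naming additionally receive per-lemma sums.
    """
    mats = np.vstack([f.feature_importances_ for f in forests])
    mean_imp = mats.mean(axis=0)
    df = pd.DataFrame({"feature": feature_names, "importance": mean_imp})
    df["lemma"] = [n.rsplit("_", 1)[0] if "_" in n else n for n in feature_names]
    return df


def lemma_importance_sums(table: pd.DataFrame) -> pd.Series:
    """Per-lemma summed importance over that lemma's chunk features."""
    return table.groupby("lemma")["importance"].sum().sort_values(ascending=False)


def importance_position_correlation(
    importance_sums: np.ndarray, abs_differences: np.ndarray
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of importance sums vs. position contrasts."""
    r, p = stats.pearsonr(
        np.asarray(importance_sums, dtype=float),
        np.asarray(abs_differences, dtype=float),
    )
    return float(r), float(p)
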