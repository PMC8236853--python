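"""Pure-text lexical features.

Two families: TF-IDF-weighted word-bound character 4-grams (each word is
padded with one space on both sides and 4-character windows never cross a
word boundary), and the positional ("temporal") bag-of-words in which a
transcript is cut into equal-length sequential chunks and every vocabulary
word is counted separately per chunk (suffixes _1, _2, _3).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer


def word_char4grams(word: str) -> Counter:
    """Word-bound character 4-gram multiset of a single word.

    The word is padded with one leading and one trailing space; a
    four-character window slides over the padded form.  Words whose padded
    form is shorter than four characters emit the whole padded form as a
    single gram; the empty word emits nothing.
    """
    if not word:
        return Counter()
    padded = f" {word} "
    if len(padded) < 4:
        return Counter([padded])
    return Counter(padded[i : i + 4] for i in range(len(padded) - 3))


def _analyze(doc: list[str] | str) -> list[str]:
    words = doc.split() if isinstance(doc, str) else doc
    grams: list[str] = []
    for w in words:
        grams.extend(word_char4grams(w).elements())
    return grams


class Char4GramVectorizer:
    """TF-IDF over word-bound char 4-grams (smoothed idf, L2 rows)."""

    def __init__(self) -> None:
        self._tfidf = TfidfVectorizer(
            analyzer=_analyze, norm="l2", smooth_idf=True, sublinear_tf=False
        )
        self.fitted = False

    @property
    def vocabulary(self) -> dict[str, int]:
        return dict(self._tfidf.vocabulary_)

    @property
    def idf(self) -> np.ndarray:
        return self._tfidf.idf_

    def fit(self, transcripts: list[list[str] | str]) -> "Char4GramVectorizer":
        if not transcripts:
            raise ValueError("cannot fit on an empty corpus")
        self._tfidf.fit(transcripts)
        self.fitted = True
        return self

    def transform(self, transcripts: list[list[str] | str]) -> np.ndarray:
        if not self.fitted:
            raise ValueError("vectorizer is not fitted")
        return self._tfidf.transform(transcripts).toarray()

    def feature_names(self) -> list[str]:
        return list(self._tfidf.get_feature_names_out())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "vocabulary": {g: int(i) for g, i in self._tfidf.vocabulary_.items()},
                    "idf": self._tfidf.idf_.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Char4GramVectorizer":
        d = json.loads(Path(path).read_text())
        vec = cls()
        tf = TfidfVectorizer(
            analyzer=_analyze, norm="l2", smooth_idf=True, vocabulary=d["vocabulary"]
        )
        tf.idf_ = np.asarray(d["idf"], dtype=float)
        vec._tfidf = tf
        vec.fitted = True
        return vec


def fit_tfidf(transcripts: list[list[str] | str]) -> Char4GramVectorizer:
    """Fit a word-bound char-4-gram TF-IDF vectorizer on a corpus."""
    return Char4GramVectorizer().fit(transcripts)


@dataclass
class TemporalBowSpec:
    """Vocabulary × chunk layout of the positional bag-of-words."""

    vocabulary: list[str] = field(default_factory=list)
    n_chunks: int = 3

    @property
    def size(self) -> int:
        return len(self.vocabulary) * self.n_chunks

    def feature_names(self) -> list[str]:
        return [
            f"{lemma}_{c + 1}"
            for lemma in self.vocabulary
            for c in range(self.n_chunks)
        ]


def chunk_indices(n_words: int, n_chunks: int) -> np.ndarray:
    """Chunk label (0-based) per word position under near-equal partition.

    With w words and c chunks the first (w mod c) chunks get ceil(w/c)
    words and the rest floor(w/c).
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    base, extra = divmod(n_words, n_chunks)
    sizes = [base + 1 if i < extra else base for i in range(n_chunks)]
    return np.repeat(np.arange(n_chunks), sizes)


def temporal_bow(words: list[str], spec: TemporalBowSpec) -> np.ndarray:
    """Count each vocabulary word separately per sequential transcript chunk.

    ``words`` should already be on the matching level (lemmas when the
    vocabulary is lemmatised).  Out-of-vocabulary words are ignored.
    """
    if not words:
        raise ValueError("transcript is empty")
    chunks = chunk_indices(len(words), spec.n_chunks)
    index = {lemma: i for i, lemma in enumerate(spec.vocabulary)}
    counts = np.zeros(spec.size)
    for word, chunk in zip(words, chunks):
        j = index.get(word)
        if j is not None:
            counts[j * spec.n_chunks + chunk] += 1
    return counts
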