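"""Synthetic labeled cohorts with the structure the method assumes.

Real picture-description corpora of AD and non-AD speakers differ along
three channels that the pipeline is designed to pick up: per-token acoustic
shifts, class-dependent lexical preferences, and a temporal reordering of
the scene nouns (AD speakers mentioning scene constituents later).  The
generator injects each effect additively and independently so every feature
family can be validated in isolation, and emits exactly the external
formats the readers consume.

The default cohort mirrors the canonical challenge proportions at the same
scale: 54 + 54 training and 24 + 24 test participants, ~90-word
descriptions mentioning up to 20 scene nouns, with inter-word pauses and an
88-column acoustic table per token of which a designated subset is
duration-correlated (to exercise the |R| > 0.2 filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from adr_speech.corpus_io import (
    EmbeddingLexicon,
    ParticipantRecord,
    Token,
    TokenKind,
    read_acoustic_table,
    read_alignment,
    read_chat_file,
    read_labels,
    read_lexicon,
    write_acoustic_table,
    write_alignment,
    write_labels,
    write_lexicon,
)

#: The 20 scene nouns of the picture-description task.
SCENE_NOUNS = (
    "window", "sink", "stool", "action", "curtain", "mother", "dish",
    "cookie", "water", "hand", "girl", "boy", "jar", "plate", "floor",
    "kid", "thing", "sister", "lady", "kitchen",
)

#: Filler vocabulary with POS tags (word -> tag).
FILLER_WORDS = {
    "the": "DET", "a": "DET", "an": "DET", "is": "VERB", "are": "VERB",
    "was": "VERB", "falling": "VERB", "reaching": "VERB", "washing": "VERB",
    "running": "VERB", "standing": "VERB", "taking": "VERB", "going": "VERB",
    "overflowing": "VERB", "and": "CCONJ", "on": "ADP", "in": "ADP",
    "of": "ADP", "at": "ADP", "from": "ADP", "over": "ADP", "he": "PRON",
    "she": "PRON", "it": "PRON", "they": "PRON", "there": "ADV",
    "here": "ADV", "down": "ADV", "up": "ADV", "while": "SCONJ",
}

#: Fillers whose sampling odds are multiplied for AD speakers (lexical
#: preference channel).
AD_PREFERRED_FILLERS = ("it", "thing", "going", "and", "there")


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic cohort; all class effects additive."""

    n_train_per_class: int = 54
    n_test_per_class: int = 24
    embedding_dim: int = 50
    acoustic_dim: int = 88
    #: per-feature mean offset added to the shifted acoustic columns for AD
    acoustic_shift: float = 0.5
    #: mean positional offset (in words) of scene nouns for AD speakers
    temporal_shift: float = 10.0
    #: odds multiplier for AD-preferred filler words in AD transcripts
    lexical_odds: float = 1.5
    token_count_mean: float = 90.0
    token_count_sd: float = 15.0
    #: probability of a pause after any word
    pause_rate: float = 0.25
    #: log-normal parameters of pause durations (seconds)
    pause_log_mu: float = -1.2
    pause_log_sigma: float = 0.8
    #: log-normal parameters of word durations (seconds)
    word_log_mu: float = -1.1
    word_log_sigma: float = 0.4
    #: number of leading acoustic columns built from token duration
    n_duration_correlated: int = 16
    #: number of acoustic columns receiving the class mean shift
    n_shifted: int = 30
    #: probability a participant mentions any given scene noun
    noun_mention_prob: float = 0.7
    #: standard deviation (words) of noun placement around its target
    position_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.acoustic_dim < 1:
            raise ValueError("dimensions must be positive")
        if self.temporal_shift < 0:
            raise ValueError("temporal shift must be nonnegative")
        if self.n_duration_correlated + self.n_shifted > self.acoustic_dim:
            raise ValueError("acoustic column roles exceed acoustic_dim")

    @property
    def acoustic_columns(self) -> list[str]:
        return [f"egemaps_{i:02d}" for i in range(self.acoustic_dim)]


@dataclass
class Cohort:
    """An in-memory synthetic cohort: records, acoustics, lexicon, labels."""

    train: list[ParticipantRecord]
    test: list[ParticipantRecord]
    acoustic: dict[str, pd.DataFrame]
    lexicon: EmbeddingLexicon
    labels: dict[str, str]
    config: SyntheticConfig

    @property
    def records(self) -> list[ParticipantRecord]:
        return self.train + self.test


def generate_lexicon(
    vocabulary: list[str], dim: int = 50, seed: int = 0
) -> EmbeddingLexicon:
    """Unit-scale Gaussian embedding per word; deterministic per seed."""
    rng = np.random.default_rng(seed)
    return EmbeddingLexicon(
        {word: rng.normal(0.0, 1.0, size=dim) for word in sorted(set(vocabulary))}
    )


def _base_positions(n_nouns: int) -> np.ndarray:
    """Nominal (non-AD) target word index of each scene noun."""
    return np.linspace(8, 60, n_nouns)


def _min_words(cfg: SyntheticConfig) -> int:
    # a transcript must be long enough to host the latest scene noun under
    # the injected shift, else the shift could not be expressed
    latest = _base_positions(len(SCENE_NOUNS)).max()
    return max(40, int(np.ceil(latest + cfg.temporal_shift + 2 * cfg.position_sd + 1)))


def _word_sequence(rng: np.random.Generator, cfg: SyntheticConfig, is_ad: bool) -> list[str]:
    n_words = max(
        _min_words(cfg), int(round(rng.normal(cfg.token_count_mean, cfg.token_count_sd)))
    )
    fillers = list(FILLER_WORDS)
    weights = np.ones(len(fillers))
    if is_ad:
        for i, w in enumerate(fillers):
            if w in AD_PREFERRED_FILLERS:
                weights[i] *= cfg.lexical_odds
    weights /= weights.sum()
    words = list(rng.choice(fillers, size=n_words, p=weights))
    # place scene nouns at class-shifted positions
    taken: set[int] = set()
    base = _base_positions(len(SCENE_NOUNS))
    for i, noun in enumerate(SCENE_NOUNS):
        if rng.random() > cfg.noun_mention_prob:
            continue
        target = base[i] + (cfg.temporal_shift if is_ad else 0.0)
        pos = int(round(rng.normal(target, cfg.position_sd)))
        pos = min(max(pos, 0), n_words - 1)
        while pos in taken:  # nearest free slot to the right, wrapping
            pos = (pos + 1) % n_words
        words[pos] = noun
        taken.add(pos)
    return words


def _tokens_for_words(
    rng: np.random.Generator, cfg: SyntheticConfig, words: list[str]
) -> list[Token]:
    tokens: list[Token] = []
    t = 0.0
    for word in words:
        dur = float(rng.lognormal(cfg.word_log_mu, cfg.word_log_sigma))
        pos = "NOUN" if word in SCENE_NOUNS else FILLER_WORDS.get(word, "X")
        tokens.append(
            Token(
                kind=TokenKind.WORD, surface=word, start=t, end=t + dur,
                lemma=word, pos=pos,
            )
        )
        t += dur
        if rng.random() < cfg.pause_rate:
            pdur = float(rng.lognormal(cfg.pause_log_mu, cfg.pause_log_sigma))
            tokens.append(Token(kind=TokenKind.PAUSE, surface="", start=t, end=t + pdur))
            t += pdur
    return tokens


def _acoustic_rows(
    rng: np.random.Generator, cfg: SyntheticConfig, tokens: list[Token], is_ad: bool
) -> pd.DataFrame:
    n = len(tokens)
    durs = np.array([t.duration for t in tokens])
    dur_z = (durs - durs.mean()) / (durs.std() or 1.0)
    mat = rng.normal(0.0, 1.0, size=(n, cfg.acoustic_dim))
    # leading columns track token duration (removed by the |R| filter)
    for j in range(cfg.n_duration_correlated):
        mat[:, j] = dur_z + 0.5 * rng.normal(size=n)
    # next block carries the class-dependent mean shift
    if is_ad:
        lo = cfg.n_duration_correlated
        mat[:, lo : lo + cfg.n_shifted] += cfg.acoustic_shift
    return pd.DataFrame(mat, columns=cfg.acoustic_columns)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full labeled cohort under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    lexicon = generate_lexicon(
        list(SCENE_NOUNS) + list(FILLER_WORDS),
        dim=config.embedding_dim,
        seed=int(rng.integers(2**31)),
    )
    groups = {
        "train": config.n_train_per_class,
        "test": config.n_test_per_class,
    }
    train: list[ParticipantRecord] = []
    test: list[ParticipantRecord] = []
    acoustic: dict[str, pd.DataFrame] = {}
    labels: dict[str, str] = {}
    for split, n_per_class in groups.items():
        for label in ("AD", "NONAD"):
            is_ad = label == "AD"
            for i in range(n_per_class):
                pid = f"{split}-{label.lower()}-{i:03d}"
                words = _word_sequence(rng, config, is_ad)
                tokens = _tokens_for_words(rng, config, words)
                record = ParticipantRecord(participant_id=pid, label=label, tokens=tokens)
                acoustic[pid] = _acoustic_rows(rng, config, tokens, is_ad)
                labels[pid] = label
                (train if split == "train" else test).append(record)
    return Cohort(
        train=train, test=test, acoustic=acoustic, lexicon=lexicon,
        labels=labels, config=config,
    )


def _chat_text(transcript: list[str]) -> str:
    """CHAT-style participant tier; consecutive repeats collapse to 'w [x n]'."""
    pieces: list[str] = []
    i = 0
    while i < len(transcript):
        j = i
        while j < len(transcript) and transcript[j] == transcript[i]:
            j += 1
        run = j - i
        pieces.append(transcript[i] if run == 1 else f"{transcript[i]} [x {run}]")
        i = j
    lines = []
    for start in range(0, len(pieces), 10):
        chunk = " ".join(pieces[start : start + 10])
        prefix = "*PAR:\t" if start == 0 else "\t"
        lines.append(prefix + chunk)
    if lines:
        lines[-1] += " ."
    return "@Begin\n@Participants:\tPAR Participant\n" + "\n".join(lines) + "\n@End\n"


def write_fixture_bundle(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write the cohort in the exact external formats the readers consume.

    Per participant: a CHAT transcript (``<id>.cha``), an alignment TSV
    (``<id>.tsv``, with lemma/POS columns) and an acoustic CSV
    (``<id>.csv``); plus ``lexicon.txt`` and ``labels.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for record in cohort.records:
        pid = record.participant_id
        cha = directory / f"{pid}.cha"
        cha.write_text(_chat_text(record.transcript))
        align = directory / f"{pid}.tsv"
        write_alignment(record.tokens, align)
        ac = directory / f"{pid}.csv"
        write_acoustic_table(cohort.acoustic[pid], ac)
        written.extend([cha, align, ac])
    lex_path = directory / "lexicon.txt"
    write_lexicon(cohort.lexicon, lex_path)
    labels_path = directory / "labels.csv"
    write_labels(cohort.labels, labels_path)
    written.extend([lex_path, labels_path])
    return written


def read_fixture_bundle(directory: str | Path) -> Cohort:
    """Read a bundle back; train/test membership comes from the id prefix."""
    directory = Path(directory)
    labels = read_labels(directory / "labels.csv")
    lexicon = read_lexicon(directory / "lexicon.txt")
    train: list[ParticipantRecord] = []
    test: list[ParticipantRecord] = []
    acoustic: dict[str, pd.DataFrame] = {}
    for pid, label in labels.items():
        tokens = read_alignment(directory / f"{pid}.tsv")
        table = read_acoustic_table(directory / f"{pid}.csv")
        if len(table) != len(tokens):
            raise ValueError(
                f"{pid}: acoustic rows ({len(table)}) do not match tokens ({len(tokens)})"
            )
        record = ParticipantRecord(participant_id=pid, label=label, tokens=tokens)
        # cross-check the CHAT transcript against the alignment words
        chat_words = read_chat_file(directory / f"{pid}.cha")
        if chat_words != record.transcript:
            raise ValueError(f"{pid}: CHAT transcript disagrees with alignment")
        acoustic[pid] = table
        (train if pid.startswith("train-") else test).append(record)
    return Cohort(
        train=train, test=test, acoustic=acoustic, lexicon=lexicon,
        labels=labels, config=SyntheticConfig(),
    )
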