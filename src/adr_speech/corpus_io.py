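"""Readers, writers and cleaning for the external corpus representations.

Consumes CHAT-style transcripts (DementiaBank participant tier), word-level
forced-alignment tables (token, start, end, with optional lemma/POS columns),
per-token acoustic descriptor tables, GloVe-format embedding lexicons and
participant label files.  Produces clean token sequences ready for fusion.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAUSE_SURFACE = "sp"

#: Pause-encoding symbols: short / medium / long (punctuation-like encoding).
SHORT_PAUSE_SYMBOL = ","
MEDIUM_PAUSE_SYMBOL = "."
LONG_PAUSE_SYMBOL = "..."

#: Pause-duration band edges in seconds.  Pauses below MIN_PAUSE are dropped;
#: [MIN_PAUSE, SHORT_MAX) is short; [SHORT_MAX, MEDIUM_MAX] is medium;
#: anything longer is long.
MIN_PAUSE = 0.05
SHORT_MAX = 0.5
MEDIUM_MAX = 2.0


class TokenKind(Enum):
    WORD = "word"
    PAUSE = "pause"


@dataclass(frozen=True)
class Token:
    """One word or inter-word pause with its time stamps.

    ``surface`` is empty for pauses.  ``lemma`` and ``pos`` are optional
    annotations consumed as input (e.g. precomputed with a tagger).
    """

    kind: TokenKind
    surface: str
    start: float
    end: float
    lemma: str | None = None
    pos: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"token end {self.end} precedes start {self.start}"
            )
        if self.kind is TokenKind.WORD and not self.surface:
            raise ValueError("WORD token requires a non-empty surface")
        if self.kind is TokenKind.PAUSE and self.surface:
            raise ValueError("PAUSE token must have an empty surface")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def is_pause(self) -> bool:
        return self.kind is TokenKind.PAUSE


@dataclass
class ParticipantRecord:
    """A labeled, time-ordered token sequence for one speaker."""

    participant_id: str
    label: str  # "AD", "NONAD" or "UNKNOWN"
    tokens: list[Token] = field(default_factory=list)

    @property
    def transcript(self) -> list[str]:
        """Surface forms of the WORD tokens, in time order."""
        return [t.surface for t in self.tokens if not t.is_pause]

    @property
    def lemmas(self) -> list[str]:
        """Lemmas of the WORD tokens (surface used where lemma is missing)."""
        return [t.lemma or t.surface for t in self.tokens if not t.is_pause]

    def durations(self) -> np.ndarray:
        return np.array([t.duration for t in self.tokens], dtype=float)


class EmbeddingLexicon:
    """Word -> fixed-length real vector map in the GloVe text dialect.

    Lookups are lowercased.  Pauses and out-of-lexicon words map to the
    all-zero vector.
    """

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("lexicon must contain at least one word")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"ragged vector lengths in lexicon: {sorted(dims)}")
        self._vectors = {w.lower(): np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dim = dims.pop()

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._vectors

    def words(self) -> list[str]:
        return sorted(self._vectors)

    def vector(self, token: Token | str) -> np.ndarray:
        """Embedding of a token; zero vector for pauses and unknown words."""
        if isinstance(token, Token):
            if token.is_pause:
                return np.zeros(self.dim)
            word = token.surface
        else:
            word = token
        return self._vectors.get(word.lower(), np.zeros(self.dim)).copy()


class ChatParseError(ValueError):
    """Raised for malformed CHAT annotations, naming the offending line."""


_REPEAT_RE = re.compile(r"(\S+)\s*\[x\s*([^\]]+)\]")
_COMMENT_RE = re.compile(r"\[[^\]]*\]")
_PAREN_PAUSE_RE = re.compile(r"\(\.{1,3}\)")
_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def clean_chat_transcript(raw: str) -> list[str]:
    """Reduce CHAT-annotated utterances to the plain surface-word sequence.

    Handles the DementiaBank constructs: ``w [x n]`` repetition markers are
    expanded to n copies of w; bracketed comments, the pause marks (.) (..)
    (...), the symbols < > /, the unintelligible-speech mark ``xxx`` and all
    punctuation are removed.  Case is preserved.  Cleaning is idempotent.
    """
    words: list[str] = []
    for lineno, line in enumerate(raw.splitlines() or [""], start=1):
        def _expand(m: re.Match) -> str:
            count = m.group(2).strip()
            if not count.isdigit() or int(count) < 1:
                raise ChatParseError(
                    f"line {lineno}: malformed repetition marker "
                    f"'[x {m.group(2)}]' (count must be a positive integer)"
                )
            return " ".join([m.group(1)] * int(count))

        line = _REPEAT_RE.sub(_expand, line)
        line = _COMMENT_RE.sub(" ", line)
        line = _PAREN_PAUSE_RE.sub(" ", line)
        line = line.replace("<", " ").replace(">", " ").replace("/", " ")
        for piece in line.split():
            piece = piece.translate(_PUNCT_TABLE)
            if piece and piece != "xxx":
                words.append(piece)
    return words


def read_chat_file(path: str | Path) -> list[str]:
    """Extract and clean the participant-tier utterances of a CHAT file.

    Only ``*PAR:`` tiers (and their tab-indented continuations) are read;
    investigator tiers and dependent tiers are ignored.
    """
    lines = Path(path).read_text().splitlines()
    kept: list[str] = []
    in_par = False
    for line in lines:
        if line.startswith("*PAR:"):
            kept.append(line[len("*PAR:"):].strip())
            in_par = True
        elif line.startswith(("\t", " ")) and in_par:
            kept.append(line.strip())
        else:
            in_par = False
    return clean_chat_transcript("\n".join(kept))


def read_alignment(path: str | Path) -> list[Token]:
    """Read a forced-alignment table into a Token sequence.

    Expects a tab-delimited file with header columns ``token``, ``start``,
    ``end`` and optional ``lemma`` / ``pos`` annotation columns.  Rows whose
    token is ``sp`` become PAUSE tokens.
    """
    df = pd.read_csv(path, sep="\t", dtype={"token": str})
    missing = {"token", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing alignment columns {sorted(missing)}")
    has_lemma = "lemma" in df.columns
    has_pos = "pos" in df.columns
    tokens: list[Token] = []
    for row in df.itertuples(index=False):
        surface = str(row.token)
        is_pause = surface == PAUSE_SURFACE
        tokens.append(
            Token(
                kind=TokenKind.PAUSE if is_pause else TokenKind.WORD,
                surface="" if is_pause else surface,
                start=float(row.start),
                end=float(row.end),
                lemma=None if is_pause or not has_lemma else str(row.lemma),
                pos=None if is_pause or not has_pos else str(row.pos),
            )
        )
    return tokens


def write_alignment(tokens: list[Token], path: str | Path) -> None:
    rows = [
        {
            "token": PAUSE_SURFACE if t.is_pause else t.surface,
            "start": t.start,
            "end": t.end,
            "lemma": "" if t.lemma is None else t.lemma,
            "pos": "" if t.pos is None else t.pos,
        }
        for t in tokens
    ]
    pd.DataFrame(rows, columns=["token", "start", "end", "lemma", "pos"]).to_csv(
        path, sep="\t", index=False
    )


def encode_pause_tokens(tokens: list[Token]) -> list[str]:
    """Interleave word surfaces with punctuation-like pause symbols.

    Pauses shorter than 50 ms are dropped; [0.05, 0.5) s becomes the short
    symbol, [0.5, 2] s the medium symbol, and longer pauses the long symbol.
    The word subsequence is never altered.
    """
    out: list[str] = []
    for t in tokens:
        if not t.is_pause:
            out.append(t.surface)
            continue
        d = t.duration
        if d < MIN_PAUSE:
            continue
        if d < SHORT_MAX:
            out.append(SHORT_PAUSE_SYMBOL)
        elif d <= MEDIUM_MAX:
            out.append(MEDIUM_PAUSE_SYMBOL)
        else:
            out.append(LONG_PAUSE_SYMBOL)
    return out


def read_lexicon(path: str | Path) -> EmbeddingLexicon:
    """Read a GloVe-text lexicon: one ``word v1 ... vT`` line per word."""
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            word, values = parts[0], parts[1:]
            if not values:
                raise ValueError(f"{path} line {lineno}: no vector values")
            vectors[word] = np.array([float(v) for v in values])
    return EmbeddingLexicon(vectors)


def write_lexicon(lexicon: EmbeddingLexicon, path: str | Path) -> None:
    with open(path, "w") as fh:
        for word in lexicon.words():
            vec = " ".join(repr(float(v)) for v in lexicon.vector(word))
            fh.write(f"{word} {vec}\n")


def read_acoustic_table(path: str | Path) -> pd.DataFrame:
    """Read a per-token acoustic descriptor table (named header columns)."""
    df = pd.read_csv(path)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: acoustic table has no columns")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: acoustic table contains non-finite values")
    return df


def write_acoustic_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a ``participant_id,label`` CSV into a mapping; duplicates reject."""
    df = pd.read_csv(path, dtype=str)
    missing = {"participant_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing label columns {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"{path}: duplicate participant ids {dupes}")
    return dict(zip(df["participant_id"], df["label"]))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"participant_id": list(labels), "label": list(labels.values())}
    ).to_csv(path, index=False)
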