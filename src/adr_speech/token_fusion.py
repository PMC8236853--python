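"""Per-token audio-textual fusion.

Acoustic descriptors that correlate with token duration (|Pearson R| > 0.2
over the pooled training tokens) are dropped to avoid a length bias; the
surviving acoustic block and the word-embedding block are min-max normalised
to [0, 1] separately and concatenated, giving one fused vector per word or
pause (122-dimensional with the canonical 72 acoustic + 50 text layout).

Filtering and normalisation are fit on the training population only and
applied frozen to held-out data; unseen values clip into [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from adr_speech.corpus_io import EmbeddingLexicon, ParticipantRecord

logger = logging.getLogger(__name__)

#: Absolute Pearson-correlation bound above which a descriptor is dropped.
DURATION_CORRELATION_THRESHOLD = 0.2

Modality = str  # "audio" | "text" | "text+audio"
MODALITIES = ("audio", "text", "text+audio")


def filter_duration_correlated(
    acoustic: pd.DataFrame,
    durations: np.ndarray,
    threshold: float = DURATION_CORRELATION_THRESHOLD,
) -> list[str]:
    """Return acoustic columns NOT duration-correlated (|R| <= threshold).

    The criterion is strictly ``|R| > threshold`` for removal, so a column at
    exactly the threshold is retained.  Zero-variance columns have undefined
    correlation and are retained with a warning.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) < 3:
        raise ValueError("need at least 3 tokens to estimate correlations")
    if np.std(durations) == 0:
        raise ValueError("durations have zero variance; correlation undefined")
    retained: list[str] = []
    d = durations - durations.mean()
    d_norm = np.sqrt((d**2).sum())
    for col in acoustic.columns:
        x = acoustic[col].to_numpy(dtype=float)
        xc = x - x.mean()
        x_norm = np.sqrt((xc**2).sum())
        if x_norm == 0:
            logger.warning(
                "column %r has zero variance; correlation undefined, retained",
                col,
            )
            retained.append(col)
            continue
        r = float((xc @ d) / (x_norm * d_norm))
        if abs(r) <= threshold:
            retained.append(col)
    return retained


@dataclass
class NormalizationRanges:
    """Per-coordinate (min, max) fitted separately per modality block."""

    audio_min: np.ndarray
    audio_max: np.ndarray
    text_min: np.ndarray
    text_max: np.ndarray
    fit_population: str = ""

    @property
    def audio_dim(self) -> int:
        return len(self.audio_min)

    @property
    def text_dim(self) -> int:
        return len(self.text_min)

    def to_dict(self) -> dict:
        return {
            "audio_min": self.audio_min.tolist(),
            "audio_max": self.audio_max.tolist(),
            "text_min": self.text_min.tolist(),
            "text_max": self.text_max.tolist(),
            "fit_population": self.fit_population,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationRanges":
        return cls(
            audio_min=np.asarray(d["audio_min"], dtype=float),
            audio_max=np.asarray(d["audio_max"], dtype=float),
            text_min=np.asarray(d["text_min"], dtype=float),
            text_max=np.asarray(d["text_max"], dtype=float),
            fit_population=d.get("fit_population", ""),
        )


def fit_normalization(
    audio_block: np.ndarray,
    text_block: np.ndarray,
    fit_population: str = "",
) -> NormalizationRanges:
    """Fit per-coordinate min-max ranges on the fitting population."""
    audio_block = np.atleast_2d(np.asarray(audio_block, dtype=float))
    text_block = np.atleast_2d(np.asarray(text_block, dtype=float))
    if audio_block.shape[0] == 0 or text_block.shape[0] == 0:
        raise ValueError("fitting population is empty")
    return NormalizationRanges(
        audio_min=audio_block.min(axis=0),
        audio_max=audio_block.max(axis=0),
        text_min=text_block.min(axis=0),
        text_max=text_block.max(axis=0),
        fit_population=fit_population,
    )


def _scale(block: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    # constant coordinates map to 0; out-of-range values clip into [0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0, (block - lo) / np.where(span > 0, span, 1.0), 0.0)
    return np.clip(scaled, 0.0, 1.0)


def apply_normalization(
    audio_block: np.ndarray,
    text_block: np.ndarray,
    ranges: NormalizationRanges,
) -> tuple[np.ndarray, np.ndarray]:
    """Map both blocks into [0, 1] with the fitted ranges."""
    audio_block = np.atleast_2d(np.asarray(audio_block, dtype=float))
    text_block = np.atleast_2d(np.asarray(text_block, dtype=float))
    if audio_block.shape[1] != ranges.audio_dim:
        raise ValueError(
            f"audio dimensionality {audio_block.shape[1]} does not match "
            f"fitted ranges ({ranges.audio_dim})"
        )
    if text_block.shape[1] != ranges.text_dim:
        raise ValueError(
            f"text dimensionality {text_block.shape[1]} does not match "
            f"fitted ranges ({ranges.text_dim})"
        )
    return (
        _scale(audio_block, ranges.audio_min, ranges.audio_max),
        _scale(text_block, ranges.text_min, ranges.text_max),
    )


@dataclass
class TokenEmbeddings:
    """Fused per-token embeddings for one participant.

    ``fused`` is the row-wise concatenation audio_part ⌢ text_part; pauses
    carry an all-zero text part.
    """

    audio_part: np.ndarray  # (n_tokens, A)
    text_part: np.ndarray  # (n_tokens, T)

    @property
    def fused(self) -> np.ndarray:
        return np.hstack([self.audio_part, self.text_part])

    @property
    def n_tokens(self) -> int:
        return self.audio_part.shape[0]

    def for_modality(self, modality: Modality) -> np.ndarray:
        if modality == "audio":
            return self.audio_part
        if modality == "text":
            return self.text_part
        if modality == "text+audio":
            return self.fused
        raise ValueError(f"unknown modality {modality!r}; expected {MODALITIES}")


def raw_blocks(
    participant: ParticipantRecord,
    acoustic: pd.DataFrame,
    lexicon: EmbeddingLexicon,
    retained_columns: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised (audio, text) blocks for one participant's tokens."""
    if len(acoustic) != len(participant.tokens):
        raise ValueError(
            f"{participant.participant_id}: acoustic rows ({len(acoustic)}) "
            f"do not align with tokens ({len(participant.tokens)})"
        )
    audio = acoustic[retained_columns].to_numpy(dtype=float)
    text = np.vstack([lexicon.vector(t) for t in participant.tokens])
    return audio, text


def fuse_tokens(
    participant: ParticipantRecord,
    acoustic: pd.DataFrame,
    lexicon: EmbeddingLexicon,
    retained_columns: list[str],
    ranges: NormalizationRanges,
) -> TokenEmbeddings:
    """One normalised audio-textual embedding per word or pause."""
    audio, text = raw_blocks(participant, acoustic, lexicon, retained_columns)
    audio_n, text_n = apply_normalization(audio, text, ranges)
    return TokenEmbeddings(audio_part=audio_n, text_part=text_n)


def save_fused(
    embeddings: TokenEmbeddings,
    retained_columns: list[str],
    ranges: NormalizationRanges,
    path: str | Path,
) -> None:
    """Persist a fused matrix as TSV with a JSON sidecar of the fit state."""
    path = Path(path)
    np.savetxt(path, embeddings.fused, delimiter="\t")
    sidecar = {
        "retained_columns": retained_columns,
        "text_dim": embeddings.text_part.shape[1],
        "ranges": ranges.to_dict(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
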