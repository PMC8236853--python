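"""Active Data Representation core.

Token-level fused embeddings are clustered with k-means over the pooled
training population; each participant is then summarised by six
fixed-length features:

* **cluster counts** — histogram of tokens per cluster (length k);
* **duration** — per-cluster summed token duration over total duration
  (length k, sums to 1);
* **word/pause embedding sequence** — the participant's token embeddings
  reduced to one dimension with PCA, truncated/zero-padded to 128;
* **centroid embedding** — the visited clusters' centroids projected onto a
  one-dimensional PCA of the participant's centroid sequence, reported per
  cluster index (length k, 0 for unvisited clusters);
* **embedding velocity** — cosine similarity of consecutive token
  embeddings, truncated/zero-padded to 128;
* **centroid velocity** — cosine similarity of the centroids of consecutive
  tokens' clusters, truncated/zero-padded to 128.

Named configurations select subsets of the six for classification.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: Fixed length of the sequence-valued ADR features.
SEQUENCE_LENGTH = 128

#: Default cluster count (selected by grid search over 10..80).
DEFAULT_K = 30

#: Canonical concatenation order of the six ADR features.
FEATURE_ORDER = (
    "counts",
    "duration",
    "word_embedding_seq",
    "centroid_embedding",
    "embedding_velocity",
    "centroid_velocity",
)

#: Named feature configurations.
CONFIGURATION_FEATURES: dict[str, tuple[str, ...]] = {
    "Temporal": ("counts", "duration", "embedding_velocity", "centroid_velocity"),
    "Embedding": ("counts", "duration", "word_embedding_seq", "centroid_embedding"),
    "Centroid": ("counts", "duration", "centroid_embedding", "centroid_velocity"),
    "New": (
        "word_embedding_seq",
        "centroid_embedding",
        "embedding_velocity",
        "centroid_velocity",
    ),
    "All": FEATURE_ORDER,
}


@dataclass
class ADRModel:
    """Fitted token-space clustering: k centroids in canonical order.

    Centroids are sorted by descending assigned-token count on the fitting
    population (ties by first-coordinate value) so that feature indices are
    reproducible across runs.
    """

    k: int
    centroids: np.ndarray  # (k, dim)
    fit_seed: int
    modality: str = "text+audio"

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "k": self.k,
                    "fit_seed": self.fit_seed,
                    "modality": self.modality,
                    "centroids": self.centroids.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ADRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            k=int(d["k"]),
            centroids=np.asarray(d["centroids"], dtype=float),
            fit_seed=int(d["fit_seed"]),
            modality=d.get("modality", "text+audio"),
        )


@dataclass
class FeatureConfiguration:
    """A named ADR feature subset × input modality (± char4grams)."""

    name: str = "All"
    modality: str = "text+audio"
    with_char4grams: bool = False

    def __post_init__(self) -> None:
        if self.name not in CONFIGURATION_FEATURES:
            raise ValueError(
                f"unknown configuration {self.name!r}; "
                f"expected one of {sorted(CONFIGURATION_FEATURES)}"
            )

    @property
    def features(self) -> tuple[str, ...]:
        feats = CONFIGURATION_FEATURES[self.name]
        if self.modality == "text":
            # duration requires audio timing
            feats = tuple(f for f in feats if f != "duration")
        return feats

    def describe(self) -> str:
        suffix = " + char4grams" if self.with_char4grams else ""
        return f"{self.name} ({self.modality}){suffix}"


def fit_adr(
    embeddings: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    modality: str = "text+audio",
) -> ADRModel:
    """k-means over the pooled training token embeddings.

    k-means++ initialisation with 10 restarts and a 300-iteration cap;
    fully seed-controlled.  Centroids are reordered canonically.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2:
        raise ValueError("pooled embeddings must be a 2-D array")
    n = embeddings.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds pooled token count {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence chatter
        labels = km.fit_predict(embeddings)
    centroids = km.cluster_centers_
    counts = np.bincount(labels, minlength=k)
    # canonical order: descending count, then ascending first coordinate
    order = sorted(range(k), key=lambda j: (-counts[j], centroids[j, 0]))
    return ADRModel(k=k, centroids=centroids[order], fit_seed=seed, modality=modality)


def assign_clusters(embeddings: np.ndarray, model: ADRModel) -> np.ndarray:
    """Nearest-centroid (Euclidean) assignment; ties go to the lower index."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    dists = cdist(embeddings, model.centroids)
    return dists.argmin(axis=1)  # argmin returns the first (lowest) index on ties


def cluster_counts(embeddings: np.ndarray, model: ADRModel) -> np.ndarray:
    """Histogram of the participant's tokens over the k clusters."""
    labels = assign_clusters(embeddings, model)
    return np.bincount(labels, minlength=model.k).astype(float)


def duration_feature(
    embeddings: np.ndarray, durations: np.ndarray, model: ADRModel
) -> np.ndarray:
    """Per-cluster summed token duration, normalised by total duration."""
    durations = np.asarray(durations, dtype=float)
    labels = assign_clusters(embeddings, model)
    if len(durations) != len(labels):
        raise ValueError("durations must align 1:1 with tokens")
    sums = np.zeros(model.k)
    np.add.at(sums, labels, durations)
    total = sums.sum()
    if total <= 0:
        return sums
    return sums / total


def _pca_1d(x: np.ndarray) -> np.ndarray:
    """Project rows of x onto their first principal component.

    Sign convention: the component's largest-magnitude loading is positive.
    Degenerate inputs (fewer than 2 rows, or zero variance) yield zeros.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 2 or np.allclose(x, x[0]):
        return np.zeros(x.shape[0])
    pca = PCA(n_components=1)
    proj = pca.fit_transform(x)[:, 0]
    comp = pca.components_[0]
    if comp[np.argmax(np.abs(comp))] < 0:
        proj = -proj
    return proj


def _fix_length(seq: np.ndarray, length: int = SEQUENCE_LENGTH) -> np.ndarray:
    """Truncate to the first `length` entries or zero-pad the tail."""
    seq = np.asarray(seq, dtype=float)
    out = np.zeros(length)
    n = min(len(seq), length)
    out[:n] = seq[:n]
    return out


def word_embedding_seq(embeddings: np.ndarray) -> np.ndarray:
    """Participant token-embedding sequence reduced to 1-D, length 128.

    PCA is fit on the participant's own sequence; participants with fewer
    than 2 tokens yield the all-zero feature.
    """
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if embeddings.shape[0] < 2:
        logger.warning("fewer than 2 tokens; word_embedding_seq is all-zero")
        return np.zeros(SEQUENCE_LENGTH)
    return _fix_length(_pca_1d(embeddings))


def centroid_embedding(embeddings: np.ndarray, model: ADRModel) -> np.ndarray:
    """Visited-cluster centroids projected to 1-D, indexed by cluster.

    The 1-D reduction is fit on the participant's per-token centroid
    sequence; entry j is the projection of centroid j for visited clusters
    and 0 for clusters the participant never enters.
    """
    labels = assign_clusters(embeddings, model)
    centroid_seq = model.centroids[labels]
    if centroid_seq.shape[0] < 2 or np.allclose(centroid_seq, centroid_seq[0]):
        return np.zeros(model.k)
    pca = PCA(n_components=1)
    pca.fit(centroid_seq)
    comp = pca.components_[0]
    if comp[np.argmax(np.abs(comp))] < 0:
        comp = -comp
    out = np.zeros(model.k)
    visited = np.unique(labels)
    out[visited] = (model.centroids[visited] - pca.mean_) @ comp
    return out


def cosine_similarity(t: np.ndarray, e: np.ndarray) -> float:
    """Cosine similarity of two vectors; defined as 0 if either is zero."""
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=float)
    nt = np.linalg.norm(t)
    ne = np.linalg.norm(e)
    if nt == 0 or ne == 0:
        return 0.0
    return float(t @ e / (nt * ne))


def _velocity(seq: np.ndarray) -> np.ndarray:
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    sims = [cosine_similarity(seq[i], seq[i + 1]) for i in range(seq.shape[0] - 1)]
    return _fix_length(np.array(sims))


def embedding_velocity(embeddings: np.ndarray) -> np.ndarray:
    """Cosine similarity of consecutive token embeddings, length 128."""
    return _velocity(embeddings)


def centroid_velocity(embeddings: np.ndarray, model: ADRModel) -> np.ndarray:
    """Cosine similarity of consecutive tokens' cluster centroids, length 128."""
    labels = assign_clusters(embeddings, model)
    return _velocity(model.centroids[labels])


def adr_features(
    embeddings: np.ndarray,
    durations: np.ndarray | None,
    model: ADRModel,
) -> dict[str, np.ndarray]:
    """All six ADR features for one participant.

    ``durations`` may be None for the text-only modality (no duration
    feature is produced then).
    """
    feats = {
        "counts": cluster_counts(embeddings, model),
        "word_embedding_seq": word_embedding_seq(embeddings),
        "centroid_embedding": centroid_embedding(embeddings, model),
        "embedding_velocity": embedding_velocity(embeddings),
        "centroid_velocity": centroid_velocity(embeddings, model),
    }
    if durations is not None:
        feats["duration"] = duration_feature(embeddings, durations, model)
    return feats


def assemble(
    features: dict[str, np.ndarray], configuration: FeatureConfiguration
) -> np.ndarray:
    """Concatenate the configuration's features in the canonical order."""
    parts = []
    for name in FEATURE_ORDER:
        if name in configuration.features:
            if name not in features:
                raise ValueError(f"feature {name!r} required but not computed")
            parts.append(np.asarray(features[name], dtype=float))
    return np.concatenate(parts)


def feature_names(configuration: FeatureConfiguration, k: int = DEFAULT_K) -> list[str]:
    """Column names matching :func:`assemble`'s layout."""
    lengths = {
        "counts": k,
        "duration": k,
        "word_embedding_seq": SEQUENCE_LENGTH,
        "centroid_embedding": k,
        "embedding_velocity": SEQUENCE_LENGTH,
        "centroid_velocity": SEQUENCE_LENGTH,
    }
    prefixes = {
        "counts": "counts",
        "duration": "dur",
        "word_embedding_seq": "wemb",
        "centroid_embedding": "cemb",
        "embedding_velocity": "evel",
        "centroid_velocity": "cvel",
    }
    names: list[str] = []
    for feat in FEATURE_ORDER:
        if feat in configuration.features:
            width = len(str(lengths[feat] - 1))
            names.extend(
                f"{prefixes[feat]}_{i:0{width}d}" for i in range(lengths[feat])
            )
    return names
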