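"""ADR features against independent brute-force recomputations."""

import numpy as np
import pytest

from adr_speech.adr import (
    ADRModel,
    FeatureConfiguration,
    SEQUENCE_LENGTH,
    assemble,
    assign_clusters,
    centroid_embedding,
    centroid_velocity,
    cluster_counts,
    cosine_similarity,
    duration_feature,
    embedding_velocity,
    feature_names,
    fit_adr,
    word_embedding_seq,
)

# ---------------------------------------------------------------- oracles


def brute_force_assign(points, centroids):
    """Exhaustive nearest-centroid assignment, lowest index on ties."""
    labels = []
    for p in points:
        d = [float(np.sum((p - c) ** 2)) for c in centroids]
        labels.append(int(np.argmin(d)))
    return np.array(labels)


def hand_pca_projection(points):
    """1-D PCA by explicit covariance eigendecomposition."""
    x = np.asarray(points, float)
    mu = x.mean(axis=0)
    cov = (x - mu).T @ (x - mu) / (len(x) - 1)
    vals, vecs = np.linalg.eigh(cov)
    comp = vecs[:, np.argmax(vals)]
    if comp[np.argmax(np.abs(comp))] < 0:
        comp = -comp
    return (x - mu) @ comp


def direct_cosine(t, e):
    nt, ne = np.linalg.norm(t), np.linalg.norm(e)
    if nt == 0 or ne == 0:
        return 0.0
    return float(np.dot(t, e) / (nt * ne))


# ---------------------------------------------------------------- fitting


class TestFitADR:
    def test_k1_centroid_is_global_mean(self, rng):
        x = rng.normal(size=(15, 4))
        model = fit_adr(x, k=1, seed=0)
        assert np.allclose(model.centroids[0], x.mean(axis=0))

    def test_two_blobs_recovered(self, rng):
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(10, 0.1, size=(20, 2))
        x = np.vstack([a, b])
        model = fit_adr(x, k=2, seed=0)
        labels = assign_clusters(x, model)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_k_equals_n_zero_within_variance(self, rng):
        x = rng.normal(size=(6, 3))
        model = fit_adr(x, k=6, seed=0)
        labels = assign_clusters(x, model)
        assert sorted(labels) == list(range(6))
        for j, lab in enumerate(labels):
            assert np.allclose(x[j], model.centroids[lab])

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_adr(rng.normal(size=(3, 2)), k=5, seed=0)

    def test_fixed_seed_bit_reproducible(self, rng):
        x = rng.normal(size=(40, 5))
        m1 = fit_adr(x, k=4, seed=7)
        m2 = fit_adr(x, k=4, seed=7)
        assert np.array_equal(m1.centroids, m2.centroids)

    def test_json_round_trip(self, rng, tmp_path):
        model = fit_adr(rng.normal(size=(20, 3)), k=3, seed=1)
        model.to_json(tmp_path / "m.json")
        back = ADRModel.from_json(tmp_path / "m.json")
        assert back.k == 3 and np.allclose(back.centroids, model.centroids)


# ---------------------------------------------------------------- features


class TestClusterCounts:
    def test_all_tokens_at_one_centroid(self):
        model = ADRModel(k=3, centroids=np.array([[0.0], [5.0], [9.0]]), fit_seed=0)
        counts = cluster_counts(np.zeros((7, 1)), model)
        assert np.array_equal(counts, [7, 0, 0])

    def test_conservation(self, rng):
        model = fit_adr(rng.normal(size=(30, 3)), k=4, seed=0)
        x = rng.normal(size=(11, 3))
        assert cluster_counts(x, model).sum() == 11

    def test_matches_bruteforce(self, rng):
        model = fit_adr(rng.normal(size=(12, 2)), k=2, seed=0)
        x = rng.normal(size=(5, 2))
        expected = np.bincount(brute_force_assign(x, model.centroids), minlength=2)
        assert np.array_equal(cluster_counts(x, model), expected)

    def test_tie_breaks_to_lower_index(self):
        model = ADRModel(k=2, centroids=np.array([[-1.0], [1.0]]), fit_seed=0)
        assert assign_clusters(np.array([[0.0]]), model)[0] == 0


class TestDurationFeature:
    def test_single_token_indicator(self):
        model = ADRModel(k=3, centroids=np.array([[0.0], [5.0], [9.0]]), fit_seed=0)
        out = duration_feature(np.array([[5.1]]), np.array([0.37]), model)
        assert np.allclose(out, [0, 1, 0])

    def test_hand_arithmetic(self):
        model = ADRModel(k=2, centroids=np.array([[0.0], [10.0]]), fit_seed=0)
        out = duration_feature(
            np.array([[0.0], [10.0]]), np.array([1.0, 3.0]), model
        )
        assert np.allclose(out, [0.25, 0.75])

    def test_sums_to_one(self, rng):
        model = fit_adr(rng.normal(size=(20, 2)), k=3, seed=0)
        out = duration_feature(
            rng.normal(size=(9, 2)), rng.uniform(0.1, 1.0, size=9), model
        )
        assert out.sum() == pytest.approx(1.0)


class TestWordEmbeddingSeq:
    def test_length_and_padding(self, rng):
        x = rng.normal(size=(40, 6))
        out = word_embedding_seq(x)
        assert out.shape == (SEQUENCE_LENGTH,)
        assert np.allclose(out[40:], 0.0)
        assert not np.allclose(out[:40], 0.0)

    def test_hand_pca_example(self):
        x = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
        out = word_embedding_seq(x)
        d = np.sqrt(5.0)
        assert np.allclose(out[:3], [-d, 0.0, d])

    def test_single_token_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = word_embedding_seq(np.ones((1, 4)))
        assert np.allclose(out, 0.0)

    def test_truncates_to_first_128(self, rng):
        x = rng.normal(size=(150, 3))
        out = word_embedding_seq(x)
        proj = hand_pca_projection(x)
        assert np.allclose(out, proj[:SEQUENCE_LENGTH])


class TestCentroidEmbedding:
    def test_length_is_k(self, rng):
        model = fit_adr(rng.normal(size=(30, 3)), k=5, seed=0)
        out = centroid_embedding(rng.normal(size=(8, 3)), model)
        assert out.shape == (5,)

    def test_single_visited_cluster_all_zero(self):
        model = ADRModel(
            k=5, centroids=np.vstack([np.full((1, 2), 10 * j) for j in range(5)]),
            fit_seed=0,
        )
        x = np.full((4, 2), 30.0)  # all tokens in cluster 3
        out = centroid_embedding(x, model)
        # constant centroid sequence: no variance, feature degenerates to zeros
        assert np.allclose(out, 0.0)

    def test_balanced_two_cluster_symmetry(self):
        model = ADRModel(k=2, centroids=np.array([[0.0, 0.0], [3.0, 4.0]]), fit_seed=0)
        x = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0], [3.0, 4.0]])
        out = centroid_embedding(x, model)
        # balanced visits centre the projection: values symmetric about 0
        assert out[0] == pytest.approx(-out[1])
        assert abs(out[0]) == pytest.approx(2.5)  # half the centroid distance


class TestVelocities:
    def test_identical_vectors_similarity_one(self):
        x = np.vstack([np.ones(4), np.ones(4)])
        assert embedding_velocity(x)[0] == pytest.approx(1.0)

    def test_orthogonal_vectors_zero(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert embedding_velocity(x)[0] == pytest.approx(0.0)

    def test_hand_cosine(self):
        x = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert embedding_velocity(x)[0] == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_convention(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    def test_centroid_velocity_same_cluster_is_one(self, rng):
        model = fit_adr(rng.normal(size=(20, 2)), k=1, seed=0)
        x = rng.normal(size=(6, 2))
        out = centroid_velocity(x, model)
        assert np.allclose(out[:5], 1.0)

    def test_centroid_velocity_matches_direct(self, rng):
        model = ADRModel(k=2, centroids=np.array([[1.0, 0.0], [0.0, 1.0]]), fit_seed=0)
        x = np.array([[0.9, 0.0], [0.1, 1.1], [0.0, 0.8], [1.2, 0.1]])
        labels = brute_force_assign(x, model.centroids)
        expected = [
            direct_cosine(model.centroids[labels[i]], model.centroids[labels[i + 1]])
            for i in range(3)
        ]
        assert np.allclose(centroid_velocity(x, model)[:3], expected)

    def test_velocity_prefix_length(self, rng):
        x = rng.normal(size=(10, 3)) + 5  # offset avoids zero vectors
        out = embedding_velocity(x)
        assert not np.any(out[:9] == 0.0)
        assert np.allclose(out[9:], 0.0)


class TestAssemble:
    @pytest.mark.parametrize(
        "name, modality, expected_len",
        [
            ("All", "text+audio", 30 + 30 + 128 + 30 + 128 + 128),   # 474
            ("Temporal", "text", 30 + 128 + 128),                    # 286
            ("New", "text+audio", 128 + 30 + 128 + 128),             # 414
            ("Embedding", "text+audio", 30 + 30 + 128 + 30),         # 316
            ("Centroid", "audio", 30 + 30 + 30 + 128),               # 218
        ],
    )
    def test_configuration_lengths(self, name, modality, expected_len):
        k = 30
        feats = {
            "counts": np.zeros(k),
            "duration": np.zeros(k),
            "word_embedding_seq": np.zeros(128),
            "centroid_embedding": np.zeros(k),
            "embedding_velocity": np.zeros(128),
            "centroid_velocity": np.zeros(128),
        }
        cfg = FeatureConfiguration(name=name, modality=modality)
        assert len(assemble(feats, cfg)) == expected_len
        assert len(feature_names(cfg, k=k)) == expected_len

    def test_unknown_configuration_rejected(self):
        with pytest.raises(ValueError, match="unknown configuration"):
            FeatureConfiguration(name="Bogus")

    def test_text_modality_drops_duration(self):
        cfg = FeatureConfiguration(name="All", modality="text")
        assert "duration" not in cfg.features
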