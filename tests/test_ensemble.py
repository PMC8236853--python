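"""Eq.-style accuracy, majority voting, LOOCV ensembles, late fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adr_speech.ensemble import (
    ConfusionCounts,
    EnsembleSpec,
    PredictionSet,
    accuracy,
    confusion_counts,
    grid_search,
    late_fusion,
    loocv_majority,
    majority_label,
    predict_majority,
    train_ensemble,
)


class TestAccuracy:
    @pytest.mark.parametrize(
        "tp, tn, fp, fn, expected",
        [
            (4, 4, 0, 0, 1.0),
            (1, 1, 1, 1, 0.5),
            (3, 2, 1, 2, 0.625),
        ],
    )
    def test_confusion_table_examples(self, tp, tn, fp, fn, expected):
        assert accuracy(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)) == expected

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_class_symmetry(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        a = accuracy(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        b = accuracy(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert a == b

    def test_counts_from_labels(self):
        y_true = ["AD", "AD", "NONAD", "NONAD", "AD"]
        y_pred = ["AD", "NONAD", "NONAD", "AD", "AD"]
        c = confusion_counts(y_true, y_pred)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)
        assert c.total == 5


class TestMajorityVoting:
    def test_strict_majority(self):
        votes = ["AD"] * 26 + ["NONAD"] * 24
        assert majority_label(votes) == "AD"

    def test_exact_tie_resolves_to_nonad(self):
        votes = ["AD"] * 25 + ["NONAD"] * 25
        assert majority_label(votes) == "NONAD"

    def test_unanimous(self):
        assert majority_label(["NONAD"] * 7) == "NONAD"

    def test_voting_idempotent(self):
        # voting over n copies of one prediction set returns its labels
        base = PredictionSet(
            instance_ids=["a", "b"],
            votes=np.array([["AD"], ["NONAD"]], dtype=object),
        )
        stacked = PredictionSet(
            instance_ids=["a", "b"],
            votes=np.array([["AD"] * 5, ["NONAD"] * 5], dtype=object),
        )
        assert stacked.majority == base.majority


def separable_data(rng, n_per_class=6, gap=8.0):
    X = np.vstack(
        [rng.normal(0, 1, (n_per_class, 4)), rng.normal(gap, 1, (n_per_class, 4))]
    )
    y = np.array(["AD"] * n_per_class + ["NONAD"] * n_per_class, dtype=object)
    return X, y


class TestLoocv:
    def test_single_member_is_plain_loocv(self, rng):
        X, y = separable_data(rng)
        pset, acc = loocv_majority(X, y, EnsembleSpec(seeds=(0,)))
        assert pset.votes.shape == (12, 1)
        assert pset.majority == list(pset.votes[:, 0])

    def test_perfectly_separable(self, rng):
        X, y = separable_data(rng)
        _, acc = loocv_majority(X, y, EnsembleSpec(seeds=(0, 1, 2)))
        assert acc == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(size=(24, 6))
        y = np.array(["AD", "NONAD"] * 12, dtype=object)
        _, acc = loocv_majority(X, y, EnsembleSpec(seeds=tuple(range(5))))
        # binomial 95% interval around 0.5 for n=24
        half = 1.96 * np.sqrt(0.25 / 24)
        assert abs(acc - 0.5) <= half + 1e-12

    def test_too_few_per_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["AD", "AD", "NONAD"], dtype=object)
        with pytest.raises(ValueError, match="at least 2"):
            loocv_majority(X, y, EnsembleSpec(seeds=(0,)))

    def test_reproducible_end_to_end(self, rng):
        X, y = separable_data(rng, gap=1.0)
        spec = EnsembleSpec(seeds=(0, 1, 2))
        p1, a1 = loocv_majority(X, y, spec)
        p2, a2 = loocv_majority(X, y, spec)
        assert a1 == a2 and np.array_equal(p1.votes, p2.votes)


class TestEnsembleSpec:
    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            EnsembleSpec(seeds=(1, 1, 2))

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            EnsembleSpec(learner="mystery")

    @pytest.mark.parametrize(
        "learner", ["random_forest", "xgboost", "svm", "logistic_regression", "lda"]
    )
    def test_all_learners_train_and_predict(self, learner, rng):
        X, y = separable_data(rng)
        members = train_ensemble(X, y, EnsembleSpec(learner=learner, seeds=(0, 1)))
        pset = predict_majority(members, X)
        assert accuracy(confusion_counts(y, pset.majority)) == 1.0


class TestTrainPredict:
    def test_unanimous_members_match_any_member(self, rng):
        X, y = separable_data(rng)
        members = train_ensemble(X, y, EnsembleSpec(seeds=(0, 1, 2)))
        pset = predict_majority(members, X)
        assert np.all(pset.votes == np.asarray(pset.majority, dtype=object)[:, None])

    def test_prediction_frame_columns(self, rng):
        X, y = separable_data(rng)
        members = train_ensemble(X, y, EnsembleSpec(seeds=(0,)))
        df = predict_majority(members, X).to_frame(y)
        assert list(df.columns) == [
            "participant_id", "ad_votes", "nonad_votes", "majority_label", "true_label",
        ]


class TestLateFusion:
    def _pset(self, labels):
        return PredictionSet(
            instance_ids=[str(i) for i in range(len(labels))],
            votes=np.array([[lab] for lab in labels], dtype=object),
        )

    def test_two_of_three(self):
        fused = late_fusion([self._pset(["AD"]), self._pset(["AD"]), self._pset(["NONAD"])])
        assert fused.majority == ["AD"]

    def test_unanimous(self):
        fused = late_fusion([self._pset(["NONAD"])] * 3)
        assert fused.majority == ["NONAD"]

    def test_requires_exactly_three(self):
        with pytest.raises(ValueError, match="top-3"):
            late_fusion([self._pset(["AD"])] * 2)

    def test_mismatched_instances_rejected(self):
        a = self._pset(["AD", "NONAD"])
        b = PredictionSet(instance_ids=["9", "8"], votes=np.array([["AD"], ["AD"]], dtype=object))
        with pytest.raises(ValueError, match="different instances"):
            late_fusion([a, a, b])


class TestGridSearch:
    def test_single_candidate_returned(self, rng):
        X, y = separable_data(rng)
        table = grid_search(lambda k: X, y, k_values=(10,), learners=("lda",), n_seeds=2)
        assert len(table) == 1
        assert table.loc[0, "learner"] == "lda" and table.loc[0, "k"] == 10

    def test_deterministic_learner_zero_variance(self, rng):
        X, y = separable_data(rng, gap=1.0)
        table = grid_search(lambda k: X, y, k_values=(10,), learners=("lda",), n_seeds=3)
        assert table.loc[0, "std_accuracy"] == 0.0

    def test_informative_representation_wins(self, rng):
        # features_for_k: small k yields the class signal, large k pure noise
        n = 16
        y = np.array(["AD"] * (n // 2) + ["NONAD"] * (n // 2), dtype=object)
        signal = np.vstack([rng.normal(0, 1, (n // 2, 3)), rng.normal(6, 1, (n // 2, 3))])
        noise = rng.normal(size=(n, 3))

        def features_for_k(k):
            return signal if k == 10 else noise

        table = grid_search(
            features_for_k, y, k_values=(10, 80), learners=("random_forest",), n_seeds=2
        )
        assert table.loc[0, "k"] == 10
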