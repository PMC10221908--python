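"""Scoring formulas, dataset splitting, classifier and Siamese contracts."""

import numpy as np
import pytest

from tssci import scoring
from tssci.errors import DegenerateTrainingError, MissingClassError


class TestContrastiveLoss:
    @pytest.mark.parametrize(
        "dw, y, m, expected",
        [
            (0.0, 0, 1.0, 0.0),    # similar pair at zero distance
            (1.0, 1, 1.0, 0.0),    # dissimilar pair at the margin
            (2.5, 1, 1.0, 0.0),    # dissimilar pair beyond the margin
            (1.0, 0, 1.0, 0.5),    # similar pair at unit distance
            (0.4, 1, 1.0, 0.18),   # dissimilar pair inside the margin
        ],
    )
    def test_values(self, dw, y, m, expected):
        assert scoring.contrastive_loss(dw, y, m) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            scoring.contrastive_loss(-1.0, 0)


class TestSimilarity:
    def test_identical_embeddings_score_one(self):
        t = np.array([3.0, 4.0])
        assert scoring.similarity_s(t, t) == pytest.approx(1.0)

    def test_zero_vector_scores_zero(self):
        t2 = np.array([3.0, 4.0])
        assert scoring.similarity_s(np.zeros(2), t2) == pytest.approx(0.0)

    def test_double_reference_scores_zero(self):
        t2 = np.array([1.0, 2.0, 2.0])
        assert scoring.similarity_s(2 * t2, t2) == pytest.approx(0.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            scoring.similarity_s(np.ones(3), np.zeros(3))


class TestEmpiricalScore:
    def test_cap_applies_below_threshold_distance(self):
        assert scoring.empirical_score(10.0) == 100.0

    def test_inverse_scaling(self):
        assert scoring.empirical_score(60.0) == pytest.approx(50.0)
        assert scoring.empirical_score(300.0) == pytest.approx(10.0)

    def test_monotone_nonincreasing(self):
        distances = np.linspace(0.1, 500, 200)
        scores = [scoring.empirical_score(d) for d in distances]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_zero_distance_is_perfect(self):
        assert scoring.empirical_score(0.0) == 100.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            scoring.empirical_score(-1.0)

    def test_range_is_zero_to_cap(self):
        config = scoring.ScoreConfig(alpha_scale=30.0, cap=100.0)
        for d in (1e-9, 1.0, 30.0, 1e9):
            assert 0.0 <= scoring.empirical_score(d, config) <= 100.0


class _Labeled:
    def __init__(self, label):
        self.label = label


class TestSplitDataset:
    def test_canonical_80_20_counts(self):
        items = [_Labeled(lab) for lab in ("AFR", "ARO", "LBE", "LFC", "SLL", "TRO") for _ in range(334)]
        train, evaluation = scoring.split_dataset(items, 0.8, seed=1)
        assert (len(train), len(evaluation)) == (1603, 401)

    def test_small_split_and_partition(self):
        items = [_Labeled("A") for _ in range(10)]
        train, evaluation = scoring.split_dataset(items, 0.8, seed=0)
        assert (len(train), len(evaluation)) == (8, 2)
        assert {id(x) for x in train} | {id(x) for x in evaluation} == {id(x) for x in items}
        assert not ({id(x) for x in train} & {id(x) for x in evaluation})

    def test_stratification_balances_classes(self):
        items = [_Labeled("A")] * 50 + [_Labeled("B")] * 50
        train, _ = scoring.split_dataset(items, 0.8, seed=2)
        labels = [x.label for x in train]
        assert labels.count("A") == labels.count("B") == 40

    def test_deterministic(self):
        items = [_Labeled(lab) for lab in "ABC" * 10]
        a = scoring.split_dataset(items, 0.8, seed=5)
        b = scoring.split_dataset(items, 0.8, seed=5)
        assert [id(x) for x in a[0]] == [id(x) for x in b[0]]

    def test_unlabeled_plain_shuffle(self):
        train, evaluation = scoring.split_dataset(list(range(10)), 0.8, seed=0, labels=[None] * 10)
        assert len(train) == 8 and len(evaluation) == 2


class TestClassifierContract:
    def test_probabilities_sum_to_one(self, trained_classifier, classifier_dataset):
        proba = trained_classifier.predict_proba(classifier_dataset[0])
        assert proba.shape == (6,)
        assert proba.sum() == pytest.approx(1.0, abs=1e-6)

    def test_separable_two_class_data_reaches_full_accuracy(self, small_dataset):
        two = [im for im in small_dataset if im.label in ("AFR", "TRO")]
        clf = scoring.train_classifier(two, seed=0, max_iter=200)
        predicted = clf.predict_label(two)
        assert np.mean([p == im.label for p, im in zip(predicted, two)]) == 1.0

    def test_single_class_rejected(self, small_dataset):
        one = [im for im in small_dataset if im.label == "AFR"]
        with pytest.raises(DegenerateTrainingError):
            scoring.train_classifier(one)

    def test_deterministic_predictions(self, small_dataset):
        a = scoring.train_classifier(small_dataset, seed=3, max_iter=30)
        b = scoring.train_classifier(small_dataset, seed=3, max_iter=30)
        imgs = small_dataset[:10]
        assert a.predict_label(imgs) == b.predict_label(imgs)

    def test_save_load(self, small_dataset, tmp_path):
        clf = scoring.train_classifier(small_dataset, seed=0, max_iter=30)
        clf.save(tmp_path / "clf.joblib")
        loaded = scoring.TSSCIClassifier.load(tmp_path / "clf.joblib")
        image = small_dataset[0]
        np.testing.assert_allclose(
            loaded.predict_proba(image), clf.predict_proba(image)
        )


class TestContrastiveEmbedder:
    def test_training_separates_classes(self, small_dataset):
        embedder = scoring.ContrastiveEmbedder(
            dim_out=16, margin=100.0, learning_rate=1e-3, seed=0
        )
        embedder.fit(small_dataset, epochs=4, pairs_per_epoch=300)
        by_class = {}
        for im in small_dataset:
            by_class.setdefault(im.label, []).append(embedder.embed(im))
        same, cross = [], []
        labels = sorted(by_class)
        for i, la in enumerate(labels):
            e = by_class[la]
            same += [np.linalg.norm(a - b) for a, b in zip(e[:-1:2], e[1::2])]
            for lb in labels[i + 1 :]:
                cross += [
                    np.linalg.norm(a - b) for a, b in zip(e[:5], by_class[lb][:5])
                ]
        assert np.mean(same) < np.mean(cross)

    def test_unfitted_embedder_rejected(self, small_dataset):
        with pytest.raises(RuntimeError):
            scoring.ContrastiveEmbedder().embed(small_dataset[0])

    def test_pair_head_outputs_probability(self):
        head = scoring.PairSimilarityHead(dim=8, seed=0)
        value = head(np.ones(8), np.zeros(8))
        assert 0.0 < value < 1.0


class TestScoreMatrix:
    def test_identical_subjects_score_diagonal_100(self, small_dataset):
        refs = {}
        for im in small_dataset:
            refs.setdefault(im.label, im)
        subjects = list(refs.values())
        table = scoring.score_matrix(refs, subjects)
        for label in scoring.CLASS_LABELS:
            assert table.loc[label, label] == pytest.approx(100.0)

    def test_shape_and_range(self, small_dataset):
        refs = {}
        for im in small_dataset:
            refs.setdefault(im.label, im)
        table = scoring.score_matrix(refs, small_dataset)
        assert table.shape == (6, 6)
        assert (table.values >= 0).all() and (table.values <= 100).all()

    def test_missing_class_rejected(self, small_dataset):
        refs = {im.label: im for im in small_dataset if im.label != "TRO"}
        with pytest.raises(MissingClassError):
            scoring.score_matrix(refs, small_dataset)
        refs = {}
        for im in small_dataset:
            refs.setdefault(im.label, im)
        subjects = [im for im in small_dataset if im.label != "LBE"]
        with pytest.raises(MissingClassError):
            scoring.score_matrix(refs, subjects)
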