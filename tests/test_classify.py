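"""Feature extraction and the few-shot balanced-annotation classifier."""

import math

import numpy as np
import pandas as pd
import pytest

from tumorfrac.classify import (
    FEATURE_NAMES,
    AnnotationSet,
    BalanceError,
    DegeneratePolygonError,
    classify_detections,
    extract_features,
    learning_curve,
    train_classifier,
)
from tumorfrac.detect import Detection
from tumorfrac.synthscene import IGNORE, NON_NEOPLASTIC, TUMOR


def _ring_from(fn, n=64):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    ring = np.column_stack(fn(t))
    return np.vstack([ring, ring[:1]])


def _detection(ring):
    return Detection(id="d0", centroid=tuple(ring[:-1].mean(axis=0)), polygon=ring,
                     area_um2=1.0)


@pytest.fixture(scope="module")
def white_tile():
    return np.full((128, 128, 3), 255, dtype=np.uint8)


class TestExtractFeatures:
    def test_circle_circularity(self, white_tile):
        ring = _ring_from(lambda t: (64 + 20 * np.cos(t), 64 + 20 * np.sin(t)))
        feats = extract_features(white_tile, _detection(ring), mpp=1.0)
        assert feats["circularity"] == pytest.approx(1.0, rel=0.02)
        assert feats["eccentricity"] < 0.3

    def test_two_to_one_ellipse_eccentricity(self, white_tile):
        ring = _ring_from(lambda t: (64 + 40 * np.cos(t), 64 + 20 * np.sin(t)))
        feats = extract_features(white_tile, _detection(ring), mpp=1.0)
        assert feats["eccentricity"] == pytest.approx(math.sqrt(1 - 0.25), rel=0.02)

    def test_degenerate_polygon_errors(self, white_tile):
        ring = _ring_from(lambda t: (10 + 0.2 * np.cos(t), 10 + 0.2 * np.sin(t)))
        with pytest.raises(DegeneratePolygonError):
            extract_features(white_tile, _detection(ring), mpp=1.0)

    def test_populations_separate_in_generator_direction(self, features, truth_labels):
        grouped = features.loc[truth_labels.index].groupby(truth_labels)["area_um2"]
        means = grouped.mean()
        assert means[TUMOR] > means[NON_NEOPLASTIC]
        # OD separates artifacts from nuclei
        od = features.loc[truth_labels.index].groupby(truth_labels)["mean_od_h"].mean()
        assert od[IGNORE] < min(od[TUMOR], od[NON_NEOPLASTIC])


class TestAnnotationProtocol:
    def test_unbalanced_annotations_rejected(self):
        labels = tuple(
            [(f"t{i}", TUMOR) for i in range(6)] + [(f"n{i}", NON_NEOPLASTIC) for i in range(5)]
        )
        with pytest.raises(BalanceError):
            AnnotationSet(labels)

    def test_cutoff_enforced(self):
        labels = tuple(
            [(f"t{i}", TUMOR) for i in range(11)]
            + [(f"n{i}", NON_NEOPLASTIC) for i in range(11)]
        )
        with pytest.raises(ValueError, match="max_per_class"):
            AnnotationSet(labels)

    def test_ignore_exempt_from_balance(self):
        labels = tuple(
            [(f"t{i}", TUMOR) for i in range(5)]
            + [(f"n{i}", NON_NEOPLASTIC) for i in range(5)]
            + [("a0", IGNORE)]
        )
        assert AnnotationSet(labels).class_counts()[IGNORE] == 1


def _balanced_annotations(truth_labels, n, n_ignore, seed=0):
    rng = np.random.default_rng(seed)
    chosen = []
    for cls, k in ((TUMOR, n), (NON_NEOPLASTIC, n), (IGNORE, n_ignore)):
        ids = truth_labels.index[truth_labels == cls]
        chosen += [(i, cls) for i in rng.choice(ids, size=k, replace=False)]
    return AnnotationSet(tuple(chosen))


class TestTrainAndClassify:
    def test_training_accuracy_perfect_on_separable(self, features, truth_labels):
        ann = _balanced_annotations(truth_labels, 5, 5)
        clf = train_classifier(features, ann, seed=1)
        ids = [i for i, _ in ann.labels]
        pred = classify_detections(clf, features.loc[ids])
        expected = pd.Series(dict(ann.labels)).loc[ids]
        assert pred["label"].loc[ids].equals(expected)

    def test_determinism_across_runs(self, features, truth_labels):
        ann = _balanced_annotations(truth_labels, 5, 5)
        p1 = classify_detections(train_classifier(features, ann, seed=3), features)
        p2 = classify_detections(train_classifier(features, ann, seed=3), features)
        assert p1.equals(p2)

    def test_few_shot_accuracy(self, features, truth_labels):
        """5+5+5 annotations reach >= 90% accuracy vs ground truth."""
        ann = _balanced_annotations(truth_labels, 5, 5)
        clf = train_classifier(features, ann, seed=1)
        pred = classify_detections(clf, features)
        acc = (pred["label"].loc[truth_labels.index] == truth_labels).mean()
        assert acc >= 0.9

    def test_probabilities_normalized(self, features, truth_labels):
        clf = train_classifier(features, _balanced_annotations(truth_labels, 5, 5), seed=1)
        pred = classify_detections(clf, features)
        pcols = [c for c in pred.columns if c.startswith("p_")]
        assert np.allclose(pred[pcols].sum(axis=1), 1.0, atol=1e-9)
        assert (pred[pcols] >= 0).all().all()

    def test_prediction_order_invariant(self, features, truth_labels):
        clf = train_classifier(features, _balanced_annotations(truth_labels, 5, 5), seed=1)
        shuffled = features.sample(frac=1.0, random_state=0)
        a = classify_detections(clf, features)["label"]
        b = classify_detections(clf, shuffled)["label"].reindex(features.index)
        assert a.equals(b)

    def test_empty_detection_list(self, features, truth_labels):
        clf = train_classifier(features, _balanced_annotations(truth_labels, 5, 5), seed=1)
        out = classify_detections(clf, features.iloc[:0])
        assert out.empty

    def test_feature_mismatch_errors(self, features, truth_labels):
        clf = train_classifier(features, _balanced_annotations(truth_labels, 5, 5), seed=1)
        with pytest.raises(ValueError, match="feature mismatch"):
            classify_detections(clf, features[list(FEATURE_NAMES[:4])])

    def test_save_load_round_trip(self, features, truth_labels, tmp_path):
        from tumorfrac.classify import TrainedClassifier

        clf = train_classifier(features, _balanced_annotations(truth_labels, 5, 5), seed=1)
        clf.save(tmp_path / "clf.joblib")
        again = TrainedClassifier.load(tmp_path / "clf.joblib")
        assert classify_detections(again, features).equals(
            classify_detections(clf, features)
        )


class TestLearningCurve:
    def test_plateau_non_degradation(self, features, truth_labels):
        feats = features.loc[truth_labels.index]
        table = learning_curve(feats, truth_labels, [5, 10], reps=3, seed=0)
        acc = dict(zip(table["n_per_class"], table["mean_accuracy"]))
        assert acc[10] >= acc[5] - 0.02

    def test_deterministic(self, features, truth_labels):
        feats = features.loc[truth_labels.index]
        a = learning_curve(feats, truth_labels, [5], reps=1, seed=4)
        b = learning_curve(feats, truth_labels, [5], reps=1, seed=4)
        assert a.equals(b)

    def test_budget_exceeding_population_errors(self, features, truth_labels):
        feats = features.loc[truth_labels.index]
        with pytest.raises(ValueError, match="annotations"):
            learning_curve(feats, truth_labels, [1000], reps=1, seed=0)
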