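"""Few-shot morphometric classification of detected nuclei.

Each detection is summarized by eight morphometric/intensity features and
assigned to Tumor, Non-neoplastic, or Ignore by a randomized decision-tree
ensemble trained on a handful of balanced manual annotations: equal Tumor
and Non-neoplastic exemplar counts (five each by default, ten at most),
with the Ignore class free to have 0-10 exemplars. The protocol emulates a
per-slide object classifier trained interactively by a pathologist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage import measure
from skimage.draw import polygon as draw_polygon
from sklearn.ensemble import RandomForestClassifier

from .detect import Detection, deconvolve_stains
from .synthscene import CLASS_NAMES, IGNORE, NON_NEOPLASTIC, TUMOR

__all__ = [
    "FEATURE_NAMES",
    "AnnotationSet",
    "BalanceError",
    "DegeneratePolygonError",
    "TrainedClassifier",
    "extract_features",
    "extract_feature_table",
    "train_classifier",
    "classify_detections",
    "learning_curve",
]

FEATURE_NAMES = (
    "area_um2",
    "perimeter_um",
    "circularity",
    "eccentricity",
    "solidity",
    "mean_od_h",
    "sd_od_h",
    "mean_od_e",
)


class DegeneratePolygonError(ValueError):
    """Polygon covers less than one pixel; no features can be measured."""


class BalanceError(ValueError):
    """Tumor / Non-neoplastic annotation counts differ (protocol violation)."""


@dataclass(frozen=True)
class AnnotationSet:
    """Manual annotations: (detection id, label) pairs under the balance rule.

    Tumor and Non-neoplastic counts must be equal and no class may exceed
    ``max_per_class`` (annotation efficacy plateaus around ten exemplars
    per class, so more are never required). Ignore is exempt from the
    balance requirement.
    """

    labels: tuple[tuple[str, str], ...]
    max_per_class: int = 10

    def __post_init__(self) -> None:
        counts = self.class_counts()
        unknown = set(counts) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown annotation labels: {sorted(unknown)}")
        if counts.get(TUMOR, 0) != counts.get(NON_NEOPLASTIC, 0):
            raise BalanceError(
                f"annotation protocol requires equal Tumor/Non-neoplastic "
                f"counts, got {counts.get(TUMOR, 0)} vs "
                f"{counts.get(NON_NEOPLASTIC, 0)}"
            )
        for cls, n in counts.items():
            if n > self.max_per_class:
                raise ValueError(
                    f"{cls}: {n} annotations exceed max_per_class="
                    f"{self.max_per_class}"
                )

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, label in self.labels:
            counts[label] = counts.get(label, 0) + 1
        return counts


@dataclass
class TrainedClassifier:
    """A fitted randomized decision-tree ensemble with its metadata."""

    model: RandomForestClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    training_counts: dict[str, int]
    seed: int

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, TrainedClassifier):
            raise TypeError(f"{path} does not contain a TrainedClassifier")
        return obj


def _polygon_pixels(ring: np.ndarray, shape: tuple[int, int]):
    return draw_polygon(ring[:, 1], ring[:, 0], shape=shape)


def extract_features(
    rgb_image: np.ndarray,
    detection: Detection,
    mpp: float = 0.4416,
    _od: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, float]:
    """Morphometric and intensity features of one detection.

    Geometry comes from the polygon (areas/perimeters in microns via
    ``mpp``); intensity statistics are taken over the hematoxylin and eosin
    OD channels restricted to the polygon's interior pixels. The OD
    channels can be passed pre-computed via ``_od`` to avoid repeated
    deconvolution.
    """
    ring = np.asarray(detection.polygon, dtype=float)
    poly = Polygon(ring)
    shape = rgb_image.shape[:2]
    rr, cc = _polygon_pixels(ring, shape)
    if rr.size < 1 or poly.area < 1.0:
        raise DegeneratePolygonError(
            f"detection {detection.id}: polygon covers {rr.size} pixels"
        )
    od_h, od_e = _od if _od is not None else deconvolve_stains(rgb_image)

    area_um2 = poly.area * mpp**2
    perimeter_um = poly.length * mpp
    circularity = 4.0 * np.pi * poly.area / poly.length**2
    solidity = poly.area / poly.convex_hull.area

    mask = np.zeros(
        (rr.max() - rr.min() + 1, cc.max() - cc.min() + 1), dtype=bool
    )
    mask[rr - rr.min(), cc - cc.min()] = True
    props = measure.regionprops(mask.astype(np.uint8))[0]
    eccentricity = props.eccentricity

    h_vals = od_h[rr, cc]
    e_vals = od_e[rr, cc]
    feats = dict(
        area_um2=float(area_um2),
        perimeter_um=float(perimeter_um),
        circularity=float(circularity),
        eccentricity=float(eccentricity),
        solidity=float(solidity),
        mean_od_h=float(h_vals.mean()),
        sd_od_h=float(h_vals.std()),
        mean_od_e=float(e_vals.mean()),
    )
    if not all(np.isfinite(v) for v in feats.values()):
        raise ValueError(f"non-finite feature for detection {detection.id}")
    detection.mean_od_h = feats["mean_od_h"]
    detection.mean_od_e = feats["mean_od_e"]
    return feats


def extract_feature_table(
    rgb_image: np.ndarray,
    detections: list[Detection],
    mpp: float = 0.4416,
) -> pd.DataFrame:
    """Feature matrix (detection id x feature) with one shared deconvolution."""
    od = deconvolve_stains(rgb_image)
    rows = {
        d.id: extract_features(rgb_image, d, mpp=mpp, _od=od) for d in detections
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    frame.index.name = "detection_id"
    return frame


def train_classifier(
    features: pd.DataFrame,
    annotations: AnnotationSet,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the few-shot ensemble on the annotated subset of ``features``.

    Deterministic given the seed. At least two classes must be annotated;
    every annotated id must be present in the feature table.
    """
    ids = [i for i, _ in annotations.labels]
    labels = [l for _, l in annotations.labels]
    missing = [i for i in ids if i not in features.index]
    if missing:
        raise KeyError(f"annotated ids missing from feature table: {missing[:5]}")
    if len(set(labels)) < 2:
        raise ValueError("need annotations from at least two classes")
    X = features.loc[ids, list(FEATURE_NAMES)].to_numpy()
    model = RandomForestClassifier(
        n_estimators=200, random_state=seed, n_jobs=1
    )
    model.fit(X, labels)
    counts: dict[str, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    return TrainedClassifier(
        model=model,
        classes=tuple(model.classes_),
        feature_names=FEATURE_NAMES,
        training_counts=counts,
        seed=seed,
    )


def classify_detections(
    clf: TrainedClassifier,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Predict a label and class-probability vector for every detection.

    Probabilities are the ensemble's vote fractions and sum to one; ties
    are broken by the fixed class order Tumor < Non-neoplastic < Ignore.
    Returns a DataFrame indexed like ``features`` with a ``label`` column
    and one ``p_<class>`` column per trained class.
    """
    if list(features.columns) != list(clf.feature_names):
        raise ValueError(
            f"feature mismatch: classifier expects {list(clf.feature_names)}, "
            f"got {list(features.columns)}"
        )
    out = pd.DataFrame(index=features.index)
    if features.empty:
        out["label"] = pd.Series(dtype=object)
        for cls in clf.classes:
            out[f"p_{cls}"] = pd.Series(dtype=float)
        return out
    proba = clf.model.predict_proba(features.to_numpy())
    # stable argmax in the fixed class order, not sklearn's internal order
    ordered = [c for c in CLASS_NAMES if c in clf.classes]
    col_of = {c: list(clf.classes).index(c) for c in ordered}
    ordered_proba = np.column_stack([proba[:, col_of[c]] for c in ordered])
    winners = np.argmax(ordered_proba, axis=1)  # first max wins the tie
    out["label"] = [ordered[k] for k in winners]
    for cls in clf.classes:
        out[f"p_{cls}"] = proba[:, list(clf.classes).index(cls)]
    return out


def learning_curve(
    features: pd.DataFrame,
    truth_labels: pd.Series,
    annotation_counts: list[int],
    reps: int = 3,
    seed: int = 0,
    n_ignore: int | None = None,
) -> pd.DataFrame:
    """Accuracy as a function of the per-class annotation budget.

    For each budget ``n`` the classifier is trained on ``n`` randomly drawn
    exemplars per nucleus class (plus ``n_ignore`` artifacts, default
    ``min(n, available)``) and evaluated on all remaining objects,
    averaged over ``reps`` repetitions with distinct sub-seeds.
    """
    if sorted(annotation_counts) != list(annotation_counts):
        raise ValueError("annotation_counts must be ascending")
    truth = truth_labels.reindex(features.index)
    if truth.isna().any():
        raise ValueError("every feature row needs a ground-truth label")
    by_class = {c: truth.index[truth == c].to_list() for c in CLASS_NAMES}
    rows = []
    for n in annotation_counts:
        for cls in (TUMOR, NON_NEOPLASTIC):
            if n > len(by_class[cls]):
                raise ValueError(
                    f"requested {n} {cls} annotations but only "
                    f"{len(by_class[cls])} ground-truth cells exist"
                )
        accs = []
        for rep in range(reps):
            rng = np.random.default_rng([seed, n, rep])
            chosen: list[tuple[str, str]] = []
            for cls in (TUMOR, NON_NEOPLASTIC):
                pick = rng.choice(len(by_class[cls]), size=n, replace=False)
                chosen += [(by_class[cls][i], cls) for i in pick]
            n_ig = min(n if n_ignore is None else n_ignore, len(by_class[IGNORE]))
            if n_ig:
                pick = rng.choice(len(by_class[IGNORE]), size=n_ig, replace=False)
                chosen += [(by_class[IGNORE][i], IGNORE) for i in pick]
            ann = AnnotationSet(tuple(chosen))
            clf = train_classifier(features, ann, seed=int(rng.integers(2**31)))
            train_ids = {i for i, _ in chosen}
            eval_ids = [i for i in features.index if i not in train_ids]
            if not eval_ids:
                continue
            pred = classify_detections(clf, features.loc[eval_ids])
            accs.append(float((pred["label"] == truth.loc[eval_ids]).mean()))
        rows.append(dict(n_per_class=n, mean_accuracy=float(np.mean(accs))))
    return pd.DataFrame(rows)
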