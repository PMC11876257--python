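import numpy as np
import pandas as pd
import pytest

from tumorfrac.classify import extract_feature_table
from tumorfrac.detect import DetectParams, detect_nuclei, match_to_ground_truth
from tumorfrac.synthscene import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def scene():
    """Reference scene: 150 nuclei at true fraction 0.30 plus 10 artifacts."""
    spec = SceneSpec(seed=7)
    rgb, cells, roi = generate_scene(spec)
    return spec, rgb, cells, roi


@pytest.fixture(scope="session")
def detections(scene):
    spec, rgb, cells, roi = scene
    return detect_nuclei(rgb, roi, DetectParams(mpp=spec.mpp))


@pytest.fixture(scope="session")
def features(scene, detections):
    spec, rgb, cells, roi = scene
    return extract_feature_table(rgb, detections, mpp=spec.mpp)


@pytest.fixture(scope="session")
def truth_labels(scene, detections):
    """Ground-truth class per detection id, via one-to-one centroid matching."""
    spec, rgb, cells, roi = scene
    centroids = np.array([c.centroid for c in cells])
    pairs = match_to_ground_truth(detections, centroids, max_dist_px=8.0)
    return pd.Series(
        {detections[di].id: cells[ti].true_class for di, ti in pairs}
    )
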