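"""QuPath-dialect GeoJSON interchange for annotations and detections.

Features are polygons in 0-based pixel coordinates (x, y), y-down, with the
class name carried under ``properties.classification.name`` — the layout
QuPath writes and reads. Round trips are lossless for geometry and class
names; a feature without a classification imports as "Unclassified" with a
logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, mapping, shape as shapely_shape

logger = logging.getLogger(__name__)

__all__ = [
    "GeoJSONParseError",
    "read_geojson_mapping",
    "read_geojson",
    "write_geojson",
    "cells_to_features",
    "detections_to_features",
]

_CLASS_COLORS = {
    "Tumor": [200, 0, 0],
    "Non-neoplastic": [0, 140, 60],
    "Ignore": [120, 120, 120],
}


class GeoJSONParseError(ValueError):
    """Schema violation; the message names the offending feature index."""


def read_geojson_mapping(source) -> dict:
    """Load a FeatureCollection mapping from a path, JSON text, or dict."""
    if isinstance(source, dict):
        collection = source
    else:
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        try:
            collection = json.loads(text)
        except json.JSONDecodeError as exc:
            raise GeoJSONParseError(f"not valid JSON: {exc}") from exc
    if collection.get("type") != "FeatureCollection":
        raise GeoJSONParseError(
            f"expected a FeatureCollection, got {collection.get('type')!r}"
        )
    return collection


def read_geojson(source) -> list[tuple[Polygon, str, str]]:
    """Read polygons with class names.

    Returns a list of ``(polygon, class_name, feature_id)`` triples.
    Non-polygon geometries raise :class:`GeoJSONParseError` naming the
    feature index; a missing classification becomes "Unclassified".
    """
    collection = read_geojson_mapping(source)
    out = []
    for i, feat in enumerate(collection.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise GeoJSONParseError(
                f"feature {i}: expected Polygon geometry, got {geom.get('type')!r}"
            )
        poly = shapely_shape(geom)
        props = feat.get("properties") or {}
        classification = props.get("classification")
        if classification and "name" in classification:
            name = classification["name"]
        else:
            name = "Unclassified"
            logger.warning("feature %d has no classification; using %r", i, name)
        out.append((poly, name, str(feat.get("id", f"feature-{i}"))))
    return out


def _feature(polygon, name: str, feature_id: str, object_type: str) -> dict:
    ring = np.asarray(
        polygon.exterior.coords if isinstance(polygon, Polygon) else polygon
    )
    if not np.allclose(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[:1]])
    return {
        "type": "Feature",
        "id": feature_id,
        "geometry": {
            "type": "Polygon",
            "coordinates": [[[float(x), float(y)] for x, y in ring]],
        },
        "properties": {
            "objectType": object_type,
            "classification": {
                "name": name,
                "color": _CLASS_COLORS.get(name, [64, 64, 64]),
            },
        },
    }


def write_geojson(features: list[dict], path) -> None:
    """Write a FeatureCollection (features from the ``*_to_features`` helpers)."""
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection))


def cells_to_features(cells) -> list[dict]:
    """Ground-truth cells as QuPath annotation features."""
    return [
        _feature(c.polygon, c.true_class, c.id, "annotation") for c in cells
    ]


def detections_to_features(detections, labels=None) -> list[dict]:
    """Detections (optionally with a label mapping by id) as features."""
    feats = []
    for d in detections:
        name = d.label or "Unclassified"
        if labels is not None and d.id in labels:
            name = labels[d.id]
        feats.append(_feature(d.polygon, name, d.id, "detection"))
    return feats
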