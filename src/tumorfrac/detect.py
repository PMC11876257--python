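"""Classical nucleus detection inside an ROI, plus GeoJSON import.

The detector is a deconvolve-threshold-split pipeline: hematoxylin OD is
recovered by color deconvolution, thresholded, holes filled, touching
blobs split by distance-transform markers and watershed, and the resulting
regions polygonized, area-gated and restricted to the ROI by the
centroid-inside rule. It is a deterministic classical stand-in at the
"nuclei as cell surrogate" stage; detections produced by external deep
detectors can enter through :func:`import_detections` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon, shape as shapely_shape
from skimage import measure
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from . import stains

__all__ = [
    "Detection",
    "DetectParams",
    "EmptyROIError",
    "GeoJSONImportError",
    "deconvolve_stains",
    "detect_nuclei",
    "import_detections",
    "match_to_ground_truth",
]


class EmptyROIError(ValueError):
    """ROI does not intersect the image."""


class GeoJSONImportError(ValueError):
    """Malformed GeoJSON input; the message names the offending feature."""


@dataclass
class Detection:
    """A detected nucleus candidate.

    ``polygon`` is a closed ring in 0-based pixel coordinates (x, y),
    clipped to the ROI; ``area_um2`` is the clipped polygon area scaled by
    mpp^2. OD features and the class label are filled by the classifier
    stage; ``label`` may carry a prior class name on import.
    """

    id: str
    centroid: tuple[float, float]
    polygon: np.ndarray
    area_um2: float
    mean_od_h: float = float("nan")
    mean_od_e: float = float("nan")
    label: str | None = None

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class DetectParams:
    """Detector hyperparameters.

    ``od_threshold`` sits between the stromal background and the faintest
    rendered object; the area gates bracket nuclear sizes at 20x (8 um^2
    excludes debris, 400 um^2 excludes confluent clumps);
    ``split_min_distance_px`` is the minimum marker separation for
    watershed splitting of touching nuclei.
    """

    od_threshold: float = 0.35
    min_area_um2: float = 8.0
    max_area_um2: float = 400.0
    split_min_distance_px: int = 9
    mpp: float = 0.4416

    def __post_init__(self) -> None:
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("need 0 < min_area_um2 < max_area_um2")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


def deconvolve_stains(rgb_image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hematoxylin and eosin OD channels of an 8-bit RGB image.

    Beer-Lambert inversion against the fixed stain pair; saturated black
    pixels are floored so the output is finite, and concentrations are
    non-negative.
    """
    return stains.deconvolve(rgb_image)


def _region_polygon(mask: np.ndarray, offset_rc: tuple[int, int]) -> Polygon | None:
    """Largest closed contour of a binary region as a shapely polygon."""
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    # (row, col) -> (x, y), undo padding
    xs = contour[:, 1] - 1 + offset_rc[1]
    ys = contour[:, 0] - 1 + offset_rc[0]
    if len(xs) < 4:
        return None
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.geom_type != "Polygon":
        return None
    return poly.simplify(0.3, preserve_topology=True)


def _ring(poly: Polygon) -> np.ndarray:
    return np.asarray(poly.exterior.coords)


def detect_nuclei(
    rgb_image: np.ndarray,
    roi_polygon: Polygon,
    params: DetectParams | None = None,
) -> list[Detection]:
    """Detect nucleus candidates whose centroids lie inside the ROI.

    Zero detections is a valid result (e.g. a blank stromal tile); an ROI
    that misses the image entirely raises :class:`EmptyROIError`.
    """
    params = params or DetectParams()
    h, w = rgb_image.shape[:2]
    from shapely.geometry import box as shapely_box

    if not roi_polygon.intersects(shapely_box(0, 0, w, h)):
        raise EmptyROIError("ROI polygon does not intersect the image")

    od_h, _ = deconvolve_stains(rgb_image)
    mask = od_h > params.od_threshold
    mask = ndi.binary_fill_holes(mask)
    min_area_px = max(4, int(params.min_area_um2 / params.mpp**2 * 0.5))
    mask = remove_small_objects(mask, max_size=min_area_px - 1)
    if not mask.any():
        return []

    distance = ndi.distance_transform_edt(mask)
    smooth = gaussian(distance, sigma=2.0)
    blob_labels, _ = ndi.label(mask)
    peaks = peak_local_max(
        smooth,
        min_distance=params.split_min_distance_px,
        labels=blob_labels,
        exclude_border=False,
    )
    markers = np.zeros_like(blob_labels)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    # blobs whose maximum was suppressed entirely keep a single marker
    missing = set(np.unique(blob_labels[mask])) - set(
        np.unique(blob_labels[markers > 0])
    )
    next_id = len(peaks) + 1
    for blob in missing:
        rr, cc = np.nonzero(blob_labels == blob)
        k = int(np.argmax(distance[rr, cc]))
        markers[rr[k], cc[k]] = next_id
        next_id += 1
    segmented = watershed(-smooth, markers, mask=mask)

    detections: list[Detection] = []
    idx = 0
    for region in measure.regionprops(segmented):
        minr, minc, maxr, maxc = region.bbox
        sub = segmented[minr:maxr, minc:maxc] == region.label
        poly = _region_polygon(sub, (minr, minc))
        if poly is None:
            continue
        clipped = poly.intersection(roi_polygon)
        if clipped.is_empty:
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        if clipped.geom_type != "Polygon" or clipped.area <= 0:
            continue
        area_um2 = clipped.area * params.mpp**2
        if not params.min_area_um2 <= area_um2 <= params.max_area_um2:
            continue
        centroid = clipped.centroid
        if not roi_polygon.contains(centroid):
            continue
        detections.append(
            Detection(
                id=f"det-{idx:04d}",
                centroid=(centroid.x, centroid.y),
                polygon=_ring(clipped),
                area_um2=float(area_um2),
            )
        )
        idx += 1
    return detections


def import_detections(
    geojson: dict | str,
    roi_polygon: Polygon,
    mpp: float = 0.4416,
) -> list[Detection]:
    """Load externally produced detections from QuPath-dialect GeoJSON.

    ``geojson`` is a FeatureCollection mapping or a path to one. Features
    are clipped to the ROI and filtered by the centroid-inside rule;
    pre-existing ``classification.name`` entries are preserved as prior
    labels. Non-polygon geometries raise :class:`GeoJSONImportError`
    naming the feature index.
    """
    from .geojson_io import read_geojson_mapping

    collection = read_geojson_mapping(geojson)
    features = collection.get("features", [])
    detections: list[Detection] = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise GeoJSONImportError(
                f"feature {i}: expected Polygon geometry, got {geom.get('type')!r}"
            )
        try:
            poly = shapely_shape(geom)
        except Exception as exc:  # malformed coordinates
            raise GeoJSONImportError(f"feature {i}: invalid geometry ({exc})") from exc
        if not poly.is_valid:
            poly = poly.buffer(0)
        clipped = poly.intersection(roi_polygon)
        if clipped.is_empty:
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        centroid = clipped.centroid
        if not roi_polygon.contains(centroid):
            continue
        props = feat.get("properties") or {}
        classification = props.get("classification") or {}
        detections.append(
            Detection(
                id=str(feat.get("id", f"det-{i:04d}")),
                centroid=(centroid.x, centroid.y),
                polygon=_ring(clipped),
                area_um2=float(clipped.area * mpp**2),
                label=classification.get("name"),
            )
        )
    return detections


def match_to_ground_truth(
    detections: list[Detection],
    truth_centroids: np.ndarray,
    max_dist_px: float,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections to ground-truth centroids.

    Pairs are accepted in increasing distance order while both sides are
    unmatched and the distance is below ``max_dist_px``. Returns a list of
    (detection index, truth index) pairs; recall is ``len(pairs) /
    len(truth_centroids)``.
    """
    truth = np.asarray(truth_centroids, dtype=float)
    if not detections or truth.size == 0:
        return []
    det = np.array([d.centroid for d in detections])
    dists = np.linalg.norm(det[:, None, :] - truth[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for di, ti in order:
        if dists[di, ti] > max_dist_px:
            break
        if di in used_d or ti in used_t:
            continue
        pairs.append((int(di), int(ti)))
        used_d.add(int(di))
        used_t.add(int(ti))
    return pairs
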