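"""Tumor cellular fraction from labeled detections, adequacy gating, and
comparison against observer scores.

The computational TCF (cTCF) is the count ratio
``n_tumor / (n_tumor + n_nonneo)`` over labeled nuclei inside the ROI;
Ignore-labeled detections never enter the ratio. Molecular adequacy
requires at least ``min_cells`` viable tumor cells and a TCF of at least
``min_tcf`` (defaults 100 and 20%, both inclusive). A tumor-area-fraction
comparator captures the area-based quantity that tracks visual perception
("illusion of size") rather than cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .synthscene import CLASS_NAMES, IGNORE, NON_NEOPLASTIC, TUMOR

__all__ = [
    "TCFResult",
    "compute_ctcf",
    "assess_adequacy",
    "tumor_area_fraction",
    "tumor_foci",
    "compare_scores",
]

MIN_TUMOR_CELLS = 100
MIN_TCF = 0.20


@dataclass(frozen=True)
class TCFResult:
    """Class counts inside the ROI and the derived fraction with flags.

    ``ctcf`` is None when no countable (non-Ignore) cells exist — an
    undefined fraction is distinct from a 0% tumor fraction.
    """

    n_tumor: int
    n_nonneo: int
    n_ignore: int
    ctcf: float | None
    adequate_cells: bool = False
    adequate_tcf: bool = False
    adequate: bool = False


def compute_ctcf(labels) -> TCFResult:
    """Count labeled detections and form the cTCF.

    ``labels`` is an iterable of class names (or objects with a ``label``
    attribute, e.g. classified detections). Unknown labels raise.
    """
    counts = {TUMOR: 0, NON_NEOPLASTIC: 0, IGNORE: 0}
    for item in labels:
        label = getattr(item, "label", item)
        if label not in counts:
            raise ValueError(f"unknown class label {label!r}; expected {CLASS_NAMES}")
        counts[label] += 1
    denom = counts[TUMOR] + counts[NON_NEOPLASTIC]
    ctcf = counts[TUMOR] / denom if denom else None
    return assess_adequacy(
        TCFResult(
            n_tumor=counts[TUMOR],
            n_nonneo=counts[NON_NEOPLASTIC],
            n_ignore=counts[IGNORE],
            ctcf=ctcf,
        )
    )


def assess_adequacy(
    result: TCFResult,
    min_cells: int = MIN_TUMOR_CELLS,
    min_tcf: float = MIN_TCF,
) -> TCFResult:
    """Fill the molecular-adequacy flags (thresholds inclusive).

    A sample is adequate when it holds at least ``min_cells`` viable tumor
    cells and its TCF is at least ``min_tcf``; an undefined TCF is never
    adequate.
    """
    adequate_cells = result.n_tumor >= min_cells
    adequate_tcf = result.ctcf is not None and result.ctcf >= min_tcf
    return replace(
        result,
        adequate_cells=adequate_cells,
        adequate_tcf=adequate_tcf,
        adequate=adequate_cells and adequate_tcf,
    )


def tumor_area_fraction(labeled_regions, roi_polygon: Polygon) -> float:
    """Fraction of ROI area covered by Tumor-labeled regions.

    ``labeled_regions`` is an iterable of (polygon, label) pairs; polygons
    may be shapely geometries or coordinate rings. Overlapping tumor
    regions are unioned before intersecting with the ROI so no area is
    double-counted.
    """
    if roi_polygon.area <= 0:
        raise ValueError("ROI polygon has zero area")
    tumor_polys = []
    for geom, label in labeled_regions:
        if label != TUMOR:
            continue
        poly = geom if isinstance(geom, Polygon) else Polygon(np.asarray(geom))
        tumor_polys.append(poly)
    if not tumor_polys:
        return 0.0
    merged = unary_union(tumor_polys)
    return float(merged.intersection(roi_polygon).area / roi_polygon.area)


def tumor_foci(
    labeled_polygons,
    halo_um: float = 6.0,
    mpp: float = 0.4416,
):
    """Heuristic tumor-focus outlines from labeled nucleus polygons.

    Dilates each Tumor nucleus by a cytoplasm halo and merges the result,
    approximating region-level tumor outlining from nucleus-level labels.
    Returns a list of (polygon, label) pairs suitable for
    :func:`tumor_area_fraction`.
    """
    halo_px = halo_um / mpp
    tumor = [
        (geom if isinstance(geom, Polygon) else Polygon(np.asarray(geom))).buffer(
            halo_px
        )
        for geom, label in labeled_polygons
        if label == TUMOR
    ]
    if not tumor:
        return []
    merged = unary_union(tumor)
    geoms = merged.geoms if merged.geom_type == "MultiPolygon" else [merged]
    return [(g, TUMOR) for g in geoms]


def compare_scores(
    ctcf_percent: pd.Series,
    observer_table: pd.DataFrame,
) -> dict:
    """Per-case deltas and direction counts of cTCF vs the observer mean.

    Both inputs are on the percent scale and indexed by case id; the
    observer comparator is the across-observer mean ("average score").
    Direction is judged on integer-rounded percentages — pathologists
    report integers, so "equal" means equal after rounding.

    Returns a dict with a per-case DataFrame and the summary: counts and
    fractions of lower/higher/equal cases plus mean +/- SD of both score
    sets.
    """
    missing = observer_table.index.difference(ctcf_percent.index)
    extra = ctcf_percent.index.difference(observer_table.index)
    if len(missing) or len(extra):
        raise KeyError(
            f"case id mismatch: missing cTCF for {list(missing)[:5]}, "
            f"missing observers for {list(extra)[:5]}"
        )
    obs_mean = observer_table.mean(axis=1)
    ctcf = ctcf_percent.reindex(obs_mean.index)
    c_int = ctcf.round().astype(int)
    p_int = obs_mean.round().astype(int)
    direction = np.where(c_int < p_int, "lower", np.where(c_int > p_int, "higher", "equal"))
    per_case = pd.DataFrame(
        {
            "ctcf": ctcf,
            "observer_mean": obs_mean,
            "delta": ctcf - obs_mean,
            "direction": direction,
        }
    )
    counts = per_case["direction"].value_counts().reindex(
        ["lower", "higher", "equal"], fill_value=0
    )
    n = len(per_case)
    return {
        "per_case": per_case,
        "n_lower": int(counts["lower"]),
        "n_higher": int(counts["higher"]),
        "n_equal": int(counts["equal"]),
        "frac_lower": float(counts["lower"] / n) if n else float("nan"),
        "mean_ctcf": float(ctcf.mean()),
        "sd_ctcf": float(ctcf.std(ddof=1)) if n > 1 else float("nan"),
        "mean_observer": float(obs_mean.mean()),
        "sd_observer": float(obs_mean.std(ddof=1)) if n > 1 else float("nan"),
    }
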