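"""Synthetic H&E scene, observer-rating, and CNV-table generation.

Everything downstream of this module (detection, classification, TCF
computation, purity-corrected CNV calling, agreement statistics) is
testable against the ground truth emitted here, without any external data.

A scene is a flat stromal field populated with three object populations:

* **Tumor** nuclei — larger, more pleomorphic ellipses;
* **Non-neoplastic** nuclei — smaller, rounder (immune/stromal/epithelial);
* **Ignore** objects — non-nuclear artifacts (red-blood-cell like blobs)
  rendered with a distinct, eosin-heavy color signature.

Nuclei are ellipses perturbed by low-order radial harmonics and placed by
rejection sampling inside the ROI; rendering goes through the shared
Beer-Lambert two-stain model in :mod:`tumorfrac.stains`. Identical spec and
seed reproduce a scene bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree
from skimage.draw import polygon as draw_polygon

from .stains import od_to_rgb

__all__ = [
    "TUMOR",
    "NON_NEOPLASTIC",
    "IGNORE",
    "CLASS_NAMES",
    "SceneSpec",
    "GroundTruthCell",
    "ObserverModel",
    "OvercrowdedSceneError",
    "generate_scene",
    "render_he",
    "true_tcf",
    "simulate_observers",
    "generate_cnv_table",
    "cnv_cohort_pair",
]

# Class labels use the QuPath-dialect names so ground truth, classifier
# output and GeoJSON round-trips share one vocabulary.
TUMOR = "Tumor"
NON_NEOPLASTIC = "Non-neoplastic"
IGNORE = "Ignore"
CLASS_NAMES = (TUMOR, NON_NEOPLASTIC, IGNORE)

# Rendering constants (natural-log optical densities). Nuclei are
# hematoxylin-dominant; artifacts sit in a band of moderate hematoxylin and
# very high eosin so they are detectable yet clearly below the darkest-blue
# nucleus signature.
BACKGROUND_OD_H = 0.04
BACKGROUND_OD_E = 0.18
NUCLEUS_OD_H_MIN = 0.80          # lower clip for any rendered nucleus
ARTIFACT_OD_H_MAX = 0.60         # upper clip for any rendered artifact
_NUCLEUS_OD_E = 0.12
_ARTIFACT_OD_E = 0.85
_PIXEL_NOISE_SD = 0.02


class OvercrowdedSceneError(RuntimeError):
    """Raised when rejection sampling cannot place the requested objects."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic H&E field.

    Defaults describe a 1024 px square tile at 0.4416 microns per pixel
    (20x scan resolution) holding 150 nuclei at a true tumor fraction of
    0.30 plus 10 non-nuclear artifacts. Mean nuclear areas follow typical
    NSCLC morphometry: ~70 um^2 tumor nuclei vs ~25 um^2 for the smaller,
    rounder non-neoplastic population.
    """

    width_px: int = 1024
    height_px: int = 1024
    mpp: float = 0.4416
    n_tumor: int = 45
    n_nonneo: int = 105
    n_artifact: int = 10
    tumor_mean_area_um2: float = 70.0
    nonneo_mean_area_um2: float = 25.0
    artifact_mean_area_um2: float = 35.0
    area_cv: float = 0.25
    max_overlap_frac: float = 0.0
    roi_margin_px: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_nonneo, self.n_artifact) < 0:
            raise ValueError("object counts must be non-negative")
        if not self.tumor_mean_area_um2 > self.nonneo_mean_area_um2 > 0:
            raise ValueError(
                "tumor_mean_area_um2 must exceed nonneo_mean_area_um2 (> 0)"
            )
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if not 0 <= self.max_overlap_frac < 1:
            raise ValueError("max_overlap_frac must lie in [0, 1)")

    @property
    def true_fraction(self) -> float | None:
        """Spec-implied tumor cellular fraction, None for an empty scene."""
        denom = self.n_tumor + self.n_nonneo
        return self.n_tumor / denom if denom else None


@dataclass
class GroundTruthCell:
    """One placed object with its per-object truth.

    ``polygon`` is a closed ring (first vertex repeated last) of >= 8
    vertices in 0-based pixel coordinates, y-down. ``ellipse`` holds the
    generating (semi-major px, semi-minor px, orientation rad) before
    radial perturbation.
    """

    id: str
    true_class: str
    centroid: tuple[float, float]
    ellipse: tuple[float, float, float]
    polygon: np.ndarray
    od_h: float = 1.0
    od_e: float = _NUCLEUS_OD_E

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class ObserverModel:
    """Additive-bias observer emulating visual TCF scoring.

    ``rating = clip(round_to(truth + bias + N(0, noise_sd), rounding), 0, 100)``.
    A positive ``bias`` reproduces the over-estimation pathologists show
    relative to cell-by-cell ground truth; ``rounding`` mimics reporting on
    a coarse percent grid (pathologists rarely report off-5 values).
    """

    name: str = "observer"
    bias: float = 18.0
    noise_sd: float = 10.0
    rounding: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rounding < 1:
            raise ValueError("rounding granularity must be >= 1")


def _perturbed_ellipse(
    cx: float,
    cy: float,
    a: float,
    b: float,
    theta: float,
    rng: np.random.Generator,
    n_vertices: int = 24,
    noise_amp: float = 0.04,
) -> np.ndarray:
    """Closed polygon ring of an ellipse with low-order radial harmonics."""
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    psi = angles - theta
    radius = a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
    for m in (2, 3, 4):
        radius *= 1.0 + rng.uniform(0.0, noise_amp) * np.cos(
            m * angles + rng.uniform(0.0, 2.0 * math.pi)
        )
    xs = cx + radius * np.cos(angles)
    ys = cy + radius * np.sin(angles)
    ring = np.column_stack([xs, ys])
    return np.vstack([ring, ring[:1]])


# Per-class shape parameters: (mean area attr, max axis ratio, od_h draw).
def _class_params(spec: SceneSpec) -> dict[str, tuple[float, float]]:
    return {
        TUMOR: (spec.tumor_mean_area_um2, 1.6),
        NON_NEOPLASTIC: (spec.nonneo_mean_area_um2, 1.25),
        IGNORE: (spec.artifact_mean_area_um2, 1.3),
    }


def generate_scene(
    spec: SceneSpec,
) -> tuple[np.ndarray, list[GroundTruthCell], Polygon]:
    """Generate one synthetic H&E tile.

    Returns
    -------
    rgb : uint8 array (height, width, 3)
    cells : list of :class:`GroundTruthCell`
        Exactly ``n_tumor + n_nonneo + n_artifact`` objects, tumor first.
    roi : shapely Polygon
        The counting region: the tile rectangle inset by ``roi_margin_px``
        (the synthetic analogue of the pen-marked microdissection area).

    Raises
    ------
    OvercrowdedSceneError
        If rejection sampling cannot satisfy ``max_overlap_frac`` for the
        requested counts within a bounded number of retries.
    """
    rng = np.random.default_rng(spec.seed)
    roi = box(
        spec.roi_margin_px,
        spec.roi_margin_px,
        spec.width_px - spec.roi_margin_px,
        spec.height_px - spec.roi_margin_px,
    )
    if roi.area <= 0:
        raise ValueError("roi_margin_px leaves no counting area")

    params = _class_params(spec)
    schedule = (
        [TUMOR] * spec.n_tumor
        + [NON_NEOPLASTIC] * spec.n_nonneo
        + [IGNORE] * spec.n_artifact
    )
    px_per_um2 = 1.0 / spec.mpp**2

    cells: list[GroundTruthCell] = []
    placed: list[Polygon] = []
    tree: STRtree | None = None
    max_attempts = 500
    for idx, cls in enumerate(schedule):
        mean_area, max_ratio = params[cls]
        for attempt in range(max_attempts):
            area_um2 = rng.normal(mean_area, spec.area_cv * mean_area)
            area_um2 = float(np.clip(area_um2, 0.35 * mean_area, 2.5 * mean_area))
            area_px = area_um2 * px_per_um2
            ratio = rng.uniform(1.0, max_ratio)
            a = math.sqrt(area_px * ratio / math.pi)
            b = area_px / (math.pi * a)
            theta = rng.uniform(0.0, math.pi)
            pad = a * 1.1 + 1.0
            minx, miny, maxx, maxy = roi.bounds
            lo_x, hi_x = max(minx, pad), min(maxx, spec.width_px - pad)
            lo_y, hi_y = max(miny, pad), min(maxy, spec.height_px - pad)
            if lo_x >= hi_x or lo_y >= hi_y:
                raise OvercrowdedSceneError(
                    f"object of radius {a:.1f}px cannot fit inside the ROI"
                )
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            ring = _perturbed_ellipse(cx, cy, a, b, theta, rng)
            poly = Polygon(ring)
            if not poly.is_valid or not poly.contains(poly.centroid):
                continue
            if tree is not None:
                ok = True
                for j in tree.query(poly):
                    other = placed[int(j)]
                    inter = poly.intersection(other).area
                    if inter > spec.max_overlap_frac * min(poly.area, other.area):
                        ok = False
                        break
                if not ok:
                    continue
            if cls == IGNORE:
                od_h = float(np.clip(rng.normal(0.50, 0.03), 0.40, ARTIFACT_OD_H_MAX))
                od_e = _ARTIFACT_OD_E
            else:
                od_h = float(np.clip(rng.normal(0.95, 0.05), NUCLEUS_OD_H_MIN, 1.15))
                od_e = _NUCLEUS_OD_E
            c = poly.centroid
            cells.append(
                GroundTruthCell(
                    id=f"cell-{idx:04d}",
                    true_class=cls,
                    centroid=(c.x, c.y),
                    ellipse=(a, b, theta),
                    polygon=ring,
                    od_h=od_h,
                    od_e=od_e,
                )
            )
            placed.append(poly)
            tree = STRtree(placed)
            break
        else:
            raise OvercrowdedSceneError(
                f"could not place object {idx + 1}/{len(schedule)} "
                f"after {max_attempts} attempts; scene is overcrowded"
            )

    rgb = render_he(cells, (spec.height_px, spec.width_px), rng=rng)
    return rgb, cells, roi


def render_he(
    cells: list[GroundTruthCell],
    shape: tuple[int, int],
    rng: np.random.Generator | int | None = None,
    background: tuple[float, float] = (BACKGROUND_OD_H, BACKGROUND_OD_E),
) -> np.ndarray:
    """Render placed objects onto an eosin-tinted stromal background.

    Nuclei are hematoxylin-dominant, artifacts eosin-dominant with a
    moderate hematoxylin component strictly below the nucleus floor, so the
    Ignore class is both detectable and learnable. With no cells the output
    is the pure background rendering.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    h, w = shape
    od_h = np.full((h, w), background[0]) + rng.normal(0, 0.01, (h, w))
    od_e = np.full((h, w), background[1]) + rng.normal(0, 0.02, (h, w))
    for cell in cells:
        ring = cell.polygon
        rr, cc = draw_polygon(ring[:, 1], ring[:, 0], shape=(h, w))
        if rr.size == 0:
            continue
        od_h[rr, cc] = cell.od_h + rng.normal(0, _PIXEL_NOISE_SD, rr.size)
        od_e[rr, cc] = cell.od_e + rng.normal(0, _PIXEL_NOISE_SD, rr.size)
    np.clip(od_h, 0.0, None, out=od_h)
    np.clip(od_e, 0.0, None, out=od_e)
    return od_to_rgb(od_h, od_e)


def true_tcf(cells: list[GroundTruthCell]) -> float | None:
    """Ground-truth tumor cellular fraction of a scene (Ignore excluded)."""
    n_tumor = sum(1 for c in cells if c.true_class == TUMOR)
    n_nonneo = sum(1 for c in cells if c.true_class == NON_NEOPLASTIC)
    denom = n_tumor + n_nonneo
    return n_tumor / denom if denom else None


def simulate_observers(
    true_tcf_list, models: list[ObserverModel], case_ids=None
) -> pd.DataFrame:
    """Simulate visual TCF ratings for a list of cases.

    Parameters
    ----------
    true_tcf_list
        Ground-truth TCF values on the percent scale, each in [0, 100].
    models
        One :class:`ObserverModel` per simulated rater; each model's own
        seed drives its noise stream.

    Returns
    -------
    DataFrame indexed by case id with one integer-percent column per
    observer.
    """
    truth = np.asarray(true_tcf_list, dtype=float)
    if truth.size and (truth.min() < 0 or truth.max() > 100):
        raise ValueError("true TCF values must lie in [0, 100]")
    if case_ids is None:
        case_ids = [f"case_{i + 1:03d}" for i in range(truth.size)]
    cols = {}
    for model in models:
        rng = np.random.default_rng(model.seed)
        noisy = truth + model.bias + rng.normal(0.0, model.noise_sd, truth.size)
        graded = np.rint(noisy / model.rounding) * model.rounding
        cols[model.name] = np.clip(graded, 0, 100).astype(int)
    return pd.DataFrame(cols, index=pd.Index(case_ids, name="case_id"))


# --------------------------------------------------------------------------
# Synthetic CNV cohort
# --------------------------------------------------------------------------
#
# Paired gene-level copy-number tables for a cohort in which the cellularity
# column is the only difference between the "pathologist" (visual, biased
# high) and "computational" (revised) versions. Records are drawn from
# archetype parameter boxes chosen so that each archetype has a provable
# relation to the x >= 4 primary-call predicate and the 6-criterion
# confidence gate under both cellularity columns:
#
#   archetype  n_cases  call before/after   confident before/after
#   conf_both     6        yes / yes             yes / yes
#   conf_lost     1        yes / yes             yes / no
#   gain_hi       3        yes / yes             no  / yes   (f_revised ~0.5)
#   gain_lo       3        yes / yes             no  / yes   (f below 50% twice)
#   call_only    13        yes / yes             no  / no
#   call_drop     3        yes / no              no  / no
#   new_call      1        no  / yes             no  / yes
#   negative     91        no  / no              no  / no
#
# The cohort therefore realizes 29 primary calls before revision vs 27
# after, 7 vs 13 confidently reported cases, and 7 of the 29 initial calls
# changing final status — the before/after call-set arithmetic downstream
# code must reproduce by computation.

_CNV_HEADER = [
    "case_id",
    "gene",
    "C",
    "f",
    "read_count",
    "mapd",
    "cn_conf_5",
    "p_value",
]

# (f_path, C, f_comp, read_count, mapd, cn_conf_5, log10_p) uniform boxes.
_ARCHETYPES: dict[str, dict] = {
    "conf_both": dict(
        f_path=(0.55, 0.65), C=(5.5, 6.5), f_comp=(0.39, 0.45),
        reads=(20000, 30000), mapd=(0.20, 0.40), conf5=(4.5, 5.5),
        log10_p=(-8.0, -6.0),
    ),
    "conf_lost": dict(
        f_path=(0.55, 0.60), C=(3.95, 4.10), f_comp=(0.82, 0.88),
        reads=(15000, 25000), mapd=(0.25, 0.45), conf5=(4.1, 4.6),
        log10_p=(-4.0, -3.0),
    ),
    "gain_hi": dict(
        f_path=(0.86, 0.90), C=(4.25, 4.38), f_comp=(0.50, 0.55),
        reads=(15000, 25000), mapd=(0.20, 0.40), conf5=(4.2, 4.8),
        log10_p=(-4.0, -3.0),
    ),
    "gain_lo": dict(
        f_path=(0.43, 0.47), C=(3.08, 3.15), f_comp=(0.28, 0.32),
        reads=(15000, 25000), mapd=(0.20, 0.40), conf5=(4.2, 4.8),
        log10_p=(-8.0, -6.0),
    ),
    "call_only": dict(
        f_path=(0.66, 0.70), C=(3.65, 3.75), f_comp=(0.52, 0.58),
        reads=(3000, 8000), mapd=(0.60, 0.90), conf5=(1.5, 3.0),
        log10_p=(-2.0, -0.7),
    ),
    "call_drop": dict(
        f_path=(0.48, 0.50), C=(3.17, 3.23), f_comp=(0.74, 0.82),
        reads=(3000, 8000), mapd=(0.60, 0.90), conf5=(1.5, 3.0),
        log10_p=(-2.0, -0.7),
    ),
    "new_call": dict(
        f_path=(0.88, 0.92), C=(3.45, 3.55), f_comp=(0.28, 0.32),
        reads=(15000, 25000), mapd=(0.20, 0.40), conf5=(4.2, 4.8),
        log10_p=(-8.0, -6.0),
    ),
    "negative": dict(
        f_path=(0.35, 0.75), C=(1.85, 2.15), f_comp=(0.22, 0.40),
        reads=(8000, 30000), mapd=(0.20, 0.60), conf5=(0.5, 2.0),
        log10_p=(-3.0, -0.3),
    ),
}

# (archetype, [genes per record]) per case; two cases carry two genes each.
_COHORT_CASES: list[tuple[str, list[str]]] = (
    [("conf_both", [g]) for g in ("EGFR", "EGFR", "KRAS", "KRAS", "KRAS", "MET")]
    + [("conf_lost", ["EGFR"])]
    + [
        ("gain_hi", ["EGFR", "PIK3CA"]),
        ("gain_hi", ["EGFR"]),
        ("gain_hi", ["KRAS"]),
        ("gain_lo", ["KRAS"]),
        ("gain_lo", ["PIK3CA"]),
        ("gain_lo", ["ERBB2"]),
    ]
    + [
        ("call_only", [g])
        for g in (
            "KRAS", "EGFR", "MET", "CCND1", "FGFR1", "MYC", "CDK4",
            "KRAS", "EGFR", "CCND1", "FGFR1", "MET", "CDK6",
        )
    ]
    + [("call_drop", [g]) for g in ("CCND1", "MYC", "FGFR1")]
    + [("new_call", ["EGFR", "MET"])]
)

_NEGATIVE_GENES = (
    "EGFR", "KRAS", "MET", "ALK", "BRAF", "ERBB2", "PIK3CA",
    "CCND1", "FGFR1", "MYC", "CDK4", "CDK6",
)
_N_NEGATIVE_CASES = 91

_CALL_MIX = ("conf_both", "conf_lost", "gain_hi", "gain_lo", "call_only", "call_drop")
_CALL_MIX_COUNTS = (6, 1, 3, 3, 13, 3)  # cases among the 29 primary calls


def _draw_record(rng: np.random.Generator, arche: str) -> dict:
    """Draw the shared (non-cellularity) fields plus both f columns."""
    p = _ARCHETYPES[arche]
    return dict(
        f_pathologist=round(rng.uniform(*p["f_path"]), 3),
        f_computational=round(rng.uniform(*p["f_comp"]), 3),
        C=round(rng.uniform(*p["C"]), 3),
        read_count=int(rng.integers(p["reads"][0], p["reads"][1] + 1)),
        mapd=round(rng.uniform(*p["mapd"]), 3),
        cn_conf_5=round(rng.uniform(*p["conf5"]), 2),
        p_value=float(10.0 ** rng.uniform(*p["log10_p"])),
    )


def _cohort_rows(seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    cases = list(_COHORT_CASES) + [
        ("negative", [_NEGATIVE_GENES[int(rng.integers(len(_NEGATIVE_GENES)))]])
        for _ in range(_N_NEGATIVE_CASES)
    ]
    order = rng.permutation(len(cases))
    rows = []
    for new_idx, old_idx in enumerate(order):
        arche, genes = cases[old_idx]
        case_id = f"case_{new_idx + 1:03d}"
        draw = _draw_record(rng, arche)
        for gene in genes:
            row = dict(draw)
            if len(genes) > 1:
                # distinct observed copy numbers per gene of the same case
                row["C"] = round(
                    float(np.clip(row["C"] + rng.uniform(-0.02, 0.02),
                                  *_ARCHETYPES[arche]["C"])), 3)
            row.update(case_id=case_id, gene=gene, archetype=arche)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cnv_table(
    n: int,
    cellularity_source: str = "pathologist",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate ``n`` synthetic gene-level CNV records that are primary calls.

    Records are drawn from the call archetypes in proportion to the cohort
    mix (largest-remainder apportionment), so ``n = 29`` reproduces the
    cohort's full primary-call stratum. ``cellularity_source`` selects which
    cellularity column fills ``f`` (``"pathologist"`` or
    ``"computational"``); two tables generated with the same seed share
    every field except ``f``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if cellularity_source not in ("pathologist", "computational"):
        raise ValueError(f"unknown cellularity_source {cellularity_source!r}")
    total = sum(_CALL_MIX_COUNTS)
    quotas = [n * c / total for c in _CALL_MIX_COUNTS]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for arche, count in zip(_CALL_MIX, counts):
        for _ in range(count):
            idx += 1
            row = _draw_record(rng, arche)
            row.update(
                case_id=f"case_{idx:03d}",
                gene=_NEGATIVE_GENES[int(rng.integers(len(_NEGATIVE_GENES)))],
            )
            rows.append(row)
    frame = pd.DataFrame(rows, columns=_CNV_HEADER[:2] + [
        "C", "f_pathologist", "f_computational", "read_count", "mapd",
        "cn_conf_5", "p_value"])
    frame["f"] = frame[f"f_{cellularity_source}"]
    return frame[_CNV_HEADER]


def cnv_cohort_pair(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired before/after CNV tables for a full 121-case synthetic cohort.

    Returns ``(before, after)`` DataFrames with the documented header
    (case_id, gene, C, f, read_count, mapd, cn_conf_5, p_value); the two
    share genes, observed copy numbers and QC fields and differ only in the
    cellularity ``f`` (visual estimate vs revised computational estimate),
    so before/after call-set comparisons are meaningful.
    """
    rows = _cohort_rows(seed)
    before = rows.assign(f=rows["f_pathologist"])[_CNV_HEADER].copy()
    after = rows.assign(f=rows["f_computational"])[_CNV_HEADER].copy()
    return before, after
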