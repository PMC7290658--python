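"""Fusion phenotyping metrics.

Given detected nuclei and a set of myotube ROIs (polygons drawn on the eMHC
channel, or ground-truth outlines from the simulator), this module computes
the standard readouts of a fusion assay:

* nuclei density — total nuclei normalised to the imaged surface (per mm^2);
* differentiation index — fraction of all nuclei residing in eMHC-positive
  cells (mono- or polynucleated);
* the nuclei-per-myotube distribution over eMHC-positive ROIs holding >= 2
  nuclei, summarised by its median, log2(median) and the fraction of myotubes
  in the size classes 2-14, 15-49 and >= 50 nuclei;
* two-group statistical comparisons: Student's pooled-variance t-test for
  approximately normal metrics, and the two-sided Wilcoxon rank-sum
  (Mann-Whitney) test for the skewed fusion distributions, with an exact
  p-value by full enumeration of rank assignments for small samples
  (n_a + n_b <= 12) and a tie/continuity-corrected normal approximation
  otherwise.
"""

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .geometry import points_in_polygon, polygon_centroid
from .scene import Scene
from .segmentation import NucleusSet

__all__ = [
    "Roi",
    "RoiSet",
    "RoiAssignment",
    "GroupComparison",
    "FusionReport",
    "roi_set_from_scene",
    "assign_nuclei_to_rois",
    "nuclei_density",
    "differentiation_index",
    "fusion_distribution",
    "compare_groups",
    "build_fusion_report",
]

BIN_EDGES = ((2, 14), (15, 49), (50, math.inf))
BIN_LABELS = ("2-14", "15-49", "50+")
EXACT_RANKSUM_LIMIT = 12


@dataclass(frozen=True)
class Roi:
    id: int
    polygon: np.ndarray
    emhc_positive: bool


@dataclass(frozen=True)
class RoiSet:
    rois: tuple
    width_px: int
    height_px: int
    pixel_size_um: float

    def __len__(self):
        return len(self.rois)


def _circle_polygon(center, radius: float, n: int = 16) -> np.ndarray:
    a = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(a),
                            center[1] + radius * np.sin(a)])


def roi_set_from_scene(scene: Scene, include_mono: bool = True) -> RoiSet:
    """Ground-truth ROIs: myotube polygons plus (optionally) a cytoplasmic
    outline per eMHC-positive mononucleated cell, mirroring how manually drawn
    eMHC-positive regions would look for this field."""
    rois = [Roi(id=i, polygon=np.asarray(m.polygon, dtype=float), emhc_positive=True)
            for i, m in enumerate(scene.myotubes)]
    if include_mono:
        next_id = len(rois)
        for cell in scene.mono_cells:
            if cell.emhc_positive:
                rois.append(Roi(id=next_id,
                                polygon=_circle_polygon(cell.center, scene.mono_cyto_radius_px),
                                emhc_positive=True))
                next_id += 1
    return RoiSet(tuple(rois), scene.field_width_px, scene.field_height_px,
                  scene.pixel_size_um)


@dataclass(frozen=True)
class RoiAssignment:
    """Per-ROI nucleus counts; counts plus unassigned always sum to total."""

    counts: pd.DataFrame  # columns: roi_id, emhc_positive, n_nuclei
    unassigned: int
    total: int


def assign_nuclei_to_rois(nuclei: NucleusSet, rois: RoiSet) -> RoiAssignment:
    """Assign each nucleus centroid to at most one ROI.

    Containment uses the even-odd rule with the boundary counting as inside.
    A centroid inside several ROIs goes to the ROI whose polygon centroid is
    nearest (ties to the lowest ROI id) — with non-overlapping manually drawn
    ROIs this rule is inert.
    """
    if (nuclei.width_px, nuclei.height_px) != (rois.width_px, rois.height_px):
        raise ParameterError(
            f"field dimension mismatch: nuclei {nuclei.width_px}x{nuclei.height_px} "
            f"vs rois {rois.width_px}x{rois.height_px}")
    pts = nuclei.centroids
    n_pts = len(pts)
    counts = {r.id: 0 for r in rois.rois}
    unassigned = n_pts
    if n_pts and len(rois.rois):
        contain = np.zeros((len(rois.rois), n_pts), dtype=bool)
        for i, roi in enumerate(rois.rois):
            contain[i] = points_in_polygon(pts, roi.polygon)
        roi_centroids = np.array([polygon_centroid(r.polygon) for r in rois.rois])
        roi_ids = np.array([r.id for r in rois.rois])
        for j in range(n_pts):
            hits = np.flatnonzero(contain[:, j])
            if hits.size == 0:
                continue
            if hits.size > 1:
                d = np.hypot(*(roi_centroids[hits] - pts[j]).T)
                # nearest ROI centroid; numpy argmin ties to the first, and
                # sorting hits by id first makes that the lowest ROI id
                order = np.lexsort((roi_ids[hits], d))
                best = hits[order[0]]
            else:
                best = hits[0]
            counts[roi_ids[best]] += 1
            unassigned -= 1
    df = pd.DataFrame({
        "roi_id": [r.id for r in rois.rois],
        "emhc_positive": [r.emhc_positive for r in rois.rois],
        "n_nuclei": [counts[r.id] for r in rois.rois],
    })
    return RoiAssignment(counts=df, unassigned=unassigned, total=n_pts)


def nuclei_density(nuclei: NucleusSet) -> float:
    """Total nuclei per mm^2 of imaged surface."""
    area_um2 = nuclei.width_px * nuclei.height_px * nuclei.pixel_size_um ** 2
    if area_um2 <= 0:
        raise ParameterError("imaged area is zero; check field dimensions and pixel size")
    return len(nuclei) / (area_um2 / 1e6)


def differentiation_index(assignment: RoiAssignment) -> float:
    """Nuclei inside eMHC-positive ROIs over all nuclei; 0 (with a warning)
    when the field holds no nuclei at all."""
    if assignment.total == 0:
        warnings.warn("no nuclei in field: differentiation index undefined, returning 0")
        return 0.0
    pos = assignment.counts.loc[assignment.counts["emhc_positive"], "n_nuclei"].sum()
    return float(pos) / assignment.total


def fusion_distribution(assignment: RoiAssignment) -> dict:
    """Nuclei-per-myotube distribution over eMHC-positive ROIs with >= 2 nuclei.

    Returns myotube_counts, median, log2(median) and the fractions of
    myotubes in the 2-14, 15-49 and >= 50 nuclei size classes.  An empty
    myotube set yields NaN summaries with a warning.
    """
    sub = assignment.counts
    counts = sub.loc[sub["emhc_positive"] & (sub["n_nuclei"] >= 2), "n_nuclei"]
    counts = counts.to_numpy(dtype=int)
    if counts.size == 0:
        warnings.warn("no eMHC-positive ROI holds >= 2 nuclei: fusion distribution undefined")
        return {
            "myotube_counts": [],
            "median_nuclei_per_myotube": math.nan,
            "log2_median": math.nan,
            "bin_fractions": {lab: math.nan for lab in BIN_LABELS},
        }
    median = float(np.median(counts))
    fractions = {}
    for (lo, hi), lab in zip(BIN_EDGES, BIN_LABELS):
        fractions[lab] = float(np.mean((counts >= lo) & (counts <= hi)))
    return {
        "myotube_counts": sorted(int(c) for c in counts),
        "median_nuclei_per_myotube": median,
        "log2_median": math.log2(median),
        "bin_fractions": fractions,
    }


# ---------------------------------------------------------------------------
# Two-group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    two_sided: bool = True


def _exact_ranksum_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided exact p for the rank-sum of group A by full enumeration of
    all C(n, n_a) assignments of the (midrank-tied) ranks to group A."""
    n = len(ranks)
    w_obs = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), n_a):
        w = float(ranks[list(combo)].sum())
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def _approx_ranksum_p(ranks: np.ndarray, values: np.ndarray, n_a: int) -> float:
    """Normal approximation with continuity and tie correction."""
    n = len(ranks)
    n_b = n - n_a
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * sps.norm.sf(z))


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   test_name: str = "wilcoxon_rank_sum",
                   welch: bool = False) -> GroupComparison:
    """Two-sided comparison of two independent samples.

    ``student_t``: pooled-variance two-sample t-test (Welch available behind
    the ``welch`` flag).  ``wilcoxon_rank_sum``: Mann-Whitney/Wilcoxon
    rank-sum with midrank ties; exact enumeration when n_a + n_b <= 12, else
    a continuity- and tie-corrected normal approximation.  The reported
    statistic is the t statistic, or the rank sum W of group A.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test_name == "student_t":
        if len(a) < 2 or len(b) < 2:
            raise ParameterError("student_t needs at least 2 values per group")
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            # degenerate: both groups constant
            equal = float(a.mean() == b.mean())
            return GroupComparison("student_t", 0.0 if equal else math.inf,
                                   1.0 if equal else 0.0, len(a), len(b))
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        return GroupComparison("student_t", float(t), float(p), len(a), len(b))
    if test_name == "wilcoxon_rank_sum":
        if len(a) < 1 or len(b) < 1:
            raise ParameterError("wilcoxon_rank_sum needs at least 1 value per group")
        combined = np.concatenate([a, b])
        ranks = sps.rankdata(combined)  # midranks for ties
        w = float(ranks[:len(a)].sum())
        if len(combined) <= EXACT_RANKSUM_LIMIT:
            p = _exact_ranksum_p(ranks, len(a))
        else:
            p = _approx_ranksum_p(ranks, combined, len(a))
        return GroupComparison("wilcoxon_rank_sum", w, min(p, 1.0), len(a), len(b))
    raise ParameterError(f"unknown test {test_name!r}")


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionReport:
    """All per-field fusion metrics, mutually consistent by construction."""

    total_nuclei: int
    imaged_area_mm2: float
    nuclei_density_per_mm2: float
    nuclei_in_emhc_positive: int
    differentiation_index: float
    myotube_counts: list
    median_nuclei_per_myotube: float
    log2_median: float
    bin_fractions: dict
    unassigned: int

    def to_dict(self) -> dict:
        return {
            "total_nuclei": self.total_nuclei,
            "imaged_area_mm2": self.imaged_area_mm2,
            "nuclei_density_per_mm2": self.nuclei_density_per_mm2,
            "nuclei_in_emhc_positive": self.nuclei_in_emhc_positive,
            "differentiation_index": self.differentiation_index,
            "myotube_counts": list(self.myotube_counts),
            "median_nuclei_per_myotube": self.median_nuclei_per_myotube,
            "log2_median": self.log2_median,
            "bin_fractions": dict(self.bin_fractions),
            "unassigned": self.unassigned,
        }


def build_fusion_report(nuclei: NucleusSet, rois: RoiSet) -> FusionReport:
    """Compose assignment, density, differentiation index and the fusion
    distribution into one report."""
    assignment = assign_nuclei_to_rois(nuclei, rois)
    area_mm2 = nuclei.width_px * nuclei.height_px * nuclei.pixel_size_um ** 2 / 1e6
    density = nuclei_density(nuclei)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        di = differentiation_index(assignment)
        dist = fusion_distribution(assignment)
    in_pos = int(assignment.counts.loc[assignment.counts["emhc_positive"], "n_nuclei"].sum())
    return FusionReport(
        total_nuclei=assignment.total,
        imaged_area_mm2=area_mm2,
        nuclei_density_per_mm2=density,
        nuclei_in_emhc_positive=in_pos,
        differentiation_index=di,
        myotube_counts=dist["myotube_counts"],
        median_nuclei_per_myotube=dist["median_nuclei_per_myotube"],
        log2_median=dist["log2_median"],
        bin_fractions=dist["bin_fractions"],
        unassigned=assignment.unassigned,
    )
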