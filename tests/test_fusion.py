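"""Fusion metrics: ROI assignment vs winding-number oracle, density and
index arithmetic, size-class bins, exact rank-sum enumeration, end-to-end
report recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from myofuse import (
    ParameterError,
    RenderParams,
    Roi,
    RoiSet,
    SceneParams,
    assign_nuclei_to_rois,
    build_fusion_report,
    compare_groups,
    differentiation_index,
    fusion_distribution,
    generate_scene,
    nuclei_density,
    render_scene,
    roi_set_from_scene,
    segment_nuclei,
)
from myofuse.fusion import GroupComparison
from myofuse.scene import GeometricShiftedSampler
from myofuse.segmentation import NucleusSet

from _oracles import permutation_ranksum_p, winding_number_inside


def _nucleus_set(points, width=100, height=100, px=1.0):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    df = pd.DataFrame({
        "label": np.arange(1, len(pts) + 1),
        "x": pts[:, 0], "y": pts[:, 1],
        "area_px": np.full(len(pts), 30, dtype=int),
    })
    return NucleusSet(df, width, height, px)


def _square_roi(roi_id=0, origin=(0.0, 0.0), side=10.0, emhc=True):
    x0, y0 = origin
    poly = np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])
    return Roi(id=roi_id, polygon=poly, emhc_positive=emhc)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def test_inside_and_outside_points_are_assigned_correctly():
    rois = RoiSet((_square_roi(),), 100, 100, 1.0)
    nuclei = _nucleus_set([(5, 5), (20, 20)])
    res = assign_nuclei_to_rois(nuclei, rois)
    assert res.counts["n_nuclei"].tolist() == [1]
    assert res.unassigned == 1
    assert res.counts["n_nuclei"].sum() + res.unassigned == res.total == 2


def test_zero_rois_leaves_everything_unassigned():
    rois = RoiSet((), 100, 100, 1.0)
    res = assign_nuclei_to_rois(_nucleus_set([(5, 5), (6, 6)]), rois)
    assert res.unassigned == 2


def test_boundary_centroid_counts_as_inside():
    rois = RoiSet((_square_roi(),), 100, 100, 1.0)
    res = assign_nuclei_to_rois(_nucleus_set([(10.0, 5.0)]), rois)
    assert res.counts["n_nuclei"].tolist() == [1]


def test_field_dimension_mismatch_rejected():
    rois = RoiSet((_square_roi(),), 50, 50, 1.0)
    with pytest.raises(ParameterError):
        assign_nuclei_to_rois(_nucleus_set([(5, 5)], width=100, height=100), rois)


def test_nucleus_in_overlapping_rois_goes_to_nearest_centroid():
    near = _square_roi(roi_id=0, origin=(0, 0), side=10)
    far = Roi(id=1, polygon=np.array([[0, 0], [40, 0], [40, 40], [0, 40]], dtype=float),
              emhc_positive=True)
    rois = RoiSet((near, far), 100, 100, 1.0)
    res = assign_nuclei_to_rois(_nucleus_set([(4.0, 4.0)]), rois)
    by_id = dict(zip(res.counts["roi_id"], res.counts["n_nuclei"]))
    assert by_id == {0: 1, 1: 0}


def test_assignment_matches_winding_number_oracle(rng):
    # 5 random simple (star-convex) polygons, 200 random points
    polys = []
    for i in range(5):
        center = rng.uniform(20, 80, size=2)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=9))
        radii = rng.uniform(5, 18, size=9)
        poly = np.column_stack([center[0] + radii * np.cos(angles),
                                center[1] + radii * np.sin(angles)])
        polys.append(Roi(id=i, polygon=poly, emhc_positive=True))
    rois = RoiSet(tuple(polys), 100, 100, 1.0)
    points = rng.uniform(0, 100, size=(200, 2))
    res = assign_nuclei_to_rois(_nucleus_set(points), rois)
    oracle_hits = sum(
        any(winding_number_inside(p, r.polygon) for r in polys) for p in points)
    assert res.total - res.unassigned == oracle_hits
    # per-point containment agrees where unambiguous (single containing ROI)
    for p in points:
        inside = [r.id for r in polys if winding_number_inside(p, r.polygon)]
        if len(inside) == 1:
            single = assign_nuclei_to_rois(_nucleus_set([p]), rois)
            by_id = dict(zip(single.counts["roi_id"], single.counts["n_nuclei"]))
            assert by_id[inside[0]] == 1


# ---------------------------------------------------------------------------
# Density and differentiation index
# ---------------------------------------------------------------------------

def test_density_in_a_one_mm2_field():
    # 1000 x 1000 px at 1 um/px = 1 mm^2
    pts = np.random.default_rng(0).uniform(0, 1000, size=(100, 2))
    nuclei = _nucleus_set(pts, width=1000, height=1000, px=1.0)
    assert nuclei_density(nuclei) == pytest.approx(100.0)


def test_density_scales_inversely_with_area():
    pts = [(5, 5)] * 0 + [(i, i) for i in range(10)]
    d1 = nuclei_density(_nucleus_set(pts, 100, 100, 1.0))
    d2 = nuclei_density(_nucleus_set(pts, 100, 100, 2.0))
    assert d1 == pytest.approx(4 * d2)


def test_density_equals_area_weighted_tile_mean(rng):
    pts = rng.uniform(0, 100, size=(60, 2))
    whole = nuclei_density(_nucleus_set(pts, 100, 100, 0.5))
    tiles = []
    for x0 in (0, 50):
        for y0 in (0, 50):
            sel = (pts[:, 0] >= x0) & (pts[:, 0] < x0 + 50) & \
                  (pts[:, 1] >= y0) & (pts[:, 1] < y0 + 50)
            tiles.append(nuclei_density(_nucleus_set(pts[sel], 50, 50, 0.5)))
    assert whole == pytest.approx(np.mean(tiles))


def test_differentiation_index_arithmetic():
    pos = _square_roi(0, (0, 0), 30, emhc=True)
    neg = _square_roi(1, (60, 60), 30, emhc=False)
    rois = RoiSet((pos, neg), 100, 100, 1.0)
    pts = [(5, 5), (10, 10), (15, 15), (65, 65), (90, 5), (5, 90),
           (20, 20), (25, 25), (28, 28), (70, 70), (80, 80), (95, 95)]
    # 6 of 12 inside the positive ROI
    res = assign_nuclei_to_rois(_nucleus_set(pts), rois)
    assert differentiation_index(res) == pytest.approx(6 / 12)


def test_differentiation_index_edge_cases():
    rois = RoiSet((_square_roi(emhc=True),), 100, 100, 1.0)
    all_in = assign_nuclei_to_rois(_nucleus_set([(2, 2), (5, 5)]), rois)
    assert differentiation_index(all_in) == 1.0
    neg_only = RoiSet((_square_roi(emhc=False),), 100, 100, 1.0)
    res = assign_nuclei_to_rois(_nucleus_set([(2, 2), (5, 5)]), neg_only)
    assert differentiation_index(res) == 0.0
    empty = assign_nuclei_to_rois(_nucleus_set([]), rois)
    with pytest.warns(UserWarning):
        assert differentiation_index(empty) == 0.0


# ---------------------------------------------------------------------------
# Fusion distribution
# ---------------------------------------------------------------------------

def _assignment_with_counts(counts, emhc=True):
    df = pd.DataFrame({
        "roi_id": range(len(counts)),
        "emhc_positive": [emhc] * len(counts),
        "n_nuclei": counts,
    })
    from myofuse.fusion import RoiAssignment
    return RoiAssignment(counts=df, unassigned=0, total=sum(counts))


def test_distribution_on_stated_example():
    dist = fusion_distribution(_assignment_with_counts([1, 2, 3, 50, 60]))
    assert dist["myotube_counts"] == [2, 3, 50, 60]
    assert dist["median_nuclei_per_myotube"] == pytest.approx(26.5)
    assert dist["bin_fractions"] == {"2-14": 0.5, "15-49": 0.0, "50+": 0.5}


def test_distribution_all_twos():
    dist = fusion_distribution(_assignment_with_counts([2, 2, 2]))
    assert dist["median_nuclei_per_myotube"] == 2
    assert dist["log2_median"] == pytest.approx(1.0)


def test_empty_myotube_set_warns_with_nan_summaries():
    with pytest.warns(UserWarning):
        dist = fusion_distribution(_assignment_with_counts([1, 1], emhc=True))
    assert dist["myotube_counts"] == []
    assert math.isnan(dist["median_nuclei_per_myotube"])


@pytest.mark.parametrize("seed", range(4))
def test_bins_partition_and_match_direct_enumeration(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(2, 80, size=25).tolist()
    dist = fusion_distribution(_assignment_with_counts(counts))
    fr = dist["bin_fractions"]
    assert sum(fr.values()) == pytest.approx(1.0)
    direct = {
        "2-14": sum(2 <= c <= 14 for c in counts) / len(counts),
        "15-49": sum(15 <= c <= 49 for c in counts) / len(counts),
        "50+": sum(c >= 50 for c in counts) / len(counts),
    }
    assert fr == pytest.approx(direct)


def test_median_monotone_under_count_increase(rng):
    counts = rng.integers(2, 40, size=15).tolist()
    base = fusion_distribution(_assignment_with_counts(counts))
    bumped = fusion_distribution(_assignment_with_counts([c + 3 for c in counts]))
    assert bumped["median_nuclei_per_myotube"] >= base["median_nuclei_per_myotube"]


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def test_t_test_identical_groups():
    res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "student_t")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_t_test_matches_closed_form():
    a, b = [4.1, 5.2, 6.0, 5.5], [2.0, 3.1, 2.5]
    res = compare_groups(a, b, "student_t")
    t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
    assert res.statistic == pytest.approx(float(t_ref))
    assert res.p_value == pytest.approx(float(p_ref))


def test_ranksum_exact_p_on_fully_separated_triples():
    res = compare_groups([1, 2, 3], [4, 5, 6], "wilcoxon_rank_sum")
    assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 splits as extreme


@pytest.mark.parametrize("seed", range(6))
def test_ranksum_exact_matches_permutation_oracle(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = rng.integers(2, 7, size=2)
    a = rng.integers(0, 8, size=n_a).astype(float)  # integer grid forces ties
    b = rng.integers(0, 8, size=n_b).astype(float)
    res = compare_groups(a, b, "wilcoxon_rank_sum")
    assert res.p_value == pytest.approx(permutation_ranksum_p(a, b))


def test_ranksum_large_sample_uses_normal_approximation():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 30)
    b = rng.normal(1, 1, 28)
    res = compare_groups(a, b, "wilcoxon_rank_sum")
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)


def test_comparison_input_validation():
    with pytest.raises(ParameterError):
        compare_groups([1.0], [2.0, 3.0], "student_t")
    with pytest.raises(ParameterError):
        compare_groups([], [1.0], "wilcoxon_rank_sum")
    with pytest.raises(ParameterError):
        compare_groups([1.0], [2.0], "median_test")


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def test_report_recovers_ground_truth_exactly(default_scene, noiseless_stack, default_rois):
    nuclei = segment_nuclei(noiseless_stack)
    report = build_fusion_report(nuclei, default_rois)
    assert report.total_nuclei == default_scene.total_nuclei
    assert report.myotube_counts == sorted(
        c for c in default_scene.nuclei_per_myotube if c >= 2)
    assert report.differentiation_index == pytest.approx(
        default_scene.true_differentiation_index)
    assert report.nuclei_in_emhc_positive <= report.total_nuclei
    assert report.nuclei_in_emhc_positive + report.unassigned == report.total_nuclei


def test_report_on_negative_mono_only_scene():
    scene = generate_scene(SceneParams(n_myotubes=0, n_mononucleated=12,
                                       fraction_mono_emhc_positive=0.0, seed=41))
    stack = render_scene(scene, RenderParams(psf_sigma_px=0, noise_model="none",
                                             background_level=0))
    report = build_fusion_report(segment_nuclei(stack), roi_set_from_scene(scene))
    assert report.differentiation_index == 0.0
    assert report.myotube_counts == []


def test_condition_difference_detected_by_rank_sum():
    """Simulated control (~5 nuclei/myotube) vs enhanced fusion (~15): the
    rank-sum comparison of 100-myotube samples separates them in >= 19/20
    seeds, and identical conditions stay near the nominal alpha."""
    rng_master = np.random.default_rng(99)
    low = GeometricShiftedSampler.from_mean(5.0)
    high = GeometricShiftedSampler.from_mean(15.0)
    detected = null_hits = 0
    n_rep = 20
    for i in range(n_rep):
        rng = np.random.default_rng(1000 + i)
        a = low.sample(rng, 100).astype(float)
        b = high.sample(rng, 100).astype(float)
        if compare_groups(a, b, "wilcoxon_rank_sum").p_value < 0.05:
            detected += 1
        a2 = low.sample(rng, 100).astype(float)
        b2 = low.sample(rng, 100).astype(float)
        if compare_groups(a2, b2, "wilcoxon_rank_sum").p_value < 0.05:
            null_hits += 1
    assert detected >= 19
    assert null_hits <= 3


def test_group_comparison_p_in_unit_interval(rng):
    for _ in range(5):
        a = rng.normal(0, 1, rng.integers(2, 10))
        b = rng.normal(0.5, 1, rng.integers(2, 10))
        for test in ("student_t", "wilcoxon_rank_sum"):
            res = compare_groups(a, b, test)
            assert isinstance(res, GroupComparison)
            assert 0.0 <= res.p_value <= 1.0
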