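"""Site calling, maxima merging, cluster selection, NND statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexpaint.designs import get_design, hexagon_coords
from hexpaint.paint_sim import AcquisitionParams, high_snr_params, simulate_acquisition
from hexpaint.pipeline import analyze, default_roi_params
from hexpaint.roi_detect import detect_rois
from hexpaint.site_quant import (
    SiteDetection,
    SiteParams,
    detect_sites,
    mean_nnd,
    merge_maxima,
    select_central_cluster,
    summarize_patterns,
)

from conftest import make_table


def brute_force_mean_nnd(pts):
    """Independent oracle: per-point nearest neighbour by explicit loops."""
    pts = np.asarray(pts, dtype=float)
    out = []
    for i in range(len(pts)):
        best = np.inf
        for j in range(len(pts)):
            if i != j:
                dx = pts[i, 0] - pts[j, 0]
                dy = pts[i, 1] - pts[j, 1]
                best = min(best, (dx * dx + dy * dy) ** 0.5)
        out.append(best)
    return float(np.mean(np.asarray(out)))


class TestMeanNnd:
    def test_full_hexagon_equals_edge(self):
        for e in (5.7, 11.1, 18.8, 37.0):
            assert mean_nnd(hexagon_coords(e, 0.7)) == pytest.approx(e, abs=1e-9)

    def test_alternate_vertices_equal_edge_times_sqrt3(self):
        e = 9.43
        tri = hexagon_coords(e, 0.2)[[0, 2, 4]]
        assert mean_nnd(tri) == pytest.approx(e * np.sqrt(3.0), abs=1e-9)
        assert brute_force_mean_nnd(tri) == pytest.approx(e * np.sqrt(3.0), abs=1e-9)

    def test_two_points(self):
        assert mean_nnd([[0.0, 0.0], [3.0, 4.0]]) == 5.0

    def test_fewer_than_two_points_errors(self):
        with pytest.raises(ValueError):
            mean_nnd(np.zeros((1, 2)))

    @settings(derandomize=True, max_examples=50)
    @given(
        pts=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=2,
            max_size=12,
            unique=True,
        )
    )
    def test_matches_brute_force_oracle_exactly(self, pts):
        assert mean_nnd(np.array(pts)) == brute_force_mean_nnd(pts)


class TestMergeMaxima:
    def test_separated_points_unchanged(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        out, w = merge_maxima(pts, 5.0)
        np.testing.assert_array_equal(np.sort(out, axis=0), np.sort(pts, axis=0))
        np.testing.assert_array_equal(w, 1.0)

    def test_equal_weight_pair_merges_to_midpoint(self):
        out, w = merge_maxima(np.array([[0.0, 0.0], [0.8, 0.0]]), 1.0)
        np.testing.assert_allclose(out, [[0.4, 0.0]])
        assert w[0] == 2.0

    def test_weighted_pair_merges_to_weighted_centroid(self):
        out, _ = merge_maxima(
            np.array([[0.0, 0.0], [1.0, 0.0]]), 2.0, weights=np.array([3.0, 1.0])
        )
        np.testing.assert_allclose(out, [[0.25, 0.0]])

    def test_three_collinear_close_points(self):
        """Spacing 0.6 x threshold: closest pair merges first, the result
        re-merges until all pairwise distances clear the threshold."""
        pts = np.array([[0.0, 0.0], [0.6, 0.0], [1.2, 0.0]])
        out, w = merge_maxima(pts, 1.0)
        assert w.sum() == 3.0
        if len(out) > 1:
            d = np.linalg.norm(out[0] - out[1])
            assert d >= 1.0

    @settings(derandomize=True, max_examples=50)
    @given(
        pts=st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
            min_size=1,
            max_size=10,
        ),
        min_dist=st.floats(0.1, 20.0),
    )
    def test_postcondition_no_close_pair_and_weight_conserved(self, pts, min_dist):
        pts = np.array(pts)
        out, w = merge_maxima(pts, min_dist)
        assert w.sum() == pytest.approx(len(pts))
        if len(out) > 1:
            d = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= min_dist - 1e-9

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValueError):
            merge_maxima(np.zeros((2, 2)), 0.0)


class TestSelectCentralCluster:
    def test_all_points_within_linkage_kept(self):
        pts = hexagon_coords(10.0)
        out = select_central_cluster(pts, (0.0, 0.0), 21.0)
        assert len(out) == 6

    def test_stray_point_dropped(self):
        pts = np.vstack([hexagon_coords(10.0), [[120.0, 0.0]]])
        out = select_central_cluster(pts, (0.0, 0.0), 21.0)
        assert len(out) == 6
        assert not any(np.allclose(p, [120.0, 0.0]) for p in out)

    def test_count_ties_broken_by_centrality(self):
        pts = np.array([[2.0, 0.0], [50.0, 0.0]])
        out = select_central_cluster(pts, (0.0, 0.0), 5.0)
        np.testing.assert_allclose(out, [[2.0, 0.0]])

    def test_requires_at_least_one_point(self):
        with pytest.raises(ValueError):
            select_central_cluster(np.zeros((0, 2)), (0.0, 0.0), 5.0)


def _roi_for(table, expected_per_site):
    rois = [r for r in detect_rois(table, default_roi_params(expected_per_site)) if r.qc_pass]
    assert rois
    return rois


class TestDetectSites:
    def test_full_w16_roi_yields_six_sites(self, w16_scene):
        table = w16_scene["table"]
        roi = _roi_for(table, w16_scene["expected_per_site"])[0]
        det = detect_sites(table, roi, w16_scene["design"])
        assert det.n_sites == 6
        assert det.mean_nnd_nm == pytest.approx(15.8, rel=0.08)

    def test_single_site_roi_has_undefined_nnd(self):
        design = get_design("W16")
        rng = np.random.default_rng(1)
        n = 300
        table = make_table(
            frame=np.linspace(0, 11999, n).astype(int),
            x=8.0 + rng.normal(0, 1.0 / 87.0, n),
            y=8.0 + rng.normal(0, 1.0 / 87.0, n),
            fov_px=[16, 16],
            n_frames=12000,
        )
        roi = detect_rois(table)[0]
        det = detect_sites(table, roi, design)
        assert det.n_sites == 1
        assert det.mean_nnd_nm is None

    def test_two_sites_below_merge_distance_merge_to_one(self):
        """Two point clouds planted 0.4 x edge apart collapse to one site."""
        design = get_design("W16")
        sep_px = 0.4 * design.nominal_edge_nm / 87.0
        rng = np.random.default_rng(2)
        n = 200
        x = np.concatenate([8.0 + rng.normal(0, 1 / 87, n), 8.0 + sep_px + rng.normal(0, 1 / 87, n)])
        y = np.concatenate([8.0 + rng.normal(0, 1 / 87, n), 8.0 + rng.normal(0, 1 / 87, n)])
        table = make_table(
            frame=np.linspace(0, 11999, 2 * n).astype(int),
            x=x, y=y, fov_px=[16, 16], n_frames=12000,
        )
        roi = detect_rois(table)[0]
        det = detect_sites(table, roi, design)
        assert det.n_sites == 1

    def test_invariant_to_roi_wide_translation(self, w16_scene):
        """Shifting the table and the ROI centre together leaves the
        ROI-local site coordinates unchanged (whole-pixel shift keeps the
        rendering grid aligned)."""
        import copy

        from hexpaint.loc_io import LocalizationTable

        table = w16_scene["table"]
        roi = _roi_for(table, w16_scene["expected_per_site"])[0]
        det = detect_sites(table, roi, w16_scene["design"])

        shifted = LocalizationTable(table.df.copy(), dict(table.metadata))
        shifted.df["x"] += 1.0
        shifted.df["y"] -= 1.0
        roi2 = copy.copy(roi)
        roi2.center_px = roi.center_px + np.array([1.0, -1.0])
        det2 = detect_sites(shifted, roi2, w16_scene["design"])
        assert det2.n_sites == det.n_sites
        np.testing.assert_allclose(det2.site_coords_nm, det.site_coords_nm, atol=1e-9)

    def test_empty_roi_errors(self, w16_scene):
        table = w16_scene["table"]
        roi = _roi_for(table, w16_scene["expected_per_site"])[0]
        import copy

        empty = copy.copy(roi)
        empty.member_indices = np.array([], dtype=int)
        with pytest.raises(ValueError, match="no member"):
            detect_sites(table, empty, w16_scene["design"])


class TestSummarizePatterns:
    @staticmethod
    def _det(n):
        pts = hexagon_coords(15.8)[:n] if n else np.zeros((0, 2))
        return SiteDetection(0, pts, n, mean_nnd(pts) if n >= 2 else None)

    def test_occupancy_arithmetic(self):
        summary = summarize_patterns(
            [self._det(n) for n in (6, 5, 4, 6)], get_design("W16")
        )
        assert summary.occupancy_estimate == pytest.approx(21 / 24)
        assert summary.sites_per_roi == {6: 2, 5: 1, 4: 1}
        assert summary.n_rois == 4

    def test_full_detections_give_unity(self):
        summary = summarize_patterns([self._det(6)] * 5, get_design("W16"))
        assert summary.occupancy_estimate == 1.0
        assert summary.mean_nnd_nm == pytest.approx(15.8, abs=1e-9)

    def test_counts_above_six_capped_for_occupancy(self):
        det7 = SiteDetection(0, np.random.default_rng(0).normal(size=(7, 2)) * 50, 7, 1.0)
        summary = summarize_patterns([det7], get_design("W16"))
        assert summary.occupancy_estimate == 1.0
        assert summary.sites_per_roi == {7: 1}

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_patterns([], get_design("W16"))


class TestPipelineRecovery:
    """Parameter recovery of the full filter -> ROI -> site pipeline."""

    @pytest.mark.parametrize("occupancy", [0.5, 0.75, 1.0])
    @pytest.mark.parametrize("name", ["W6", "W16", "L11"])
    def test_occupancy_recovery_grid(self, name, occupancy):
        from hexpaint.paint_sim import expected_locs_per_site, fov_for

        design = get_design(name)
        acq = AcquisitionParams(fov_px=fov_for(110))
        kin = high_snr_params()
        table, _ = simulate_acquisition(design, 110, occupancy, acq, kin, seed=29)
        res = analyze(
            table, design,
            roi_params=default_roi_params(expected_locs_per_site(acq, kin)),
        )
        assert res.summary.n_rois >= 100 or occupancy < 0.6
        assert res.summary.occupancy_estimate == pytest.approx(occupancy, abs=0.05)

    @pytest.mark.parametrize(
        "name", ["W6", "W9", "W16", "W19", "W26", "L6", "L11", "W37"]
    )
    def test_edge_recovery_all_designs(self, name):
        """At full occupancy the mean per-ROI mean NND reproduces every
        registered design edge within 5% (high-SNR regime)."""
        from hexpaint.paint_sim import expected_locs_per_site, fov_for

        design = get_design(name)
        acq = AcquisitionParams(fov_px=fov_for(60))
        kin = high_snr_params()
        table, _ = simulate_acquisition(design, 60, 1.0, acq, kin, seed=31)
        res = analyze(
            table, design,
            roi_params=default_roi_params(expected_locs_per_site(acq, kin)),
        )
        assert res.summary.mean_nnd_nm == pytest.approx(
            design.nominal_edge_nm, rel=0.05
        )
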