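"""Quality filters and RCC drift correction."""

import numpy as np
import pandas as pd
import pytest

from hexpaint.loc_filter import (
    FilterParams,
    apply_drift,
    estimate_drift,
    filter_localizations,
    remove_fiducials,
)

from conftest import make_table


@pytest.fixture
def five_row_table():
    """Hand-checkable fixture: row 1 fails ellipticity, row 2 fails
    precision, row 4 has 10000 photons but survives the photon rule
    (mean 2080 + 2 x SD 4427 = 10934)."""
    return make_table(
        frame=[0, 1, 2, 3, 4],
        x=[1.0, 2.0, 3.0, 4.0, 5.0],
        y=[1.0, 2.0, 3.0, 4.0, 5.0],
        precision=[0.01, 0.01, 0.05, 0.01, 0.01],
        ellipticity=[0.9, 0.05, 0.9, 0.9, 0.9],
        photons=[100.0, 100.0, 100.0, 100.0, 10000.0],
        n_frames=10,
    )


class TestFilterRules:
    def test_hand_applied_outcome(self, five_row_table):
        filtered, report = filter_localizations(five_row_table)
        assert report.photon_mean == pytest.approx(2080.0)
        assert report.photon_sd == pytest.approx(4427.0, abs=0.5)
        assert list(filtered.df["frame"]) == [0, 3, 4]
        assert report.n_input == 5
        assert report.n_removed == 2
        assert report.n_retained == 3
        assert report.removed_low_precision == 1
        assert report.removed_asymmetric == 1
        assert report.removed_multilocalization == 0

    def test_high_precision_value_removed(self):
        # precision 0.05 px exceeds the 0.03 camera-pixel cut
        table = make_table(frame=[0, 1], x=[1, 2], y=[1, 2], precision=[0.05, 0.02])
        filtered, _ = filter_localizations(table)
        assert list(filtered.df["precision"]) == [0.02]

    def test_equal_photons_never_trip_photon_rule(self):
        table = make_table(frame=range(4), x=range(4), y=range(4), photons=[777.0] * 4)
        filtered, report = filter_localizations(table)
        assert report.n_removed == 0
        assert len(filtered) == 4

    def test_survivor_rows_unchanged_and_ordered(self, five_row_table):
        filtered, _ = filter_localizations(five_row_table)
        surv = five_row_table.df.iloc[[0, 3, 4]].reset_index(drop=True)
        pd.testing.assert_frame_equal(filtered.df, surv)

    def test_idempotent_with_frozen_photon_stats(self, five_row_table):
        filtered, report = filter_localizations(five_row_table)
        again, report2 = filter_localizations(
            filtered, photon_stats=(report.photon_mean, report.photon_sd)
        )
        pd.testing.assert_frame_equal(again.df, filtered.df)
        assert report2.n_removed == 0

    def test_empty_input_is_not_an_error(self):
        table = make_table(frame=[], x=[], y=[])
        filtered, report = filter_localizations(table)
        assert len(filtered) == 0
        assert report.n_input == report.n_removed == report.n_retained == 0

    def test_remove_fiducials_radius_mask(self):
        table = make_table(frame=[0, 1, 2], x=[5.0, 5.5, 20.0], y=[5.0, 5.0, 20.0])
        out = remove_fiducials(table, np.array([[5.0, 5.0]]), radius_px=1.0)
        assert list(out.df["x"]) == [20.0]

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            FilterParams(precision_max_px=-0.01)


class TestDriftCorrection:
    def test_linear_drift_recovered_end_to_end(self, drifted_scene):
        """Injected 0.002 px/frame drift over 12000 frames: the estimated
        trace must recover the ~24 px end-to-end displacement within 10%."""
        table = drifted_scene["table"]
        trace = estimate_drift(table, 200)
        est = trace[-1] - trace[0]
        true = np.array([0.002, -0.001]) * (table.n_frames - 1)
        assert np.all(np.abs(est - true) <= 0.1 * np.abs(true))

    def test_trace_gauge_zero_mean(self, drifted_scene):
        trace = estimate_drift(drifted_scene["table"], 200)
        np.testing.assert_allclose(trace.mean(axis=0), 0.0, atol=1e-9)

    def test_null_case_trace_small(self, w16_scene):
        """Drift-free scene: the estimated trace stays within the RCC noise
        floor (a few hundredths of a camera pixel)."""
        trace = estimate_drift(w16_scene["table"], 200)
        assert np.abs(trace).max() < 0.1

    def test_apply_zero_trace_is_identity(self, w16_scene):
        table = w16_scene["table"]
        out = apply_drift(table, np.zeros((table.n_frames, 2)))
        pd.testing.assert_frame_equal(
            out.df[["x", "y"]], table.df[["x", "y"]]
        )

    def test_apply_then_apply_negated_restores(self, drifted_scene):
        table = drifted_scene["table"]
        trace = estimate_drift(table, 200)
        back = apply_drift(apply_drift(table, trace), -trace)
        np.testing.assert_allclose(back.df["x"], table.df["x"], atol=1e-12)
        np.testing.assert_allclose(back.df["y"], table.df["y"], atol=1e-12)

    def test_correction_tightens_site_spread(self, drifted_scene):
        """After correction each site's localization SD approaches the 1 nm
        simulated precision instead of the many-nm drift smear."""
        table, truth = drifted_scene["table"], drifted_scene["truth"]
        trace = estimate_drift(table, 200)
        corrected = apply_drift(table, trace)
        px = table.camera_pixel_nm
        sources = truth.sources
        sel = (sources["kind"] == "site").to_numpy()
        key = sources.loc[sel, ["structure_id", "site_index"]]
        raw_sd = []
        corr_sd = []
        for df, store in ((table.df, raw_sd), (corrected.df, corr_sd)):
            sub = df.loc[sel, ["x", "y"]].copy()
            sub["sid"] = key["structure_id"].to_numpy()
            sub["site"] = key["site_index"].to_numpy()
            sd = sub.groupby(["sid", "site"])[["x", "y"]].std(ddof=1)
            store.append(float(sd.mean().mean() * px))
        assert corr_sd[0] < 0.2 * raw_sd[0]
        assert corr_sd[0] < 5.0  # nm; near the simulated 1 nm precision

    def test_estimate_equivariant_under_rigid_translation(self, drifted_scene):
        """A time-constant rigid translation changes no relative fragment
        offsets, so the gauge-fixed trace is unchanged."""
        from hexpaint.loc_io import LocalizationTable

        table = drifted_scene["table"]
        base = estimate_drift(table, 200)
        shifted = LocalizationTable(table.df.copy(), dict(table.metadata))
        shifted.df["x"] += 2.0
        shifted.df["y"] += 1.0
        moved = estimate_drift(shifted, 200)
        np.testing.assert_allclose(moved, base, atol=0.02)

    def test_too_few_frames_errors(self):
        table = make_table(frame=[0, 50], x=[1.0, 1.0], y=[1.0, 1.0], n_frames=100)
        with pytest.raises(ValueError, match="fragment"):
            estimate_drift(table, 200)

    def test_frame_outside_trace_errors(self, w16_scene):
        table = w16_scene["table"]
        with pytest.raises(ValueError, match="cover"):
            apply_drift(table, np.zeros((10, 2)))
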