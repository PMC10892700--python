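import numpy as np
import pandas as pd
import pytest

from conftest import grid_layout, make_recording
from ergofield import plantar
from ergofield.io import SchemaError, ValidationError, window


def loop_region_metrics(rec, masks, thresh=0.6, min_frac=0.01):
    """Naive per-sensor loop oracle for all five region metrics."""
    out = {}
    dt = rec.dt
    n = rec.n_frames
    for name, idx in masks.items():
        means, peaks, imps, fracs, loaded_sensors = [], [], [], [], 0
        for j in idx:
            trace = rec.pressures[:, j]
            loaded = trace >= thresh
            means.append(trace[loaded].mean() if loaded.any() else 0.0)
            peaks.append(trace.max())
            imps.append(sum(p * dt for p in trace))
            fracs.append(loaded.sum() / n)
            if loaded.sum() / n >= min_frac:
                loaded_sensors += 1
        out[name] = dict(
            mean_pressure=float(np.mean(means)),
            peak_pressure=float(np.mean(peaks)),
            impulse=float(np.mean(imps)),
            loaded_time_fraction=float(np.mean(fracs)),
            loaded_sensor_pct=100.0 * loaded_sensors / len(idx))
    return out


class TestCalibration:
    def test_baseline_equal_to_recording_zeroes_output(self, rng):
        P = rng.uniform(0, 5, (30, 6))
        base = make_recording(np.tile(P.mean(axis=0), (10, 1)))
        rec = make_recording(np.tile(P.mean(axis=0), (30, 1)),
                             layout=base.layout)
        out = plantar.zero_calibrate(rec, base)
        np.testing.assert_allclose(out.pressures, 0.0, atol=1e-12)

    def test_zero_baseline_is_identity(self, rng):
        rec = make_recording(rng.uniform(0, 5, (30, 6)))
        base = make_recording(np.zeros((10, 6)), layout=rec.layout)
        out = plantar.zero_calibrate(rec, base)
        np.testing.assert_array_equal(out.pressures, rec.pressures)

    def test_constant_offset_subtracted_and_clamped(self):
        rec = make_recording(np.full((5, 3), 2.0))
        base = make_recording(np.full((4, 3), 0.5), layout=rec.layout)
        out = plantar.zero_calibrate(rec, base)
        np.testing.assert_allclose(out.pressures, 1.5)
        big_base = make_recording(np.full((4, 3), 3.0), layout=rec.layout)
        np.testing.assert_allclose(
            plantar.zero_calibrate(rec, big_base).pressures, 0.0)

    def test_layout_mismatch_rejected(self, rng):
        rec = make_recording(rng.uniform(0, 5, (10, 6)))
        base = make_recording(np.zeros((5, 4)))
        with pytest.raises(SchemaError):
            plantar.zero_calibrate(rec, base)


class TestExclusion:
    @pytest.mark.parametrize("size,k", [(39, 3), (41, 4), (43, 4), (45, 5)])
    def test_exclusion_count_by_shoe_size(self, size, k, rng):
        rec = make_recording(rng.uniform(0, 5, (10, 20)), layout=grid_layout(5, 4))
        out = plantar.exclude_rear_lateral(rec, size)
        assert len(out.excluded) == k

    def test_most_posterior_lateral_sensors_chosen(self, rng):
        layout = grid_layout(5, 4)
        rec = make_recording(rng.uniform(0, 5, (10, 20)), layout=layout)
        out = plantar.exclude_rear_lateral(rec, 39)
        picked = layout.iloc[sorted(out.excluded)]
        # all picked sensors lie in the most posterior row, lateral first
        assert (picked["length_pct"] == layout["length_pct"].min()).all()
        assert picked["width_pct"].min() > layout["width_pct"].min()

    def test_unsupported_size_rejected(self, rng):
        rec = make_recording(rng.uniform(0, 5, (5, 8)))
        with pytest.raises(ValidationError):
            plantar.exclude_rear_lateral(rec, 40)

    def test_excluded_sensors_contribute_nothing(self, rng):
        layout = grid_layout(6, 5)
        P = rng.uniform(0, 10, (50, 30))
        rec = plantar.exclude_rear_lateral(
            make_recording(P, layout=layout), 45)
        masks = plantar.assign_regions(layout, rec.excluded)
        got = plantar.region_metrics(rec, masks)
        P2 = P.copy()
        P2[:, sorted(rec.excluded)] = 0.0  # hard-zero the excluded sensors
        rec2 = make_recording(P2, layout=layout, excluded=rec.excluded)
        got2 = plantar.region_metrics(rec2, masks)
        pd.testing.assert_frame_equal(got, got2)


class TestRegions:
    def test_canonical_assignments(self):
        layout = pd.DataFrame({
            "sensor_id": ["a", "b", "c", "d", "e"],
            "length_pct": [15.0, 70.0, 30.0, 45.0, 95.0],
            "width_pct": [50.0, 60.0, 61.0, 10.0, 90.0]})
        masks = plantar.assign_regions(layout)
        assert 0 in masks["rearfoot"]
        assert 1 in masks["metatarsal_heads"]
        assert 2 in masks["rearfoot"]          # exactly 30% -> upper-closed
        assert 3 in masks["midfoot"]
        assert 4 in masks["forefoot"]
        assert 0 in masks["inner_foot"] and 1 in masks["inner_foot"]  # 60% closed
        assert 2 in masks["outer_foot"] and 4 in masks["outer_foot"]

    def test_masks_partition_active_sensors(self, rng):
        layout = grid_layout(8, 6)
        excluded = frozenset({0, 7, 13})
        masks = plantar.assign_regions(layout, excluded)
        n_active = len(layout) - len(excluded)
        long_members = sum(len(masks[r]) for r in plantar.LENGTH_REGIONS)
        wide_members = sum(len(masks[r]) for r in plantar.WIDTH_REGIONS)
        assert long_members == n_active == wide_members
        all_long = np.concatenate([masks[r] for r in plantar.LENGTH_REGIONS])
        assert len(set(all_long)) == n_active
        assert not set(all_long) & excluded


class TestImpulse:
    def test_constant_trace(self):
        assert plantar.sensor_impulse(np.full(300, 2.0), dt=0.01) == pytest.approx(6.0)
        assert plantar.sensor_impulse(np.zeros(100), dt=0.01) == 0.0

    def test_random_trace_matches_direct_sum(self, rng):
        trace = rng.uniform(0, 30, 777)
        expected = sum(p * 0.01 for p in trace)
        assert plantar.sensor_impulse(trace, 0.01) == pytest.approx(expected, rel=1e-12)

    def test_additivity_over_windows(self, rng):
        rec = make_recording(rng.uniform(0, 20, (400, 5)), rate=100.0)
        full = plantar.region_metrics(rec, {"all": np.arange(5)})
        a = plantar.region_metrics(window(rec, 0, 2), {"all": np.arange(5)})
        b = plantar.region_metrics(window(rec, 2, 4), {"all": np.arange(5)})
        assert full.loc["all", "impulse"] == pytest.approx(
            a.loc["all", "impulse"] + b.loc["all", "impulse"], rel=1e-9)

    def test_linear_in_pressure_and_dt(self, rng):
        trace = rng.uniform(0, 10, 100)
        assert plantar.sensor_impulse(2 * trace, 0.01) == pytest.approx(
            2 * plantar.sensor_impulse(trace, 0.01))
        assert plantar.sensor_impulse(trace, 0.02) == pytest.approx(
            2 * plantar.sensor_impulse(trace, 0.01))


class TestRegionMetrics:
    def test_single_sensor_arithmetic(self):
        rec = make_recording(np.array([[0.0], [4.0], [2.0]]), rate=100.0)
        m = plantar.region_metrics(rec, {"only": np.array([0])})
        assert m.loc["only", "peak_pressure"] == 4.0
        assert m.loc["only", "impulse"] == pytest.approx(0.06)
        assert m.loc["only", "mean_pressure"] == pytest.approx(3.0)  # loaded frames
        assert m.loc["only", "loaded_time_fraction"] == pytest.approx(2 / 3)

    def test_uniform_field_mean_equals_peak(self):
        layout = grid_layout(5, 4)
        rec = make_recording(np.full((50, 20), 7.0), layout=layout)
        m = plantar.region_metrics(rec)
        assert (m["mean_pressure"] == 7.0).all()
        assert (m["peak_pressure"] == 7.0).all()
        assert (m["loaded_sensor_pct"] == 100.0).all()

    def test_peak_at_least_mean_everywhere(self, rng):
        rec = make_recording(rng.uniform(0, 30, (100, 24)), layout=grid_layout(6, 4))
        m = plantar.region_metrics(rec)
        assert (m["peak_pressure"] >= m["mean_pressure"] - 1e-12).all()

    def test_random_field_matches_loop_oracle(self, rng):
        layout = grid_layout(7, 5)
        rec = make_recording(rng.uniform(0, 30, (120, 35)) *
                             (rng.random((120, 35)) > 0.3), layout=layout)
        masks = plantar.assign_regions(layout)
        got = plantar.region_metrics(rec, masks)
        expected = loop_region_metrics(rec, masks)
        for region in got.index:
            for col in got.columns:
                assert got.loc[region, col] == pytest.approx(
                    expected[region][col], rel=1e-9, abs=1e-12), (region, col)

    def test_empty_region_is_error(self, rng):
        rec = make_recording(rng.uniform(0, 5, (10, 4)))
        with pytest.raises(ValidationError, match="nowhere"):
            plantar.region_metrics(rec, {"nowhere": np.array([], dtype=int)})

    def test_mirrored_layout_is_side_symmetric(self, rng):
        layout = grid_layout(6, 5)
        P = rng.uniform(0, 30, (80, 30))
        rec = make_recording(P, layout=layout, side="left")
        mirrored = layout.copy()
        mirrored["width_pct"] = 100.0 - mirrored["width_pct"]
        rec_m = make_recording(P, layout=mirrored, side="right")
        m = plantar.region_metrics(rec, plantar.assign_regions(layout))
        m_m = plantar.region_metrics(rec_m, plantar.assign_regions(mirrored))
        for region in plantar.LENGTH_REGIONS:  # width-symmetric regions
            pd.testing.assert_series_equal(m.loc[region], m_m.loc[region])


class TestContrast:
    def test_signed_differences(self):
        pre = pd.DataFrame({"impulse": [13.48, 12.75]},
                           index=pd.Index(["metatarsal_heads", "midfoot"],
                                          name="region"))
        post = pd.DataFrame({"impulse": [15.45, 12.05]}, index=pre.index)
        d = plantar.contrast(pre, post)
        assert d.loc["metatarsal_heads", "impulse"] == pytest.approx(1.97)
        assert d.loc["midfoot", "impulse"] == pytest.approx(-0.70)

    def test_identical_metrics_give_zero(self, rng):
        rec = make_recording(rng.uniform(0, 10, (30, 20)), layout=grid_layout(5, 4))
        m = plantar.region_metrics(rec)
        assert (plantar.contrast(m, m) == 0).all().all()

    def test_region_set_mismatch_rejected(self):
        a = pd.DataFrame({"impulse": [1.0]}, index=["rearfoot"])
        b = pd.DataFrame({"impulse": [1.0]}, index=["midfoot"])
        with pytest.raises(SchemaError):
            plantar.contrast(a, b)
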