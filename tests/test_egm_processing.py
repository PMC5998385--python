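"""Electrogram-processing tests: LAT detection, piecewise-linear CV
estimation, physiological filtering and ERP extraction."""

import numpy as np
import pytest

from atriafit.egm_processing import (ElectrodeRecording, CatheterSnapshot,
                                     cv_from_lats, detect_lat, estimate_erp,
                                     filter_physiological,
                                     read_electrode_table,
                                     write_electrode_table)


def _wavelet(t, centre, width=5.0):
    """Biphasic test deflection: first extremum (a peak) at centre - width/2."""
    z = (t - centre) / width
    return -np.gradient(np.exp(-(z ** 2)), t)


class TestDetectLat:
    def test_flat_trace_has_no_activation(self):
        t = np.arange(0.0, 200.0, 1.0)
        assert detect_lat(t, np.zeros_like(t), (0, 200)) is None

    def test_first_extremum_of_biphasic_wavelet(self):
        t = np.arange(0.0, 300.0, 0.5)
        v = _wavelet(t, 120.5, width=2.5)
        lat = detect_lat(t, v, (100, 150), threshold=0.01)
        # analytic first extremum of -d/dt exp(-z^2): centre - width/sqrt(2)
        assert lat == pytest.approx(120.5 - 2.5 / np.sqrt(2), abs=0.5)

    def test_valley_before_peak_returns_valley_time(self):
        t = np.arange(0.0, 100.0, 1.0)
        v = np.zeros_like(t)
        v[30] = -1.0  # valley first
        v[60] = 0.5   # later peak
        assert detect_lat(t, v, (0, 100), threshold=0.1) == 30.0

    def test_subthreshold_extrema_ignored(self):
        t = np.arange(0.0, 100.0, 1.0)
        v = np.zeros_like(t)
        v[40] = 0.05
        assert detect_lat(t, v, (0, 100), threshold=0.1) is None

    def test_empty_window_is_an_error(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            detect_lat(t, np.zeros_like(t), (50, 50))
        with pytest.raises(ValueError):
            detect_lat(t, np.zeros_like(t), (500, 600))


def _pentaray_layout():
    """10 positions resembling two bipoles on each of five splines (mm)."""
    pos = []
    for s in range(5):
        ang = np.radians(72 * s)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        pos.append(4.0 * u)
        pos.append(12.0 * u)
    return np.array(pos)


class TestCVField:
    def test_planar_wave_recovered_exactly(self):
        pos = _pentaray_layout()
        for v_cm_s in (30.0, 80.0, 150.0):
            v_mm_ms = v_cm_s / 100.0
            lats = pos[:, 0] / v_mm_ms
            cv = cv_from_lats(pos, lats)
            assert cv == pytest.approx(np.full(10, v_cm_s), rel=1e-9)

    def test_planar_wave_on_tilted_plane_in_3d(self):
        """Positions off the coordinate planes: the best-fit-plane projection
        must not distort an affine LAT field."""
        pos = _pentaray_layout()
        rot = np.array([[0.8, -0.6, 0.0], [0.36, 0.48, -0.8], [0.48, 0.64, 0.6]])
        pos3 = pos @ rot.T + np.array([5.0, -3.0, 11.0])
        lats = pos[:, 0] / 0.7  # planar wave in the intrinsic frame
        cv = cv_from_lats(pos3, lats)
        assert cv == pytest.approx(np.full(10, 70.0), rel=1e-9)

    def test_constant_lat_yields_no_cv(self):
        pos = _pentaray_layout()
        cv = cv_from_lats(pos, np.full(10, 42.0))
        assert np.all(np.isnan(cv))

    def test_radial_wave_within_ten_percent(self):
        pos = _pentaray_layout()
        focus = np.array([40.0, 0.0, 0.0])
        v_cm_s = 60.0
        lats = np.linalg.norm(pos - focus, axis=1) / (v_cm_s / 100.0)
        cv = cv_from_lats(pos, lats)
        assert np.all(np.abs(cv - v_cm_s) / v_cm_s < 0.10)

    def test_collinear_layout_is_an_error(self):
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            cv_from_lats(pos, np.arange(5.0))

    def test_single_corrupt_electrode_is_contained_by_the_median(self):
        pos = _pentaray_layout()
        lats = pos[:, 0] / 0.8
        clean = cv_from_lats(pos, lats)
        corrupt = lats.copy()
        corrupt[3] += 50.0
        dirty = cv_from_lats(pos, corrupt)
        others = np.arange(10) != 3
        rel = np.abs(dirty[others] - clean[others]) / clean[others]
        assert np.all(rel < 0.15)


def test_filter_physiological():
    cv = np.array([50.0, 150.0, 250.0])
    out = filter_physiological(cv)
    assert out[0] == 50.0 and out[1] == 150.0 and np.isnan(out[2])
    cv2 = np.array([10.0, 199.9, 200.0])
    assert np.array_equal(filter_physiological(cv2), cv2)


def test_cutoff_rule_reproduces_the_round_number():
    """The published cut-off came from rounding mean + 2 SD of the pooled
    CV distribution; on a synthetic population with the published moments
    the same rule lands on a round 160."""
    rng = np.random.default_rng(11)
    pop = rng.normal(88.0, 35.0, 50_000)
    cutoff = round((pop.mean() + 2 * pop.std()) / 10.0) * 10.0
    assert cutoff == 160.0


class TestEstimateERP:
    def test_largest_non_capturing_interval(self):
        s2 = np.array([343.0, 300.0, 260.0, 230.0, 210.0])
        captured = np.array([True, True, True, False, False])
        assert estimate_erp(s2, captured) == 230.0

    def test_capture_everywhere_censors_the_erp(self):
        s2 = np.array([343.0, 300.0, 260.0])
        assert np.isnan(estimate_erp(s2, np.array([True, True, True])))

    def test_non_monotone_pattern_warns_but_applies_definition(self):
        s2 = np.array([343.0, 300.0, 260.0, 230.0])
        captured = np.array([True, False, True, False])
        with pytest.warns(UserWarning):
            erp = estimate_erp(s2, captured)
        assert erp == 300.0


def test_electrode_table_round_trip(tmp_path):
    recs = [
        ElectrodeRecording(
            electrode_id=k,
            position_mm=np.array([k * 2.0, 1.0, 0.5]),
            s2_values_ms=np.array([343.0, 300.0]),
            lats_ms=np.array([510.0 + k, np.nan]),
            captured=np.array([True, False]),
        )
        for k in range(3)
    ]
    path = tmp_path / "recordings.csv"
    write_electrode_table(recs, path)
    back = read_electrode_table(path)
    assert len(back) == 3
    for a, b in zip(recs, back):
        assert a.electrode_id == b.electrode_id
        np.testing.assert_allclose(a.position_mm, b.position_mm)
        np.testing.assert_allclose(a.lats_ms, b.lats_ms)
        np.testing.assert_array_equal(a.captured, b.captured)
    with pytest.raises(ValueError):
        (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
        read_electrode_table(tmp_path / "bad.csv")
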