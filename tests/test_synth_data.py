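"""Synthetic-case tests: mesh sanity, catheter geometry, recording
conventions and determinism.  The heavier pipeline-level recovery checks
live in the acceptance suite."""

import numpy as np
import pytest

from atriafit.cable1d import PacingProtocol, s2_ladder
from atriafit.surface_sim import SimConfig
from atriafit.synth_data import (NoiseSpec, make_sheet_case, make_sheet_mesh,
                                 measurements_from_snapshots, place_pentaray,
                                 record_case)


class TestSheetMesh:
    def test_edges_are_shared_by_at_most_two_triangles(self):
        verts, tris = make_sheet_mesh(2.0, 1.0)
        edges = np.sort(np.vstack([tris[:, [0, 1]], tris[:, [1, 2]],
                                   tris[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert counts.max() <= 2

    def test_triangles_are_near_equilateral(self):
        verts, tris = make_sheet_mesh(2.0, 1.0)
        for t in tris[:50]:
            e = [np.linalg.norm(verts[t[i]] - verts[t[(i + 1) % 3]])
                 for i in range(3)]
            assert max(e) / min(e) < 1.05

    def test_covers_the_requested_extent(self):
        verts, _ = make_sheet_mesh(3.0, 0.8)
        assert verts[:, 0].max() >= 30.0 - 0.8
        assert verts[:, 1].max() >= 30.0 - 0.8


class TestSheetCase:
    def test_same_seed_reproduces_the_case_exactly(self):
        a = make_sheet_case(size_cm=5.0, n_regions=3, seed=11, edge_mm=1.0)
        b = make_sheet_case(size_cm=5.0, n_regions=3, seed=11, edge_mm=1.0)
        np.testing.assert_array_equal(a.region_id, b.region_id)
        assert a.region_markers == b.region_markers
        np.testing.assert_allclose(a.snapshot_centres, b.snapshot_centres)

    def test_single_region_is_homogeneous(self):
        case = make_sheet_case(size_cm=5.0, n_regions=1, seed=0, edge_mm=1.0)
        assert len(case.region_markers) == 1
        assert np.all(case.region_id == 0)
        assert np.ptp(case.model.tau_out) == 0.0

    def test_sampled_markers_stay_inside_the_database_ranges(self):
        for seed in range(5):
            case = make_sheet_case(size_cm=6.0, n_regions=4, seed=seed,
                                   edge_mm=1.0)
            for m in case.region_markers:
                assert 10.0 <= m.cv_max <= 300.0
                assert 120.0 <= m.apd_max <= 270.0
                assert 0.01 <= m.h_min <= 0.5
                assert 0.01 <= m.tau_in <= 0.31
                assert 65.0 <= m.tau_open <= 215.0

    def test_regions_cover_the_mesh(self):
        case = make_sheet_case(size_cm=6.0, n_regions=4, seed=2, edge_mm=1.0)
        assert set(np.unique(case.region_id)) == set(range(4))


class TestPentaray:
    def test_layout_counts_and_coplanarity(self):
        verts, _ = make_sheet_mesh(6.0, 1.0)
        g = place_pentaray((30.0, 30.0, 0.0), 0.0, verts)
        assert g.pole_positions_mm.shape == (20, 3)
        assert len(g.bipole_pairs) == 10
        assert np.ptp(g.pole_positions_mm[:, 2]) == 0.0

    def test_five_fold_rotation_symmetry(self):
        verts, _ = make_sheet_mesh(6.0, 1.0)
        g0 = place_pentaray((30.0, 30.0, 0.0), 0.0, verts)
        g72 = place_pentaray((30.0, 30.0, 0.0), 72.0, verts)
        a = {tuple(np.round(p, 6)) for p in g0.pole_positions_mm}
        b = {tuple(np.round(p, 6)) for p in g72.pole_positions_mm}
        assert a == b

    def test_footprint_must_stay_on_the_mesh(self):
        verts, _ = make_sheet_mesh(2.0, 1.0)
        with pytest.raises(ValueError, match="footprint"):
            place_pentaray((19.0, 19.0, 0.0), 0.0, verts)


@pytest.fixture(scope="module")
def recorded_case():
    """One homogeneous case recorded at a supra- and a sub-refractory rung."""
    case = make_sheet_case(size_cm=6.0, n_regions=1, seed=5, edge_mm=0.8)
    ladder = s2_ladder(case.protocol)
    snaps, lat_maps = record_case(case, "A", SimConfig.desk(),
                                  np.array([ladder[0], ladder[24]]))
    return case, snaps, lat_maps


class TestRecording:
    def test_capture_follows_refractoriness(self, recorded_case):
        case, snaps, _ = recorded_case
        caps = np.array([r.captured for r in snaps[0].recordings])
        assert caps[:, 0].all()       # s2 = 343 ms: everything captures
        assert not caps[:, 1].any()   # s2 = 211 ms: below every pool ERP

    def test_egm_lat_agrees_with_threshold_crossing_up_to_a_uniform_offset(
            self, recorded_case):
        """The trace-extremum LAT lags the gate-threshold crossing by half a
        bipole length over the front speed; the lag must be uniform across
        electrodes (within 2 ms) so the downstream offset correction can
        absorb it."""
        case, snaps, lat_maps = recorded_case
        lm = lat_maps[343.0]
        diffs = []
        for r in snaps[0].recordings:
            v = case.model.vertices_mm
            nearest = int(np.argmin(np.linalg.norm(v - r.position_mm, axis=1)))
            if np.isfinite(lm.lat_ms[nearest]) and np.isfinite(r.lats_ms[0]):
                diffs.append(r.lats_ms[0] - lm.lat_ms[nearest])
        assert len(diffs) >= 8
        assert np.ptp(diffs) < 2.0          # uniform across the catheter
        assert 0.0 < np.mean(diffs) < 8.0   # a small positive lag

    def test_dropout_one_removes_every_recording(self):
        case = make_sheet_case(size_cm=6.0, n_regions=1, seed=5, edge_mm=0.8,
                               noise=NoiseSpec(dropout_p=1.0))
        ladder = s2_ladder(case.protocol)
        snaps, _ = record_case(case, "A", SimConfig.desk(),
                               np.array([ladder[0]]))
        assert all(len(s.recordings) == 0 for s in snaps)
        assert measurements_from_snapshots(snaps, ladder) == []

    def test_high_erp_patch_blocks_downstream_tissue(self):
        """Functional block: a long-APD (high-ERP) patch between the
        stimulus and distal tissue stops a premature beat that the distal
        tissue could locally sustain — the mechanism behind spurious
        non-activations in model validation."""
        from atriafit.atlas_mapping import SurfaceModel
        from atriafit.mms_cell import CellMarkers, invert_markers
        from atriafit.surface_sim import StimulusSpec, simulate_pacing

        verts, tris = make_sheet_mesh(5.0, 0.8)
        prox = CellMarkers(cv_max=70.0, apd_max=225.0, h_min=0.3,
                           tau_in=0.28, tau_open=105.0)  # high ERP
        dist = CellMarkers(cv_max=70.0, apd_max=150.0, h_min=0.3,
                           tau_in=0.28, tau_open=105.0)  # low ERP
        pp, pD = invert_markers(prox)
        dp, dD = invert_markers(dist)
        in_prox = verts[:, 0] < 25.0
        cents = verts[tris].mean(axis=1)
        model = SurfaceModel(
            vertices_mm=verts, triangles=tris,
            tau_in=np.where(in_prox, pp.tau_in, dp.tau_in),
            tau_out=np.where(in_prox, pp.tau_out, dp.tau_out),
            tau_open=np.where(in_prox, pp.tau_open, dp.tau_open),
            tau_close=np.where(in_prox, pp.tau_close, dp.tau_close),
            D_element=np.where(cents[:, 0] < 25.0, pD, dD),
        )
        stim = StimulusSpec(centre_mm=(0.0, 25.0, 0.0))
        distal = verts[:, 0] > 35.0
        protocol = PacingProtocol()
        lat_long = simulate_pacing(model, stim, protocol, 343.0, SimConfig.desk())
        assert np.isfinite(lat_long.lat_ms[distal]).mean() > 0.99
        # 238 ms: above the distal patch's own ERP but below the proximal
        # patch's — the wave dies en route and the distal tissue stays silent
        lat_short = simulate_pacing(model, stim, protocol, 238.4, SimConfig.desk())
        assert np.isfinite(lat_short.lat_ms[distal]).mean() < 0.01

    def test_recording_is_deterministic(self, recorded_case):
        case, snaps, _ = recorded_case
        snaps2, _ = record_case(case, "A", SimConfig.desk(),
                                np.array([343.0, s2_ladder(case.protocol)[24]]))
        for a, b in zip(snaps[0].recordings, snaps2[0].recordings):
            np.testing.assert_allclose(a.lats_ms, b.lats_ms, equal_nan=True)
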