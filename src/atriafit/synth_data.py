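"""Synthetic ground-truth cases: heterogeneous tissue sheets, virtual
five-spline catheter recordings and full end-to-end pipeline runs.

Clinical recordings are not publicly available, so every pipeline stage is
exercised against cases whose electrophysiology is known by construction:
a flat triangulated sheet with Voronoi-patch heterogeneity in (CV_max,
APD_max), two remote pacing sites emulated as boundary stimulus disks
(the clinical coronary-sinus and high-right-atrium entries reduce to disk
stimuli on the chamber wall), and virtual catheter snapshots whose bipolar
traces are synthesised from the simulated transmembrane potential via the
1D extracellular identity (pole difference halved).  The fitted quantity
is LAT timing, which is insensitive to the surrogate's amplitude scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .atlas_mapping import SurfaceModel, bin_conductivities, build_surface_model
from .cable1d import PacingProtocol, CVRestitution, s2_ladder
from .egm_processing import (CAPTURE_FRACTION, CatheterSnapshot, CVMeasurement,
                             ElectrodeRecording, detect_lat, estimate_erp,
                             filter_physiological, local_cv_field)
from .eikonal import locate_onset, nearest_neighbour_speed_field
from .fitting import FitConfig, fit_all
from .mms_cell import CellMarkers, invert_markers
from .restitution_db import RestitutionDB
from .surface_sim import (LATMap, SimConfig, StimulusSpec,
                          sample_at_electrodes, simulate_pacing)
from .validation import ValidationReport, build_report

__all__ = [
    "NoiseSpec",
    "GroundTruthCase",
    "PentarayGeometry",
    "make_sheet_mesh",
    "make_sheet_case",
    "place_pentaray",
    "record_case",
    "measurements_from_snapshots",
    "end_to_end_case",
]

#: default marker values held fixed across regions (mid-grid)
FIXED_TAU_IN = 0.28
FIXED_H_MIN = 0.3
FIXED_TAU_OPEN = 105.0

#: default sampling pools for the heterogeneous markers, all grid values.
#: CV_max spans the bulk of the clinical left-atrial range (population mean
#: ~88 cm/s); above ~90 cm/s the wavefront-curvature slowdown at catheter
#: standoff approaches half a database bin, so faster pools are not defaults.
CV_MAX_POOL = (50.0, 60.0, 70.0, 80.0, 90.0)
APD_MAX_POOL = (150.0, 165.0, 180.0, 195.0, 210.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: additive LAT jitter (ms, Gaussian) and
    per-electrode dropout probability (an affected electrode records
    nothing at all)."""

    lat_jitter_sd_ms: float = 0.0
    dropout_p: float = 0.0


@dataclass
class GroundTruthCase:
    """A synthetic 'clinical case' with known local electrophysiology."""

    model: SurfaceModel
    region_id: np.ndarray           # per vertex
    region_markers: list[CellMarkers]
    region_seeds: np.ndarray        # (n_regions, 3) mm, Voronoi seeds
    pacing_sites: dict              # site name -> centre (mm)
    snapshot_centres: np.ndarray    # (k, 3) mm
    protocol: PacingProtocol
    noise: NoiseSpec
    seed: int
    edge_mm: float

    def true_markers_at(self, vertex: int) -> CellMarkers:
        return self.region_markers[int(self.region_id[vertex])]


def make_sheet_mesh(size_cm: float, edge_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Flat near-equilateral triangular lattice covering a size x size sheet.

    Rows are offset by half an edge; the 12 lattice directions keep both
    the FEM and the graph-eikonal metrication error small and isotropic.
    Returns (vertices_mm (n,3), triangles (m,3))."""
    size_mm = size_cm * 10.0
    row_h = edge_mm * math.sqrt(3.0) / 2.0
    ny = int(round(size_mm / row_h)) + 1
    nx = int(round(size_mm / edge_mm)) + 1
    verts = np.empty((ny * nx, 3))
    for j in range(ny):
        off = 0.5 * edge_mm if j % 2 else 0.0
        for i in range(nx):
            verts[j * nx + i] = (i * edge_mm + off, j * row_h, 0.0)
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a, b = j * nx + i, j * nx + i + 1
            c, d = (j + 1) * nx + i, (j + 1) * nx + i + 1
            if j % 2 == 0:
                tris.append((a, b, c))
                tris.append((b, d, c))
            else:
                tris.append((a, b, d))
                tris.append((a, d, c))
    return verts, np.array(tris, dtype=int)


def make_sheet_case(
    size_cm: float = 8.0,
    n_regions: int = 4,
    protocol: PacingProtocol | None = None,
    seed: int = 0,
    edge_mm: float = 0.6,
    noise: NoiseSpec | None = None,
    cv_max_pool=CV_MAX_POOL,
    apd_max_pool=APD_MAX_POOL,
    n_bins: int = 200,
    n_snapshots: int | None = None,
) -> GroundTruthCase:
    """Build a reproducible heterogeneous sheet case.

    ``n_regions`` Voronoi patches each draw (CV_max, APD_max) from the
    marker-grid pools; tau_in, h_min and tau_open are held at mid-grid
    values so that the ground truth is exactly representable by database
    rows.  Pacing sites are disks at two opposite sheet corners (remote
    entries).  Catheter snapshot centres (default ``max(n_regions, 4)`` —
    the catheter is manoeuvred to several sites in a study, and the onset
    search needs angular aperture) are clipped away from the boundary
    (footprint) and kept at least 3 cm from both pacing sites so the
    measured wavefronts are nearly planar.
    """
    protocol = protocol or PacingProtocol()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    verts, tris = make_sheet_mesh(size_cm, edge_mm)
    size_mm = size_cm * 10.0
    margin = 18.0  # keep catheter footprint (~16 mm radius) on the sheet
    pacing_sites = {
        "A": (0.0, 0.0, 0.0),
        "B": (size_mm, size_mm, 0.0),
    }
    corners = np.array([pacing_sites["A"], pacing_sites["B"]])
    lo, hi = margin, size_mm - margin
    if hi <= lo:
        raise ValueError("sheet too small for the catheter footprint")

    def draw_sites(k_sites):
        out = np.empty((k_sites, 3))
        for k in range(k_sites):
            for _ in range(1000):
                cand = np.array([rng.uniform(lo, hi), rng.uniform(lo, hi), 0.0])
                if np.min(np.linalg.norm(corners - cand, axis=1)) >= 30.0:
                    out[k] = cand
                    break
            else:
                raise ValueError("could not place sites away from the "
                                 "pacing corners; enlarge the sheet")
        return out

    if n_regions == 1:
        seeds = np.array([[size_mm / 2, size_mm / 2, 0.0]])
    else:
        seeds = draw_sites(n_regions)
    region_markers = [
        CellMarkers(
            cv_max=float(rng.choice(cv_max_pool)),
            apd_max=float(rng.choice(apd_max_pool)),
            h_min=FIXED_H_MIN,
            tau_in=FIXED_TAU_IN,
            tau_open=FIXED_TAU_OPEN,
        )
        for _ in range(n_regions)
    ]
    if n_snapshots is None:
        n_snapshots = max(n_regions, 4)
    # snapshots at the region seeds first (local properties observed where
    # they live); extra placements add angular aperture for the onset search
    extra = draw_sites(n_snapshots - n_regions) if n_snapshots > n_regions \
        else np.empty((0, 3))
    snapshot_centres = np.vstack([seeds[:n_snapshots], extra])
    d_v = np.linalg.norm(verts[:, None, :] - seeds[None, :, :], axis=2)
    region_id = np.argmin(d_v, axis=1)
    params = [invert_markers(m) for m in region_markers]
    tau_in = np.array([params[r][0].tau_in for r in region_id])
    tau_out = np.array([params[r][0].tau_out for r in region_id])
    tau_open = np.array([params[r][0].tau_open for r in region_id])
    tau_close = np.array([params[r][0].tau_close for r in region_id])
    centroids = verts[tris].mean(axis=1)
    d_e = np.linalg.norm(centroids[:, None, :] - seeds[None, :, :], axis=2)
    region_e = np.argmin(d_e, axis=1)
    D_elem = np.array([params[r][1] for r in region_e])
    bin_id, D_binned = bin_conductivities(D_elem, n_bins)
    model = SurfaceModel(
        vertices_mm=verts, triangles=tris,
        tau_in=tau_in, tau_out=tau_out, tau_open=tau_open,
        tau_close=tau_close, D_element=D_binned,
        v_gate=params[0][0].v_gate, bin_id=bin_id,
    )
    return GroundTruthCase(
        model=model, region_id=region_id, region_markers=region_markers,
        region_seeds=seeds, pacing_sites=pacing_sites,
        snapshot_centres=snapshot_centres,
        protocol=protocol, noise=noise, seed=seed, edge_mm=edge_mm,
    )


@dataclass
class PentarayGeometry:
    """Electrode geometry of one five-spline catheter placement.

    20 pole positions (5 splines x 4 poles at radii 2, 6, 10, 14 mm from
    the hub) and 10 bipoles (per spline: distal pair = two outer poles,
    proximal pair = two inner poles).  Bipole ids are
    ``10*snapshot + 2*spline (+1 for proximal)``."""

    snapshot_id: int
    pole_positions_mm: np.ndarray          # (20, 3)
    bipole_pairs: list[tuple[int, int]]    # pole indices (outer, inner)
    bipole_positions_mm: np.ndarray        # (10, 3)
    bipole_ids: list[int]


def place_pentaray(
    centre_mm,
    orientation_deg: float,
    vertices_mm: np.ndarray,
    snapshot_id: int = 0,
    edge_hint_mm: float | None = None,
) -> PentarayGeometry:
    """Lay the catheter flat at ``centre_mm`` on a (locally planar) mesh.

    Poles are placed in the best-fit plane of the nearby surface (for the
    sheet: the sheet plane) and validated to lie on the mesh: every pole
    must have a mesh vertex within twice the local edge length.
    """
    centre = np.asarray(centre_mm, dtype=float)
    v = np.asarray(vertices_mm, dtype=float)
    radii = np.array([2.0, 6.0, 10.0, 14.0])
    poles = np.empty((20, 3))
    for s in range(5):
        ang = math.radians(72.0 * s + orientation_deg)
        u = np.array([math.cos(ang), math.sin(ang), 0.0])
        for j, r in enumerate(radii):
            poles[4 * s + j] = centre + r * u
    if edge_hint_mm is None:
        d0 = np.sort(np.linalg.norm(v - v[0], axis=1))
        edge_hint_mm = d0[1] if len(d0) > 1 else 1.0
    for k, p in enumerate(poles):
        if np.min(np.linalg.norm(v - p, axis=1)) > 2.0 * edge_hint_mm:
            raise ValueError(
                f"catheter footprint leaves the mesh (pole {k} at {p})"
            )
    pairs, pos, ids = [], [], []
    for s in range(5):
        # distal bipole: poles at 14 and 10 mm; proximal: 6 and 2 mm
        pairs.append((4 * s + 3, 4 * s + 2))
        pos.append(0.5 * (poles[4 * s + 3] + poles[4 * s + 2]))
        ids.append(10 * snapshot_id + 2 * s)
        pairs.append((4 * s + 1, 4 * s + 0))
        pos.append(0.5 * (poles[4 * s + 1] + poles[4 * s + 0]))
        ids.append(10 * snapshot_id + 2 * s + 1)
    return PentarayGeometry(
        snapshot_id=snapshot_id,
        pole_positions_mm=poles,
        bipole_pairs=pairs,
        bipole_positions_mm=np.array(pos),
        bipole_ids=ids,
    )


def _nearest_vertices(vertices_mm: np.ndarray, points_mm: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(vertices_mm[None, :, :] - points_mm[:, None, :], axis=2)
    return np.argmin(d, axis=1)


def record_case(
    case: GroundTruthCase,
    site: str,
    sim_cfg: SimConfig | None = None,
    s2_subset: np.ndarray | None = None,
    stim: StimulusSpec | None = None,
) -> tuple[list[CatheterSnapshot], dict]:
    """Simulate the pacing protocol on the ground truth and synthesise the
    catheter recordings.

    One surface simulation per tested s2 serves all snapshots at once.
    Bipolar traces are ``(vm(inner pole) - vm(outer pole)) / 2`` sampled at
    the pole-nearest vertices; the beat LAT is the first supra-threshold
    trace extremum (threshold: the capture fraction of the drive-beat
    deflection, see ``egm_processing.CAPTURE_FRACTION``) and capture
    additionally requires both pole vertices to activate.  LAT jitter and
    electrode dropout follow the case's noise spec (seeded by case seed and
    site).  Returns (snapshots, {s2: ground-truth LATMap}).
    """
    sim_cfg = sim_cfg or SimConfig.desk()
    ladder = s2_ladder(case.protocol)
    s2_tested = np.asarray(s2_subset if s2_subset is not None else ladder, dtype=float)
    stim = stim or StimulusSpec(centre_mm=case.pacing_sites[site])
    rng = np.random.default_rng((case.seed, 0 if site == "A" else 1, 12345))
    geoms = [
        place_pentaray(c, 0.0, case.model.vertices_mm, snapshot_id=k,
                       edge_hint_mm=case.edge_mm)
        for k, c in enumerate(case.snapshot_centres)
    ]
    all_poles = np.vstack([g.pole_positions_mm for g in geoms])
    pole_verts = _nearest_vertices(case.model.vertices_mm, all_poles)
    t_last = case.protocol.s1 * (case.protocol.n_s1 - 1)

    # lat[s2_index][bipole global index], capture flags
    n_bip = 10 * len(geoms)
    lats = np.full((len(s2_tested), n_bip), np.nan)
    caps = np.zeros((len(s2_tested), n_bip), dtype=bool)
    lat_maps = {}
    for si, s2 in enumerate(s2_tested):
        lat_map, (ts, rec) = simulate_pacing(
            case.model, stim, case.protocol, float(s2), sim_cfg,
            record_idx=pole_verts,
        )
        lat_maps[float(s2)] = lat_map
        t_s2 = t_last + s2
        for gi, g in enumerate(geoms):
            for bi, (pa, pb) in enumerate(g.bipole_pairs):
                ia, ib = 20 * gi + pa, 20 * gi + pb
                b = 0.5 * (rec[ib] - rec[ia])
                in_s1 = (ts >= t_last) & (ts < t_s2)
                ref = np.max(np.abs(b[in_s1])) if in_s1.any() else 0.0
                if ref <= 0:
                    continue
                lat = detect_lat(ts, b, (float(t_s2), float(ts[-1])),
                                 threshold=CAPTURE_FRACTION * ref)
                both_active = np.isfinite(lat_map.lat_ms[pole_verts[ia]]) and \
                    np.isfinite(lat_map.lat_ms[pole_verts[ib]])
                if lat is not None and both_active:
                    j = 10 * gi + bi
                    lats[si, j] = lat
                    caps[si, j] = True
    if case.noise.lat_jitter_sd_ms > 0:
        lats += rng.normal(0.0, case.noise.lat_jitter_sd_ms, lats.shape)
    dropped = rng.random(n_bip) < case.noise.dropout_p
    snapshots = []
    for gi, g in enumerate(geoms):
        recs = []
        for bi in range(10):
            j = 10 * gi + bi
            if dropped[j]:
                continue
            recs.append(
                ElectrodeRecording(
                    electrode_id=g.bipole_ids[bi],
                    position_mm=g.bipole_positions_mm[bi],
                    s2_values_ms=s2_tested,
                    lats_ms=lats[:, j],
                    captured=caps[:, j],
                )
            )
        snapshots.append(CatheterSnapshot(snapshot_id=gi, recordings=recs))
    return snapshots, lat_maps


def measurements_from_snapshots(
    snapshots: list[CatheterSnapshot],
    ladder: np.ndarray,
    cv_cutoff: float = 200.0,
) -> list[CVMeasurement]:
    """Per-electrode CV restitutions and ERPs from the snapshot LATs.

    The CV arrays are aligned with the full database s2 ladder; rungs the
    recordings did not test stay NaN.
    """
    ladder = np.asarray(ladder, dtype=float)
    out = []
    for snap in snapshots:
        if not snap.recordings:
            continue
        tested = snap.recordings[0].s2_values_ms
        cv_by_s2 = {}
        for s2 in tested:
            try:
                cv_by_s2[float(s2)] = filter_physiological(
                    local_cv_field(snap, float(s2)), cv_cutoff
                )
            except ValueError:
                cv_by_s2[float(s2)] = np.full(len(snap.recordings), np.nan)
        for k, r in enumerate(snap.recordings):
            cv = np.full(len(ladder), np.nan)
            for s2 in tested:
                i = int(np.argmin(np.abs(ladder - s2)))
                cv[i] = cv_by_s2[float(s2)][k]
            erp = estimate_erp(r.s2_values_ms, r.captured)
            out.append(
                CVMeasurement(
                    electrode_id=r.electrode_id,
                    restitution=CVRestitution(s2_values=ladder, cv_values=cv, erp=erp),
                    position_mm=r.position_mm,
                )
            )
    return out


def end_to_end_case(
    case: GroundTruthCase,
    db: RestitutionDB,
    sim_cfg: SimConfig | None = None,
    fit_cfg: FitConfig | None = None,
    s2_subset: np.ndarray | None = None,
    val_s2_subset: np.ndarray | None = None,
    fit_site: str = "A",
    validation_sites: tuple = ("A", "B"),
) -> dict:
    """Full pipeline on a synthetic case.

    Records the fitting site, estimates per-electrode restitutions, fits
    the database, extrapolates parameters over the mesh, then for every
    validation site localises the stimulus from that site's measured LATs
    (graph eikonal + exhaustive search), simulates the personalised model
    and scores measured vs computed LATs.  Returns a dict with the fits,
    the personalised model, per-site onset results and
    :class:`ValidationReport` objects.

    ``s2_subset`` are the rungs recorded at the fitting site (should span
    the ladder down past the expected ERPs so the refractory marker is
    identifiable); ``val_s2_subset`` (default: the rungs of ``s2_subset``
    above all database ERPs, or its top three) are the rungs simulated and
    scored at the validation sites.
    """
    sim_cfg = sim_cfg or SimConfig.desk()
    fit_cfg = fit_cfg or FitConfig()
    ladder = s2_ladder(case.protocol)
    s2_tested = np.asarray(s2_subset if s2_subset is not None else ladder, dtype=float)
    if val_s2_subset is None:
        val_s2 = np.sort(s2_tested)[::-1][:3]
    else:
        val_s2 = np.asarray(val_s2_subset, dtype=float)

    recorded = {fit_site: record_case(case, fit_site, sim_cfg, s2_tested)}
    for site in validation_sites:
        if site not in recorded:
            recorded[site] = record_case(case, site, sim_cfg, val_s2)

    snapshots_fit, _ = recorded[fit_site]
    measurements = measurements_from_snapshots(snapshots_fit, ladder)
    fits = fit_all(measurements, db, fit_cfg)
    model = build_surface_model(
        fits, case.model.vertices_mm, case.model.triangles
    )

    reports, onsets = {}, {}
    t_last = case.protocol.s1 * (case.protocol.n_s1 - 1)
    for site in validation_sites:
        snapshots, _ = recorded[site]
        site_rungs = snapshots[0].recordings[0].s2_values_ms
        site_val_s2 = np.array([s for s in val_s2
                                if np.min(np.abs(site_rungs - s)) < 1e-6])
        site_meas = measurements_from_snapshots(snapshots, ladder)
        positions = np.array([m.position_mm for m in site_meas])
        s2_max = float(np.max(site_rungs))
        i343 = int(np.argmin(np.abs(ladder - s2_max)))
        cv343 = np.array([m.restitution.cv_values[i343] for m in site_meas])
        speed = nearest_neighbour_speed_field(
            case.model.vertices_mm, positions, cv343
        )
        lat343 = np.full(len(site_meas), np.nan)
        by_id = {}
        for snap in snapshots:
            for r in snap.recordings:
                by_id[r.electrode_id] = r
        for k, m in enumerate(site_meas):
            lat343[k] = by_id[m.electrode_id].lat_at(s2_max)
        onset = locate_onset(
            case.model.vertices_mm, case.model.triangles, speed,
            positions, lat343 - (t_last + s2_max),
        )
        onsets[site] = onset
        stim = StimulusSpec(
            centre_mm=tuple(case.model.vertices_mm[onset.best_vertex])
        )
        measured_all, computed_all = [], []
        for s2 in site_val_s2:
            lat_map = simulate_pacing(model, stim, case.protocol, float(s2), sim_cfg)
            comp = sample_at_electrodes(lat_map, model.vertices_mm, positions)
            meas = np.array([by_id[m.electrode_id].lat_at(float(s2))
                             for m in site_meas])
            measured_all.append(meas)
            computed_all.append(comp)
        measured_all = np.concatenate(measured_all)
        computed_all = np.concatenate(computed_all)
        reports[site] = build_report(measured_all, computed_all)
    return {
        "fits": fits,
        "model": model,
        "measurements": measurements,
        "onsets": onsets,
        "reports": reports,
    }
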