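"""Electrogram processing: local activation times, local conduction-velocity
fields and effective refractory periods from multi-electrode recordings.

The LAT of a beat is the time of the first local extremum (peak or valley)
of the bipolar trace inside the beat window whose absolute deflection
exceeds a capture threshold.  Local CV is estimated from the LATs of a
catheter snapshot with a piecewise-linear scheme: electrode positions are
projected onto their best-fit plane, Delaunay-triangulated, the constant
per-triangle LAT gradient inverted (CV = 1/|grad LAT|), and each electrode
receives the median of the triangle CVs whose centroid lies within a
2.5 cm radius.  CV values above a physiological cut-off (default 200 cm/s)
are discarded.  The ERP at an electrode is the largest s2 coupling
interval that failed to produce a local activation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import Delaunay, QhullError

from .cable1d import CVRestitution

__all__ = [
    "ElectrodeRecording",
    "CatheterSnapshot",
    "CVMeasurement",
    "detect_lat",
    "local_cv_field",
    "cv_from_lats",
    "filter_physiological",
    "estimate_erp",
    "read_electrode_table",
    "write_electrode_table",
]

#: physiological CV cut-off (cm/s); derived clinically as mean + 2 SD of the
#: pooled CV distribution, rounded
CV_CUTOFF_CM_S = 200.0

#: capture threshold as a fraction of the drive-beat bipolar deflection.
#: Depolarisation fronts deflect at >~80% of the drive-beat amplitude even
#: when crawling near the refractory limit (the front steepens as it slows),
#: while the repolarisation wave of the preceding beat — which can fall
#: inside the premature-beat search window at short coupling intervals —
#: stays below ~25%.  0.4 separates the two with margin on both sides.
CAPTURE_FRACTION = 0.4

#: radius of the median filter around each electrode (cm); twice the length
#: of a catheter spline
CV_MEDIAN_RADIUS_CM = 2.5


@dataclass
class ElectrodeRecording:
    """One bipolar electrode: position (mm), per-s2 LATs and capture flags.

    ``lats_ms`` is aligned with ``s2_values_ms``; NaN marks no activation.
    Raw traces, when carried, are a list of (t_ms, value) arrays aligned the
    same way (None where absent).
    """

    electrode_id: int
    position_mm: np.ndarray
    s2_values_ms: np.ndarray
    lats_ms: np.ndarray
    captured: np.ndarray
    traces: list | None = None

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.s2_values_ms = np.asarray(self.s2_values_ms, dtype=float)
        self.lats_ms = np.asarray(self.lats_ms, dtype=float)
        self.captured = np.asarray(self.captured, dtype=bool)
        if not np.all(np.isfinite(self.position_mm)):
            raise ValueError("electrode position must be finite")
        if not (len(self.s2_values_ms) == len(self.lats_ms) == len(self.captured)):
            raise ValueError("per-s2 arrays must be aligned")

    def lat_at(self, s2: float) -> float:
        i = int(np.argmin(np.abs(self.s2_values_ms - s2)))
        if abs(self.s2_values_ms[i] - s2) > 1e-6:
            raise KeyError(f"s2 = {s2} ms not in this recording's ladder")
        return float(self.lats_ms[i])


@dataclass
class CatheterSnapshot:
    """One multi-electrode placement (10 bipoles for a 5-spline catheter)."""

    snapshot_id: int
    recordings: list[ElectrodeRecording]

    def positions(self) -> np.ndarray:
        return np.array([r.position_mm for r in self.recordings])

    def lats_at(self, s2: float) -> np.ndarray:
        return np.array([r.lat_at(s2) for r in self.recordings])


@dataclass
class CVMeasurement:
    """Fitting input for one electrode: its CV restitution and ERP."""

    electrode_id: int
    restitution: CVRestitution
    position_mm: np.ndarray | None = None

    @property
    def erp(self) -> float:
        return self.restitution.erp


def detect_lat(
    t_ms: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float],
    threshold: float = 0.0,
) -> float | None:
    """Time of the first peak or valley in ``window`` with |value| above
    ``threshold``; None when no such extremum exists.

    A flat trace has no local extrema and yields None.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty LAT search window")
    mask = (t_ms >= lo) & (t_ms <= hi)
    if not mask.any():
        raise ValueError("LAT search window lies outside the trace span")
    v = values[mask]
    t = t_ms[mask]
    peaks, _ = find_peaks(v)
    valleys, _ = find_peaks(-v)
    idx = np.concatenate([peaks, valleys])
    idx = idx[np.abs(v[idx]) > threshold]
    if idx.size == 0:
        return None
    return float(t[idx.min()])


def _project_to_plane(positions: np.ndarray) -> np.ndarray:
    """Least-squares best-fit-plane coordinates (n, 2), in mm."""
    centred = positions - positions.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s.size < 2 or s[1] < 1e-9:
        raise ValueError("electrode positions are collinear; cannot form a plane")
    return centred @ vt[:2].T


def cv_from_lats(
    positions_mm: np.ndarray,
    lats_ms: np.ndarray,
    radius_cm: float = CV_MEDIAN_RADIUS_CM,
) -> np.ndarray:
    """Per-electrode CV (cm/s) from scattered LATs; NaN where undefined.

    Electrodes with NaN LAT do not participate in the triangulation but
    still receive a CV from nearby triangles when available.
    """
    positions_mm = np.asarray(positions_mm, dtype=float)
    lats_ms = np.asarray(lats_ms, dtype=float)
    n = len(positions_mm)
    out = np.full(n, np.nan)
    good = np.isfinite(lats_ms)
    if good.sum() < 3:
        raise ValueError("need at least 3 electrodes with LATs for a CV field")
    pts2 = _project_to_plane(positions_mm)
    try:
        tri = Delaunay(pts2[good])
    except QhullError as e:
        raise ValueError(f"degenerate electrode triangulation: {e}") from e
    gp = pts2[good]
    gl = lats_ms[good]
    simplices = tri.simplices
    cv_tri = np.full(len(simplices), np.nan)
    centroids = gp[simplices].mean(axis=1)
    for k, (i, j, l) in enumerate(simplices):
        a = np.array([gp[j] - gp[i], gp[l] - gp[i]])
        b = np.array([gl[j] - gl[i], gl[l] - gl[i]])
        try:
            g = np.linalg.solve(a, b)  # ms/mm
        except np.linalg.LinAlgError:
            continue
        gn = np.linalg.norm(g)
        if gn > 0:
            cv_tri[k] = 1.0 / gn * 100.0  # mm/ms -> cm/s
    radius_mm = radius_cm * 10.0
    for e in range(n):
        d = np.linalg.norm(centroids - pts2[e], axis=1)
        vals = cv_tri[(d <= radius_mm) & np.isfinite(cv_tri)]
        if vals.size:
            out[e] = float(np.median(vals))
    return out


def local_cv_field(snapshot: CatheterSnapshot, s2: float,
                   radius_cm: float = CV_MEDIAN_RADIUS_CM) -> np.ndarray:
    """Per-electrode CV (cm/s) of a snapshot at one coupling interval."""
    return cv_from_lats(snapshot.positions(), snapshot.lats_at(s2), radius_cm)


def filter_physiological(cv: np.ndarray, cutoff: float = CV_CUTOFF_CM_S) -> np.ndarray:
    """Mark CV values above the physiological cut-off as absent (NaN)."""
    cv = np.asarray(cv, dtype=float).copy()
    cv[cv > cutoff] = np.nan
    return cv


def estimate_erp(s2_values_ms: np.ndarray, captured: np.ndarray) -> float:
    """Largest s2 that did not produce a local activation; NaN when every
    tested s2 captured (ERP below the ladder floor).

    A non-monotone capture pattern (loss of capture above an s2 that
    captured) is physiologically suspect; the literal definition is still
    applied and a warning emitted.
    """
    s2_values_ms = np.asarray(s2_values_ms, dtype=float)
    captured = np.asarray(captured, dtype=bool)
    if captured.all():
        return float("nan")
    erp = float(np.max(s2_values_ms[~captured]))
    if np.any(captured & (s2_values_ms < erp)):
        warnings.warn(
            f"non-monotone capture pattern: capture observed below the "
            f"largest non-capturing s2 ({erp:g} ms)",
            stacklevel=2,
        )
    return erp


# ---------------------------------------------------------------------------
# tabular I/O

_TABLE_COLUMNS = ["electrode_id", "x_mm", "y_mm", "z_mm", "s2_ms", "lat_ms", "captured"]


def write_electrode_table(recordings: list[ElectrodeRecording], path) -> None:
    """Long-format CSV: one row per (electrode, s2)."""
    rows = []
    for r in recordings:
        x, y, z = r.position_mm
        for s2, lat, cap in zip(r.s2_values_ms, r.lats_ms, r.captured):
            rows.append((r.electrode_id, x, y, z, s2, lat, bool(cap)))
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def read_electrode_table(path) -> list[ElectrodeRecording]:
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"electrode table missing columns: {sorted(missing)}")
    out = []
    for eid, g in df.groupby("electrode_id", sort=True):
        g = g.sort_values("s2_ms", ascending=False)
        out.append(
            ElectrodeRecording(
                electrode_id=int(eid),
                position_mm=g[["x_mm", "y_mm", "z_mm"]].iloc[0].to_numpy(),
                s2_values_ms=g["s2_ms"].to_numpy(),
                lats_ms=g["lat_ms"].to_numpy(),
                captured=g["captured"].to_numpy(dtype=bool),
            )
        )
    return out
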