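"""Pre-computed restitution database over the physiological marker grid.

The database sweeps a Cartesian grid of physiological markers (CV_max,
tau_in, h_min, tau_open, APD_max), inverts each tuple to mMS parameters
plus a diffusion coefficient, runs the full S1S2 cable protocol and stores
the resulting CV restitution and ERP.  Fitting later matches a measured
restitution against these rows by least squares.

The full grid (580,800 rows) is a cluster-scale build; :func:`build_database`
accepts a stride or an explicit sub-grid for desk-scale use.  Rows whose
leading-order depolarisation front spans fewer than 4 grid cells at the
configured resolution are flagged ``resolved = False``: their discrete CV is
grid-limited and should not be interpreted quantitatively.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cable1d import (CableConfig, CVRestitution, PacingProtocol,
                      SolverInstabilityError, front_width_cm,
                      restitution_curve, s2_ladder)
from .mms_cell import CellMarkers, invert_markers

__all__ = [
    "MarkerGrid",
    "RestitutionDB",
    "enumerate_grid",
    "build_database",
    "save_db",
    "load_db",
]

_SCHEMA_VERSION = 1

MARKER_COLUMNS = ["cv_max", "tau_in", "h_min", "tau_open", "apd_max"]


def _arange_inclusive(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + k * step, 10) for k in range(n))


@dataclass(frozen=True)
class MarkerGrid:
    """Axis values of the marker grid; defaults are the published sweep:
    CV_max 10..300 cm/s step 10, tau_in 0.01..0.31 ms step 0.03, h_min
    {0.01..0.09 step 0.02} + {0.1..0.5 step 0.1}, tau_open 65..215 ms step
    10, APD_max 120..270 ms step 15 — 30*11*10*16*11 = 580,800 tuples."""

    cv_max: tuple = _arange_inclusive(10, 300, 10)
    tau_in: tuple = _arange_inclusive(0.01, 0.31, 0.03)
    h_min: tuple = _arange_inclusive(0.01, 0.09, 0.02) + _arange_inclusive(0.1, 0.5, 0.1)
    tau_open: tuple = _arange_inclusive(65, 215, 10)
    apd_max: tuple = _arange_inclusive(120, 270, 15)

    @property
    def axis_counts(self) -> tuple[int, ...]:
        return tuple(len(getattr(self, c)) for c in MARKER_COLUMNS)

    @property
    def size(self) -> int:
        return int(np.prod(self.axis_counts))

    def to_dict(self) -> dict:
        return {c: list(getattr(self, c)) for c in MARKER_COLUMNS}

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerGrid":
        return cls(**{c: tuple(d[c]) for c in MARKER_COLUMNS})


def enumerate_grid(spec: MarkerGrid) -> pd.DataFrame:
    """All marker tuples in deterministic lexicographic order
    (cv_max slowest, apd_max fastest), one row per tuple."""
    axes = [np.asarray(getattr(spec, c), dtype=float) for c in MARKER_COLUMNS]
    mesh = np.meshgrid(*axes, indexing="ij")
    return pd.DataFrame(
        {c: m.reshape(-1) for c, m in zip(MARKER_COLUMNS, mesh)}
    )


def markers_from_row(row) -> CellMarkers:
    return CellMarkers(
        cv_max=float(row["cv_max"]),
        apd_max=float(row["apd_max"]),
        h_min=float(row["h_min"]),
        tau_in=float(row["tau_in"]),
        tau_open=float(row["tau_open"]),
    )


@dataclass
class RestitutionDB:
    """Columnar restitution table plus provenance metadata.

    ``table`` columns: the five marker columns, derived parameters
    (``tau_out``, ``tau_close``, ``D``), ``erp`` (NaN = capture never lost),
    ``status`` ('ok' / 'skipped:...' / 'unstable'), ``resolved`` (front
    resolved at the build resolution) and one ``cv_XX`` column per s2-ladder
    rung (cm/s, NaN = no capture)."""

    table: pd.DataFrame
    s2_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s2_values = np.asarray(self.s2_values, dtype=float)

    @property
    def cv_columns(self) -> list[str]:
        return [f"cv_{i:02d}" for i in range(len(self.s2_values))]

    def cv_matrix(self) -> np.ndarray:
        return self.table[self.cv_columns].to_numpy(dtype=float)

    def markers(self, index: int) -> CellMarkers:
        return markers_from_row(self.table.iloc[index])

    def restitution(self, index: int) -> CVRestitution:
        row = self.table.iloc[index]
        return CVRestitution(
            s2_values=self.s2_values,
            cv_values=row[self.cv_columns].to_numpy(dtype=float),
            erp=float(row["erp"]),
        )


def build_database(
    spec: MarkerGrid,
    cfg: CableConfig,
    protocol: PacingProtocol,
    stride: int | None = None,
    row_filter=None,
    progress: bool = False,
) -> RestitutionDB:
    """Simulate the restitution of every grid row (optionally strided or
    filtered) and assemble the database.

    ``row_filter(markers) -> bool`` drops rows before simulation; a solver
    instability marks the row ``status='unstable'`` and the build continues.
    Deterministic: no randomness anywhere, so identical configs reproduce
    identical tables.
    """
    grid = enumerate_grid(spec)
    if stride is not None:
        grid = grid.iloc[::stride]
    ladder = s2_ladder(protocol)
    n_cv = len(ladder)
    records = []
    it = grid.iterrows()
    if progress:
        from tqdm import tqdm

        it = tqdm(it, total=len(grid))
    for idx, row in it:
        m = markers_from_row(row)
        if row_filter is not None and not row_filter(m):
            continue
        rec = {c: row[c] for c in MARKER_COLUMNS}
        rec["grid_index"] = idx
        try:
            p, D = invert_markers(m)
        except ValueError as e:
            rec.update(tau_out=np.nan, tau_close=np.nan, D=np.nan,
                       erp=np.nan, status=f"skipped:{e}", resolved=False)
            rec.update({f"cv_{i:02d}": np.nan for i in range(n_cv)})
            records.append(rec)
            continue
        rec.update(tau_out=p.tau_out, tau_close=p.tau_close, D=D)
        rec["resolved"] = front_width_cm(p, D) >= 4.0 * cfg.dx_cm
        try:
            curve = restitution_curve(p, D, cfg, protocol)
        except SolverInstabilityError:
            rec.update(erp=np.nan, status="unstable")
            rec.update({f"cv_{i:02d}": np.nan for i in range(n_cv)})
            records.append(rec)
            continue
        rec["erp"] = curve.erp
        rec["status"] = "ok"
        rec.update({f"cv_{i:02d}": curve.cv_values[i] for i in range(n_cv)})
        records.append(rec)
    table = pd.DataFrame.from_records(records).reset_index(drop=True)
    meta = {
        "schema_version": _SCHEMA_VERSION,
        "grid": spec.to_dict(),
        "cable_config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "protocol": {k: getattr(protocol, k) for k in protocol.__dataclass_fields__},
        "stride": stride,
        "n_rows": len(table),
        "s2_values": [float(s) for s in ladder],
    }
    return RestitutionDB(table=table, s2_values=ladder, metadata=meta)


def save_db(db: RestitutionDB, path) -> None:
    """Persist as ``<dir>/restitutions.csv`` + ``<dir>/metadata.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    db.metadata["n_rows"] = len(db.table)
    db.table.to_csv(path / "restitutions.csv", index=False)
    (path / "metadata.json").write_text(json.dumps(db.metadata, indent=1))


def load_db(path) -> RestitutionDB:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    if meta.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"database schema version {meta.get('schema_version')} "
            f"!= supported {_SCHEMA_VERSION}"
        )
    table = pd.read_csv(path / "restitutions.csv")
    if len(table) != meta["n_rows"]:
        raise ValueError(
            f"database truncated: {len(table)} rows on disk, "
            f"{meta['n_rows']} expected"
        )
    return RestitutionDB(table=table, s2_values=np.array(meta["s2_values"]),
                         metadata=meta)


def db_digest(db: RestitutionDB) -> str:
    """SHA-256 digest of the serialised table (reproducibility checks)."""
    return hashlib.sha256(db.table.to_csv(index=False).encode()).hexdigest()
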