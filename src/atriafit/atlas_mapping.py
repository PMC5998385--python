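"""Extrapolation of per-electrode fits over the surface mesh.

Every mesh vertex inherits the parameters of its Euclidean-nearest fitted
electrode (ties to the lowest electrode id); every element inherits the
conductivity of the electrode nearest its centroid.  Element conductivities
are then binned into a fixed number of equal-width sets (the solver defines
conductivity per element group), with the bin mean as representative value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitResult
from .mms_cell import MMSParams, V_GATE_DEFAULT

__all__ = ["SurfaceModel", "nearest_neighbour_map", "bin_conductivities",
           "build_surface_model"]


@dataclass
class SurfaceModel:
    """Triangulated surface with per-vertex cell parameters and per-element
    conductivity.

    ``vertices_mm``: (n, 3); ``triangles``: (m, 3) int; parameter arrays are
    per vertex (ms); ``D_element`` per element (cm^2/ms).  ``source_electrode``
    and ``source_distance_mm`` record the provenance of each vertex's
    parameters; ``bin_id`` the conductivity bin of each element.
    """

    vertices_mm: np.ndarray
    triangles: np.ndarray
    tau_in: np.ndarray
    tau_out: np.ndarray
    tau_open: np.ndarray
    tau_close: np.ndarray
    D_element: np.ndarray
    v_gate: float = V_GATE_DEFAULT
    source_electrode: np.ndarray | None = None
    source_distance_mm: np.ndarray | None = None
    bin_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices_mm = np.asarray(self.vertices_mm, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        n = len(self.vertices_mm)
        for name in ("tau_in", "tau_out", "tau_open", "tau_close"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == ():
                arr = np.full(n, float(arr))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per vertex")
            setattr(self, name, arr)
        self.D_element = np.asarray(self.D_element, dtype=float)
        if self.D_element.shape == ():
            self.D_element = np.full(len(self.triangles), float(self.D_element))
        if self.D_element.shape != (len(self.triangles),):
            raise ValueError("D_element must have one value per triangle")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices_mm)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_centroids_mm(self) -> np.ndarray:
        return self.vertices_mm[self.triangles].mean(axis=1)

    def element_areas_cm2(self) -> np.ndarray:
        v = self.vertices_mm / 10.0
        a = v[self.triangles[:, 1]] - v[self.triangles[:, 0]]
        b = v[self.triangles[:, 2]] - v[self.triangles[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def params_at(self, vertex: int) -> MMSParams:
        return MMSParams(
            tau_in=float(self.tau_in[vertex]),
            tau_out=float(self.tau_out[vertex]),
            tau_open=float(self.tau_open[vertex]),
            tau_close=float(self.tau_close[vertex]),
            v_gate=self.v_gate,
        )


def _nearest_fit(points_mm: np.ndarray, fits: list[FitResult]) -> tuple[np.ndarray, np.ndarray]:
    """Index (into id-sorted fits) and distance of the nearest electrode for
    each query point; exact ties resolve to the lowest electrode id."""
    pos = np.array([f.position_mm for f in fits], dtype=float)
    d = np.linalg.norm(points_mm[:, None, :] - pos[None, :, :], axis=2)
    idx = np.argmin(d, axis=1)  # first occurrence = lowest id after sorting
    return idx, d[np.arange(len(points_mm)), idx]


def nearest_neighbour_map(
    fits: list[FitResult],
    vertices_mm: np.ndarray,
    triangles: np.ndarray,
) -> SurfaceModel:
    """Assign every vertex/element the parameters of its nearest electrode."""
    if not fits:
        raise ValueError("no fitted electrodes to map")
    for f in fits:
        if f.position_mm is None:
            raise ValueError(f"fit for electrode {f.electrode_id} has no position")
    fits = sorted(fits, key=lambda f: f.electrode_id)
    vertices_mm = np.asarray(vertices_mm, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    vidx, vdist = _nearest_fit(vertices_mm, fits)
    centroids = vertices_mm[triangles].mean(axis=1)
    eidx, _ = _nearest_fit(centroids, fits)
    take = lambda attr: np.array([getattr(fits[i].params, attr) for i in vidx])
    return SurfaceModel(
        vertices_mm=vertices_mm,
        triangles=triangles,
        tau_in=take("tau_in"),
        tau_out=take("tau_out"),
        tau_open=take("tau_open"),
        tau_close=take("tau_close"),
        D_element=np.array([fits[i].D for i in eidx]),
        v_gate=fits[0].params.v_gate,
        source_electrode=np.array([fits[i].electrode_id for i in vidx]),
        source_distance_mm=vdist,
    )


def bin_conductivities(
    D_element: np.ndarray, n_bins: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width conductivity binning.

    Returns ``(bin_id per element, binned D per element)`` where the binned
    value is the mean of the bin's members; the per-element error is bounded
    by the bin width ``(Dmax - Dmin)/n_bins``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    D = np.asarray(D_element, dtype=float)
    lo, hi = float(D.min()), float(D.max())
    if hi == lo:
        return np.zeros(len(D), dtype=int), D.copy()
    width = (hi - lo) / n_bins
    bin_id = np.minimum(((D - lo) / width).astype(int), n_bins - 1)
    rep = np.zeros(n_bins)
    for b in np.unique(bin_id):
        rep[b] = D[bin_id == b].mean()
    return bin_id, rep[bin_id]


def build_surface_model(
    fits: list[FitResult],
    vertices_mm: np.ndarray,
    triangles: np.ndarray,
    n_bins: int = 200,
) -> SurfaceModel:
    """Nearest-neighbour mapping followed by conductivity binning."""
    model = nearest_neighbour_map(fits, vertices_mm, triangles)
    model.bin_id, model.D_element = bin_conductivities(model.D_element, n_bins)
    return model
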