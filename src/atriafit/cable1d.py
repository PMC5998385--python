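"""1D monodomain cable reproducing the clinical S1S2 restitution protocol.

The cable is stimulated at one end with a drive train of ``n_s1`` beats at
interval ``s1`` followed by a single premature beat at coupling interval
``s2``; sweeping ``s2`` down a geometric ladder traces the local
conduction-velocity (CV) restitution and the effective refractory period
(ERP).  Two bipolar electrode pairs in the middle of the domain record the
passing wave; CV is the pair separation divided by the difference of the
two local activation times (LATs, first extremum of the bipolar trace).

Numerics: Godunov splitting with forward-Euler reaction sub-steps
(``dt_ode``) and a Crank--Nicolson diffusion step (``dt_pde``) on a uniform
grid with sealed (zero-flux) ends.  The extracellular potential of the
uniform-conductivity monodomain cable satisfies
``d^2/dx^2 (vm + 2 phi_e) = 0`` with zero-flux ends, whose zero-mean
solution is the closed form ``phi_e = (mean(vm) - vm) / 2``; the bipolar
signal is the difference of ``phi_e`` at the two poles of a pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from ._kernels import react_uniform
from .mms_cell import MMSParams

__all__ = [
    "CableConfig",
    "PacingProtocol",
    "CVRestitution",
    "CableTraces",
    "SolverInstabilityError",
    "s2_ladder",
    "run_cable",
    "extracellular",
    "bipolar_signal",
    "restitution_curve",
    "rested_cv",
    "front_width_cm",
]


class SolverInstabilityError(RuntimeError):
    """Raised when |vm| exceeds the blow-up bound during time stepping."""


@dataclass(frozen=True)
class CableConfig:
    """Cable geometry, discretisation and electrode assembly.

    Lengths carry their unit in the field name.  The electrode assembly is
    two bipolar pairs centred in the domain: poles of a pair are
    ``pole_spacing_mm`` apart and the pair barycentres are
    ``pair_separation_mm`` apart.
    """

    length_cm: float = 10.0
    dx_um: float = 200.0
    dt_ode_us: float = 10.0
    dt_pde_us: float = 100.0
    stim_length_mm: float = 0.5
    stim_amplitude: float = 4.0  # 1/ms
    stim_duration_ms: float = 1.0
    pole_spacing_mm: float = 2.0
    pair_separation_mm: float = 7.0
    post_s2_window_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.dt_ode_us > self.dt_pde_us:
            raise ValueError("dt_ode must not exceed dt_pde")
        nsub = self.dt_pde_us / self.dt_ode_us
        if abs(nsub - round(nsub)) > 1e-9:
            raise ValueError("dt_pde must be an integer multiple of dt_ode")
        extent_cm = (self.pair_separation_mm + self.pole_spacing_mm) / 10.0
        if extent_cm >= self.length_cm:
            raise ValueError("electrode assembly does not fit inside the domain")

    @classmethod
    def desk(cls) -> "CableConfig":
        """Coarser preset for interactive use and the test suite."""
        return cls(length_cm=5.0, dx_um=250.0, dt_ode_us=10.0, dt_pde_us=200.0)

    @property
    def dx_cm(self) -> float:
        return self.dx_um * 1e-4

    @property
    def n_nodes(self) -> int:
        return int(round(self.length_cm / self.dx_cm)) + 1

    @property
    def n_sub(self) -> int:
        return int(round(self.dt_pde_us / self.dt_ode_us))

    def pole_positions_cm(self) -> np.ndarray:
        """x-positions of the four poles: (pair1_a, pair1_b, pair2_a, pair2_b).

        Pair 1 is the pair closer to the stimulated end (x = 0).
        """
        mid = self.length_cm / 2.0
        half_sep = self.pair_separation_mm / 20.0
        half_pole = self.pole_spacing_mm / 20.0
        c1, c2 = mid - half_sep, mid + half_sep
        return np.array([c1 - half_pole, c1 + half_pole,
                         c2 - half_pole, c2 + half_pole])

    def pole_indices(self) -> np.ndarray:
        return np.rint(self.pole_positions_cm() / self.dx_cm).astype(int)


@dataclass(frozen=True)
class PacingProtocol:
    """S1S2 protocol: ``n_s1`` drive beats at ``s1`` ms, then one premature
    beat whose coupling interval walks down a geometric ladder from
    ``s2_start`` in steps of ``s2_decrement_fraction`` until ``s2_floor``."""

    s1: float = 470.0
    n_s1: int = 2
    s2_start: float = 343.0
    s2_decrement_fraction: float = 0.02
    s2_floor: float = 200.0

    def __post_init__(self) -> None:
        if self.s1 <= 0 or self.s2_start <= 0 or self.s2_floor <= 0:
            raise ValueError("all intervals must be positive")
        if not 0 < self.s2_decrement_fraction < 1:
            raise ValueError("s2_decrement_fraction must lie in (0, 1)")
        if self.n_s1 < 1:
            raise ValueError("need at least one drive beat")


@dataclass
class CVRestitution:
    """Per-electrode CV restitution: CV (cm/s) per tested s2 (ms), NaN where
    the premature beat was not captured, plus the measured ERP (ms, NaN when
    capture never failed within the ladder)."""

    s2_values: np.ndarray
    cv_values: np.ndarray
    erp: float

    def __post_init__(self) -> None:
        self.s2_values = np.asarray(self.s2_values, dtype=float)
        self.cv_values = np.asarray(self.cv_values, dtype=float)
        if self.s2_values.shape != self.cv_values.shape:
            raise ValueError("s2_values and cv_values must be aligned")

    @property
    def captured(self) -> np.ndarray:
        return ~np.isnan(self.cv_values)


@dataclass
class CableTraces:
    """Transmembrane potential sampled at the four pole positions."""

    t_ms: np.ndarray        # (nt,)
    vm_poles: np.ndarray    # (4, nt)
    pole_x_cm: np.ndarray   # (4,)
    stim_times_ms: np.ndarray

    def bipolar(self, pair: int) -> np.ndarray:
        """Bipolar trace of pair 0 or 1 (phi_e difference of its poles)."""
        a, b = (0, 1) if pair == 0 else (2, 3)
        return 0.5 * (self.vm_poles[b] - self.vm_poles[a])


def s2_ladder(protocol: PacingProtocol) -> np.ndarray:
    """Geometric s2 ladder ``s2_start * (1 - f)^k`` truncated at the floor."""
    vals = []
    s2 = protocol.s2_start
    while s2 >= protocol.s2_floor:
        vals.append(s2)
        s2 *= 1.0 - protocol.s2_decrement_fraction
    if not vals:
        # s2_start already below the floor: test the starting interval only
        vals = [protocol.s2_start]
    return np.array(vals)


def extracellular(vm: np.ndarray) -> np.ndarray:
    """Closed-form extracellular potential ``phi_e = (mean(vm) - vm)/2``.

    Accepts any array whose last axis is the spatial grid; the mean is taken
    along that axis, so ``mean(phi_e) == 0`` and ``vm + 2 phi_e`` is constant
    across the cable at every instant.
    """
    vm = np.asarray(vm, dtype=float)
    return 0.5 * (vm.mean(axis=-1, keepdims=True) - vm)


def bipolar_signal(phi_e: np.ndarray, pole_a: int, pole_b: int) -> np.ndarray:
    """Bipolar trace: extracellular potential at pole a minus at pole b.

    ``phi_e`` has the spatial grid on its last axis (time on the first axis
    for a history)."""
    phi_e = np.asarray(phi_e, dtype=float)
    return phi_e[..., pole_a] - phi_e[..., pole_b]


def front_width_cm(p: MMSParams, D: float) -> float:
    """Leading-order depolarisation front width ``sqrt(8 D tau_in)`` (cm).

    Rows whose front spans fewer than ~4 grid cells are flagged unresolved
    at the configured resolution."""
    return math.sqrt(8.0 * D * p.tau_in)


class _CableSim:
    """Stateful operator-splitting integrator on the 1D grid."""

    _BLOWUP = 10.0
    _CHECK_EVERY = 25

    def __init__(self, p: MMSParams, D: float, cfg: CableConfig):
        self.p, self.D, self.cfg = p, D, cfg
        n = cfg.n_nodes
        dx = cfg.dx_cm
        dt = cfg.dt_pde_us * 1e-3  # ms
        self.dt_pde_ms = dt
        self.dt_ode_ms = cfg.dt_ode_us * 1e-3
        self.n_sub = cfg.n_sub
        # lumped mass (cm) and stiffness (cm^-1 * D) in symmetric banded form
        m = np.full(n, dx)
        m[0] = m[-1] = dx / 2.0
        kd = np.full(n, 2.0 * D / dx)
        kd[0] = kd[-1] = D / dx
        ko = np.full(n - 1, -D / dx)
        # A v^{n+1} = B v^n with A = M + dt/2 K, B = M - dt/2 K
        self._ab = np.zeros((2, n))
        self._ab[0, 1:] = 0.5 * dt * ko
        self._ab[1] = m + 0.5 * dt * kd
        self._b_diag = m - 0.5 * dt * kd
        self._b_off = -0.5 * dt * ko
        self.n_stim = max(1, int(round(cfg.stim_length_mm * 0.1 / dx)))
        self.vm = np.zeros(n)
        self.h = np.ones(n)
        self.t = 0.0
        self._steps = 0

    def state(self) -> tuple[np.ndarray, np.ndarray, float]:
        return self.vm.copy(), self.h.copy(), self.t

    def restore(self, state) -> None:
        vm, h, t = state
        self.vm, self.h, self.t = vm.copy(), h.copy(), t

    def step(self, stim_on: bool) -> None:
        amp = self.cfg.stim_amplitude if stim_on else 0.0
        react_uniform(self.vm, self.h, self.p.tau_in, self.p.tau_out,
                      self.p.tau_open, self.p.tau_close, self.p.v_gate,
                      self.dt_ode_ms, self.n_sub, amp, self.n_stim)
        rhs = self._b_diag * self.vm
        rhs[:-1] += self._b_off * self.vm[1:]
        rhs[1:] += self._b_off * self.vm[:-1]
        self.vm = solveh_banded(self._ab, rhs)
        self.t += self.dt_pde_ms
        self._steps += 1
        if self._steps % self._CHECK_EVERY == 0 and np.max(np.abs(self.vm)) > self._BLOWUP:
            raise SolverInstabilityError(
                f"|vm| > {self._BLOWUP} at t = {self.t:.2f} ms with "
                f"dt_ode = {self.cfg.dt_ode_us} us, dt_pde = {self.cfg.dt_pde_us} us, "
                f"dx = {self.cfg.dx_um} um"
            )

    def run(self, t_end: float, stim_times: np.ndarray, record_idx: np.ndarray):
        """Advance to ``t_end``, recording vm at ``record_idx`` each PDE step."""
        dur = self.cfg.stim_duration_ms
        n_steps = int(round((t_end - self.t) / self.dt_pde_ms))
        rec = np.empty((len(record_idx), n_steps + 1))
        ts = np.empty(n_steps + 1)
        rec[:, 0] = self.vm[record_idx]
        ts[0] = self.t
        for k in range(n_steps):
            t0 = self.t
            stim_on = bool(np.any((stim_times <= t0) & (t0 < stim_times + dur)))
            self.step(stim_on)
            rec[:, k + 1] = self.vm[record_idx]
            ts[k + 1] = self.t
        return ts, rec


def run_cable(
    p: MMSParams,
    D: float,
    cfg: CableConfig,
    protocol: PacingProtocol,
    s2: float,
) -> CableTraces:
    """Simulate one full S1S2 train at coupling interval ``s2``.

    Returns vm sampled at the four pole positions at ``dt_pde`` resolution.
    """
    sim = _CableSim(p, D, cfg)
    drive = protocol.s1 * np.arange(protocol.n_s1)
    t_s2 = drive[-1] + s2
    stim_times = np.append(drive, t_s2)
    t_end = t_s2 + cfg.post_s2_window_ms
    idx = cfg.pole_indices()
    ts, rec = sim.run(t_end, stim_times, idx)
    return CableTraces(t_ms=ts, vm_poles=rec, pole_x_cm=cfg.pole_positions_cm(),
                       stim_times_ms=stim_times)


def rested_cv(p: MMSParams, D: float, cfg: CableConfig,
              t_end_ms: float = 400.0) -> float:
    """Conduction velocity of a single beat into fully rested tissue (cm/s).

    This is the quantity the ``cv_max`` marker describes: the s2-beat CVs
    of a restitution curve are systematically slower because the gate has
    not fully recovered at clinical coupling intervals.  Timing is taken
    from the upward ``vm = 0.5`` crossings at the four poles (a
    convention-free oracle; the action-potential plateau always exceeds
    0.5).  NaN when no causal propagating wave reaches all poles — a
    stimulus much smaller than the front width cannot ignite the tissue
    (sub-critical nucleus), and its passive diffusion transient must not
    be mistaken for propagation.
    """
    sim = _CableSim(p, D, cfg)
    idx = cfg.pole_indices()
    ts, rec = sim.run(t_end_ms, np.array([0.0]), idx)
    lats = []
    for k in range(4):
        above = rec[k] >= 0.5
        if not above.any():
            return float("nan")
        lats.append(ts[int(np.argmax(above))])
    if not all(b >= a for a, b in zip(lats, lats[1:])):
        return float("nan")
    # pair LAT = mean of its two pole crossings
    lat1 = 0.5 * (lats[0] + lats[1])
    lat2 = 0.5 * (lats[2] + lats[3])
    if lat2 <= lat1:
        return float("nan")
    return cfg.pair_separation_mm / 10.0 / (lat2 - lat1) * 1000.0


def restitution_curve(
    p: MMSParams,
    D: float,
    cfg: CableConfig,
    protocol: PacingProtocol,
) -> CVRestitution:
    """CV restitution and ERP from the full s2 ladder.

    The drive train is shared across ladder rungs: the state just before
    the last drive stimulus is cached once and each s2 continues from it.
    CV = pair separation / (LAT_pair2 - LAT_pair1) of the premature beat;
    the beat is captured when both pairs show an activation whose bipolar
    deflection exceeds the capture fraction of the drive-beat deflection at
    that pair (see ``egm_processing.CAPTURE_FRACTION``).  ERP
    is the largest non-captured s2 (NaN when capture never fails).
    """
    from .egm_processing import CAPTURE_FRACTION, detect_lat

    ladder = s2_ladder(protocol)
    sim = _CableSim(p, D, cfg)
    idx = cfg.pole_indices()
    drive = protocol.s1 * np.arange(protocol.n_s1)
    t_last = drive[-1]
    if protocol.n_s1 > 1:
        sim.run(t_last, drive[:-1], idx[:1])
    cached = sim.state()

    sep_cm = cfg.pair_separation_mm / 10.0
    cv = np.full(len(ladder), np.nan)
    captured = np.zeros(len(ladder), dtype=bool)
    for i, s2 in enumerate(ladder):
        sim.restore(cached)
        t_s2 = t_last + s2
        ts, rec = sim.run(t_s2 + cfg.post_s2_window_ms,
                          np.array([t_last, t_s2]), idx)
        tr = CableTraces(ts, rec, cfg.pole_positions_cm(),
                         np.array([t_last, t_s2]))
        lats = []
        ok = True
        for pair in (0, 1):
            b = tr.bipolar(pair)
            in_s1 = (ts >= t_last) & (ts < t_s2)
            ref_amp = np.max(np.abs(b[in_s1])) if in_s1.any() else 0.0
            thr = CAPTURE_FRACTION * ref_amp
            lat = detect_lat(ts, b, (t_s2, ts[-1]), threshold=thr)
            if lat is None or ref_amp == 0.0:
                ok = False
                break
            lats.append(lat)
        captured[i] = ok
        if ok and lats[1] > lats[0]:
            cv[i] = sep_cm / (lats[1] - lats[0]) * 1000.0

    if captured.all():
        erp = float("nan")
    elif not captured.any():
        erp = protocol.s2_start
    else:
        erp = float(np.max(ladder[~captured]))
    # CV is only defined above the ERP
    if not math.isnan(erp):
        cv[ladder <= erp] = np.nan
    return CVRestitution(s2_values=ladder, cv_values=cv, erp=erp)
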