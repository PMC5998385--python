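"""Cell-model unit and property tests: reaction terms, marker formulas,
inversion bijectivity, resting-state stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriafit.mms_cell import (CellMarkers, CellState, MMSParams,
                               cv_prefactor, gate_rate, integrate_cell,
                               invert_markers, ionic_current,
                               leading_order_markers, nullcline_h)


@pytest.mark.parametrize(
    "vm,h,expected",
    [
        (0.0, 1.0, 0.0),                       # rest: both terms vanish
        (1.0, 0.7, -1.0 / 6.0),                # plateau: outward only
        (1.0, 0.0, -1.0 / 6.0),
    ],
)
def test_ionic_current_closed_form_points(vm, h, expected):
    p = MMSParams(tau_in=0.3, tau_out=6.0, tau_open=100.0, tau_close=150.0)
    assert ionic_current(CellState(vm=vm, h=h), p) == pytest.approx(expected)


def test_ionic_current_subthreshold_is_repolarising():
    """Below the gate potential the total current is strictly negative,
    which is the no-pacemaker property of the modified model."""
    p = MMSParams(tau_in=0.3, tau_out=6.0, tau_open=100.0, tau_close=150.0)
    for vm in (0.01, 0.05, 0.099):
        assert ionic_current(CellState(vm=vm, h=1.0), p) < 0


@pytest.mark.parametrize(
    "vm,h,tau_open,expected",
    [
        (0.0, 1.0, 100.0, 0.0),
        (1.0, 0.0, 100.0, 0.0),
        (0.0, 0.5, 100.0, 0.005),
    ],
)
def test_gate_rate_points(vm, h, tau_open, expected):
    p = MMSParams(tau_in=0.3, tau_out=6.0, tau_open=tau_open, tau_close=150.0)
    assert gate_rate(CellState(vm=vm, h=h), p) == pytest.approx(expected)


def test_h_min_arithmetic_and_nullcline_oracle():
    p = MMSParams(tau_in=0.3, tau_out=6.0, tau_open=100.0, tau_close=150.0)
    m = leading_order_markers(p, D=0.01)
    assert m.h_min == pytest.approx(1.2 / 4.86, rel=1e-12)
    # oracle: numerically located minimum of the null-cline h(v)
    vs = np.linspace(p.v_gate + 1e-6, 1 - 1e-6, 200001)
    h_null = np.array([nullcline_h(v, p) for v in vs])
    assert m.h_min == pytest.approx(h_null.min(), rel=1e-8)


def test_apd_formula_at_unit_log():
    m = CellMarkers(cv_max=80.0, apd_max=150.0, h_min=math.exp(-1),
                    tau_in=0.3, tau_open=100.0)
    p, _ = invert_markers(m)
    assert p.tau_close == pytest.approx(150.0)


def test_invert_markers_arithmetic():
    m = CellMarkers(cv_max=80.0, apd_max=120.0, h_min=0.25,
                    tau_in=0.3, tau_open=100.0)
    p, _ = invert_markers(m)
    assert p.tau_out == pytest.approx(4 * 0.3 / (0.25 * 0.81), rel=1e-12)
    m2 = CellMarkers(cv_max=80.0, apd_max=120.0, h_min=0.5,
                     tau_in=0.3, tau_open=100.0)
    p2, _ = invert_markers(m2)
    assert p2.tau_close == pytest.approx(120.0 / math.log(2.0), rel=1e-12)


def test_cv_prefactor_limits():
    # vanishing h_min recovers the classical cubic-front coefficient
    assert cv_prefactor(1e-12, 0.1) == pytest.approx(1 - 2 * 0.1, rel=1e-5)
    # beyond the propagation bound the prefactor is non-positive
    assert cv_prefactor(0.9, 0.1) < 0


@given(
    cv=st.sampled_from([10.0, 50.0, 100.0, 200.0, 300.0]),
    tau_in=st.sampled_from([0.01, 0.13, 0.31]),
    h_min=st.sampled_from([0.01, 0.09, 0.1, 0.3, 0.5]),
    tau_open=st.sampled_from([65.0, 135.0, 215.0]),
    apd=st.sampled_from([120.0, 180.0, 270.0]),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_marker_inversion_is_a_bijection(cv, tau_in, h_min, tau_open, apd):
    m = CellMarkers(cv_max=cv, apd_max=apd, h_min=h_min,
                    tau_in=tau_in, tau_open=tau_open)
    p, D = invert_markers(m)
    m2 = leading_order_markers(p, D)
    for attr in ("cv_max", "apd_max", "h_min", "tau_in", "tau_open"):
        assert getattr(m2, attr) == pytest.approx(getattr(m, attr), rel=1e-12)


def test_no_pacemaker_from_subthreshold_states():
    """Unstimulated dynamics from any subthreshold state relax to (0, 1)
    for random parameter sets across the database ranges."""
    rng = np.random.default_rng(42)
    n_sets = 100
    cv = rng.uniform(10, 300, n_sets)
    tau_in = rng.uniform(0.01, 0.31, n_sets)
    h_min = rng.uniform(0.01, 0.5, n_sets)
    tau_open = rng.uniform(65, 215, n_sets)
    apd = rng.uniform(120, 270, n_sets)
    params = [invert_markers(CellMarkers(cv[i], apd[i], h_min[i],
                                         tau_in[i], tau_open[i]))[0]
              for i in range(n_sets)]
    states = [(0.0, 1.0), (0.05, 0.2), (0.099, 1.0), (0.09, 0.0)]
    vm0, h0 = np.meshgrid([s[0] for s in states], np.arange(n_sets))
    vm = np.repeat([[s[0] for s in states]], n_sets, axis=0).astype(float)
    h = np.repeat([[s[1] for s in states]], n_sets, axis=0).astype(float)
    ti = np.array([p.tau_in for p in params])[:, None]
    to = np.array([p.tau_out for p in params])[:, None]
    topen = np.array([p.tau_open for p in params])[:, None]
    tclose = np.array([p.tau_close for p in params])[:, None]
    dt, t_end = 0.004, 700.0
    for _ in range(int(t_end / dt)):
        dv = h * vm * (vm - 0.1) * (1 - vm) / ti - vm / to
        dh = np.where(vm < 0.1, (1 - h) / topen, -h / tclose)
        vm = vm + dt * dv
        h = h + dt * dh
    assert np.all(np.abs(vm) < 0.02)
    assert np.all(h > 0.9)


def test_gate_stays_in_unit_interval_under_euler():
    p = MMSParams(tau_in=0.3, tau_out=6.0, tau_open=65.0, tau_close=30.0)
    s = integrate_cell(CellState(vm=0.09, h=0.0), p, t_end=300.0, dt=0.05)
    assert 0.0 <= s.h <= 1.0
    with pytest.raises(ValueError):
        integrate_cell(CellState(vm=0.0, h=1.0), p, t_end=1.0, dt=10.0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        MMSParams(tau_in=0.3, tau_out=0.2, tau_open=100.0, tau_close=150.0)
    with pytest.raises(ValueError):
        MMSParams(tau_in=0.3, tau_out=6.0, tau_open=100.0, tau_close=150.0,
                  v_gate=0.7)
    with pytest.raises(ValueError):
        CellMarkers(cv_max=80.0, apd_max=120.0, h_min=1.2, tau_in=0.3,
                    tau_open=100.0)
    p = MMSParams(tau_in=0.3, tau_out=1.3, tau_open=100.0, tau_close=150.0)
    with pytest.raises(ValueError):
        leading_order_markers(p, D=0.01)  # h_min >= 1
    p = MMSParams(tau_in=0.3, tau_out=1.646, tau_open=100.0, tau_close=150.0)
    with pytest.raises(ValueError):
        leading_order_markers(p, D=0.01)  # h_min ~0.9: front speed non-positive


def test_json_round_trip_with_units():
    p = MMSParams(tau_in=0.28, tau_out=4.6, tau_open=105.0, tau_close=149.5)
    d = p.to_json_dict()
    assert d["tau_in_ms"] == 0.28
    assert MMSParams.from_json(p.to_json()) == p
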