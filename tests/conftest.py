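"""Shared fixtures: desk-scale configurations and the session-wide test
restitution database (built once; several suites fit against it)."""

from dataclasses import replace

import numpy as np
import pytest

from atriafit.cable1d import CableConfig, PacingProtocol, s2_ladder
from atriafit.mms_cell import CellMarkers, invert_markers
from atriafit.restitution_db import MarkerGrid, build_database


@pytest.fixture(scope="session")
def protocol():
    return PacingProtocol()


@pytest.fixture(scope="session")
def ladder(protocol):
    return s2_ladder(protocol)


@pytest.fixture(scope="session")
def desk_cable():
    """Desk cable preset with the electrode pairs at catheter standoff
    (~4.5 cm) to match the synthetic sheet geometry."""
    return CableConfig(length_cm=9.0, dx_um=250.0, dt_ode_us=10.0,
                       dt_pde_us=200.0, post_s2_window_ms=400.0)


@pytest.fixture(scope="session")
def mid_markers():
    return CellMarkers(cv_max=100.0, apd_max=180.0, h_min=0.3,
                       tau_in=0.28, tau_open=105.0)


@pytest.fixture(scope="session")
def mid_params(mid_markers):
    return invert_markers(mid_markers)


@pytest.fixture(scope="session")
def test_grid():
    """Sub-grid bracketing the synthetic-case marker pools by one step."""
    return MarkerGrid(
        cv_max=tuple(float(v) for v in range(40, 101, 10)),
        tau_in=(0.28,),
        h_min=(0.3,),
        tau_open=(105.0,),
        apd_max=(135.0, 150.0, 165.0, 180.0, 195.0, 210.0, 225.0),
    )


@pytest.fixture(scope="session")
def test_db(test_grid, desk_cable, protocol):
    """Desk-scale restitution database shared across the fitting and
    end-to-end suites (the expensive session fixture)."""
    return build_database(test_grid, desk_cable, protocol)
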