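"""Shared fixtures: default model objects and cached corner-case runs.

Expensive surfaces used by several acceptance checks are session-scoped so
each grid point is integrated exactly once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ptlkin import (
    SCENARIOS,
    SWEEP_TIME_GRID,
    CellPhenotype,
    GridSpec,
    ModelConstants,
    TimeGrid,
    run_sweep,
    simulate,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


#: Coarse output grid for fast end-to-end tests (~3000 output points).
COARSE_TIME_GRID = TimeGrid(dt1=1e-5, dt2=1e-3, dt3=1e-1)


def normalized_discrepancy(a, b, atol: float = 1e-14) -> float:
    """Max over species of max|a-b| scaled by that species' max |b|.

    Species whose magnitude never rises above the solver's absolute
    tolerance carry no resolvable signal, so the scale is floored at atol.
    """
    times = np.intersect1d(a.times, b.times)
    ia = np.searchsorted(a.times, times)
    ib = np.searchsorted(b.times, times)
    diff = np.abs(a.states[ia, :14] - b.states[ib, :14])
    scale = np.maximum(np.abs(b.states[ib, :14]).max(axis=0), atol)
    return float((diff.max(axis=0) / scale).max())

#: The four phenotype-plane corners of the default sweep ranges:
#: (kD1, CAT0) with cancer-like = (2000, 1e-8), normal-like = (100, 1e-5).
CORNERS = [(100.0, 1e-8), (2000.0, 1e-8), (100.0, 1e-5), (2000.0, 1e-5)]


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def default_run(constants):
    """Reference-phenotype selective run on the sweep output grid."""
    return simulate(CellPhenotype(kD1=920.0, CAT0=1e-8),
                    SCENARIOS["selective_non_synergistic"],
                    constants, SWEEP_TIME_GRID)


@pytest.fixture(scope="session")
def corner_runs(constants):
    """Trajectories at the four phenotype corners for all four regimes."""
    runs = {}
    for kd1, cat0 in CORNERS:
        for label, sc in SCENARIOS.items():
            runs[(kd1, cat0, label)] = simulate(
                CellPhenotype(kD1=kd1, CAT0=cat0), sc, constants, SWEEP_TIME_GRID)
    return runs


@pytest.fixture(scope="session")
def selective_surface_10x10(constants):
    """10x10 sweep, 1 uM extracellular H2O2, no nitrite."""
    grid = GridSpec(n_kd1=10, n_cat0=10)
    return run_sweep(grid, [SCENARIOS["selective_non_synergistic"]], constants)


@pytest.fixture(scope="session")
def nonselective_surface_10x10(constants):
    """10x10 sweep, 1 mM extracellular H2O2, no nitrite."""
    grid = GridSpec(n_kd1=10, n_cat0=10)
    return run_sweep(grid, [SCENARIOS["non_selective_non_synergistic"]], constants)


@pytest.fixture(scope="session")
def synergy_surfaces_5x5(constants):
    """5x5 selective-regime sweeps with and without 1 mM nitrite."""
    grid = GridSpec(n_kd1=5, n_cat0=5)
    with_no2 = run_sweep(grid, [SCENARIOS["selective_synergistic"]], constants)
    without = run_sweep(grid, [SCENARIOS["selective_non_synergistic"]], constants)
    return with_no2, without
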