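"""Shared fixtures.

The expensive steady states (600-cell benchmark and near-washout points) are
session-scoped so the whole suite solves each of them once.
"""

import numpy as np
import pytest
from hypothesis import settings

from gutfix import (
    GutParameters,
    make_parameters,
    solve_steady_state,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Benchmark parameter values: strongly spatial steady state (profiles figure).
BENCH = dict(v=0.5, D=0.2, k=0.1, r=0.42, vFin=1.0, alpha=6.13e8, L=6.0, S=1.0)
#: Near-washout, strongly spatial point used for the active-population analyses.
ACTIVE = dict(v=0.181, D=0.02, k=0.1, r=0.42, vFin=1.0, alpha=6.13e8, L=6.0, S=1.0)


@pytest.fixture(scope="session")
def bench_params() -> GutParameters:
    return make_parameters(BENCH)


@pytest.fixture(scope="session")
def active_params() -> GutParameters:
    return make_parameters(ACTIVE)


@pytest.fixture(scope="session")
def bench_steady(bench_params):
    steady = solve_steady_state(bench_params, n_cells=600)
    assert steady.converged and not steady.washed_out
    return steady


@pytest.fixture(scope="session")
def active_steady(active_params):
    steady = solve_steady_state(active_params, n_cells=600)
    assert steady.converged and not steady.washed_out
    return steady


@pytest.fixture(scope="session")
def bench_steady_coarse(bench_params):
    """Cheap 200-cell benchmark steady state for unit tests."""
    steady = solve_steady_state(bench_params, n_cells=200)
    assert steady.converged
    return steady


@pytest.fixture(scope="session")
def mixed_steady(bench_params):
    """A well-mixed (quasi-flat) steady state: strong mixing, moderate flow."""
    p = bench_params.replace(D=20.0, v=0.3)
    steady = solve_steady_state(p, n_cells=200)
    assert steady.converged and not steady.washed_out
    return steady
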