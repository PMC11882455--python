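"""Shared fixtures: simulated colonies at a desk scale reused across tests."""

import numpy as np
import pytest

from mycowave import colonysim as cs


@pytest.fixture(scope="session")
def colony_medium():
    """A 60 h colony with branching, crossings and a few fusions."""
    params = cs.SimParams(t_max_h=60, roi_radius_mm=25, n_anchors=5, seed=4)
    series, events, report = cs.simulate_colony(params)
    return params, series, events, report


@pytest.fixture(scope="session")
def colony_decorated(colony_medium):
    params, series, events, report = colony_medium
    decorated = cs.decorate_bas(series, params)
    cs.inject_spores(decorated, params)
    return params, decorated, events, report


@pytest.fixture(scope="session")
def colony_dense():
    """A longer, denser colony for rate/saturation statistics."""
    params = cs.SimParams(t_max_h=120, roi_radius_mm=30, n_anchors=5, seed=5)
    series, events, report = cs.simulate_colony(params)
    return params, series, events, report


@pytest.fixture(scope="session")
def colony_longrun():
    """A run long enough for the wake density to stop densifying."""
    params = cs.SimParams(t_max_h=220, roi_radius_mm=40, n_anchors=5, seed=5)
    series, events, report = cs.simulate_colony(params)
    return params, series, events, report


@pytest.fixture(scope="session")
def longrun_profiles(colony_longrun):
    from mycowave import waveprofile as wp

    params, series, _, _ = colony_longrun
    rings = wp.make_rings((0, 0), params.roi_radius_mm, 10)
    prof = wp.ring_densities(series, rings)
    return rings, prof


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
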