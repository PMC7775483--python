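"""Shared fixtures: steady states, burst runs and threshold searches are
expensive, so they are computed once per session and reused."""

import numpy as np
import pytest

from camkii_atria import (build_release_map, build_threshold_map,
                          burst_protocol, make_scenario, pace_to_steady_state,
                          release_after_unclamp, ryr_threshold_search)

PRESET_NAMES = ("wt", "oe", "wt_ros", "oe_ros")


@pytest.fixture(scope="session")
def steady():
    """1 Hz steady-state runs for every preset (from shipped equilibria)."""
    out = {}
    for name in PRESET_NAMES:
        out[name] = pace_to_steady_state(make_scenario(name), max_beats=60)
    return out


@pytest.fixture(scope="session")
def bursts(steady):
    """Burst-pacing runs for every preset."""
    out = {}
    for name in PRESET_NAMES:
        out[name] = burst_protocol(make_scenario(name),
                                   y0=steady[name].state)
    return out


@pytest.fixture(scope="session")
def thresholds():
    """RyR activation thresholds at the three reference clamp conditions."""
    cfg = make_scenario("wt")
    return {
        "A": ryr_threshold_search(cfg, 300.0, 0.2),
        "B": ryr_threshold_search(cfg, 450.0, 0.4),
        "C": ryr_threshold_search(cfg, 600.0, 0.6),
    }


@pytest.fixture(scope="session")
def releases():
    """Post-unclamp 200-beat release runs at conditions A, B, C."""
    cfg = make_scenario("wt")
    return {
        "A": release_after_unclamp(cfg, 300.0, 0.2, n_beats=200),
        "B": release_after_unclamp(cfg, 450.0, 0.4, n_beats=200),
        "C": release_after_unclamp(cfg, 600.0, 0.6, n_beats=200),
    }


@pytest.fixture(scope="session")
def small_threshold_map():
    cfg = make_scenario("wt")
    ca = np.array([300.0, 450.0, 600.0])
    ph = np.array([0.2, 0.4, 0.6])
    return build_threshold_map(cfg, ca, ph)


@pytest.fixture(scope="session")
def small_release_map():
    cfg = make_scenario("wt")
    ca = np.array([250.0, 350.0, 450.0, 550.0, 650.0])
    ph = np.array([0.2, 0.4, 0.6])
    return build_release_map(cfg, ca, ph, n_beats=2)
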