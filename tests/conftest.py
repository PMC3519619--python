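"""Shared fixtures: one Monte Carlo baseline serves the whole session."""

import pytest

from margindrs.forward import MCConfig, ProbeGeometry, build_baseline
from margindrs.spectra import default_grid, load_default_library

#: documented baseline seed used across the test session
BASELINE_SEED = 2


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def baseline(geometry):
    """Reference simulation at the median clinical scattering level.

    1e6 photons, the study default: the per-record collection kernel gets
    smoother with record count, and smaller baselines measurably deepen
    the inversion's spurious minima.
    """
    cfg = MCConfig(photon_count=1_000_000, rng_seed=BASELINE_SEED)
    return build_baseline(geometry, cfg)


@pytest.fixture(scope="session")
def small_baseline(geometry):
    """Cheaper baseline for tests that only need qualitative behavior."""
    cfg = MCConfig(photon_count=100_000, rng_seed=BASELINE_SEED + 1)
    return build_baseline(geometry, cfg)
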