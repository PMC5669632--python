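"""Shared fixtures: small simulated window sets reused across test modules.

The heavier fixtures are session-scoped so each study condition is simulated
once per run; all seeds are fixed.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from permeon import (
    AdaptiveConfig,
    AnalysisGrid,
    BiasSpec,
    BrownianParams,
    DoubleWell,
    Harmonic,
    bin_samples,
    landscape_preset,
    run_adaptive,
    simulate_windows,
)

from .oracles import flood_fill_nodes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TEMPERATURE = 323.25

#: Conditions of the 2D adaptive-exploration study: three map topologies,
#: three seed wells each; 305 ps / 5 ps equilibration at 0.06 ps sampling
#: keeps 5000 retained samples per window.
ADAPTIVE_CONFIG = AdaptiveConfig(
    window_duration=305.0, equilibration=5.0, max_rounds=40
)
ADAPTIVE_BROWNIAN = BrownianParams(
    sampling_interval=0.06, timestep=0.004, metropolis=True
)
ADAPTIVE_CASES = [
    ("open_valley", (-1.5, 0.0), 100),
    ("open_valley", (0.0, 0.0), 101),
    ("open_valley", (1.5, 0.0), 102),
    ("blocking_ridge", (-1.0, 0.0), 103),
    ("blocking_ridge", (1.0, 0.5), 104),
    ("blocking_ridge", (-0.5, -1.0), 105),
    ("gated_ridge", (-1.0, 0.0), 106),
    ("gated_ridge", (1.0, 1.0), 107),
    ("gated_ridge", (-1.5, 0.5), 108),
]


def window_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n)]


@pytest.fixture(scope="session")
def harmonic_1d():
    """k = 1.2 kcal/mol/A^2 well on [-3.5, 3.5] with its analysis grid."""
    landscape = Harmonic(bounds=((-3.5, 3.5),), center=(0.0,), k=(1.2,))
    grid = AnalysisGrid((-3.5,), (3.5,), 0.1)
    return landscape, grid


@pytest.fixture(scope="session")
def harmonic_windows(harmonic_1d):
    """Nine 600 ps umbrella windows (0.5 A apart, k_w = 20) on the 1D well;
    5000 retained samples each after the 100 ps discard."""
    landscape, grid = harmonic_1d
    centers = np.arange(-2.0, 2.01, 0.5)
    trajs = simulate_windows(
        landscape,
        [BiasSpec((c,), (20.0,)) for c in centers],
        BrownianParams(),
        600.0,
        seeds=window_seeds(42, len(centers)),
    )
    return [bin_samples(t, grid, discard=100.0) for t in trajs]


@pytest.fixture(scope="session")
def harmonic_long_windows(harmonic_1d):
    """Nine 1100 ps windows giving twenty 50 ps / five 200 ps error slices."""
    landscape, grid = harmonic_1d
    centers = np.arange(-2.0, 2.01, 0.5)
    trajs = simulate_windows(
        landscape,
        [BiasSpec((c,), (20.0,)) for c in centers],
        BrownianParams(),
        1100.0,
        seeds=window_seeds(43, len(centers)),
    )
    return [bin_samples(t, grid, discard=100.0) for t in trajs]


@pytest.fixture(scope="session")
def double_well_1d():
    """Quartic double well with a designed 6 kcal/mol barrier."""
    landscape = DoubleWell(
        bounds=((-3.0, 3.0),), barrier=6.0, half_separation=1.5
    )
    grid = AnalysisGrid((-3.0,), (3.0,), 0.1)
    return landscape, grid


@pytest.fixture(scope="session")
def adaptive_runs():
    """The nine 2D adaptive runs plus their exact-surface flood-fill sets."""
    out = []
    for name, seed_center, master in ADAPTIVE_CASES:
        landscape = landscape_preset(name)
        run = run_adaptive(
            landscape, seed_center, ADAPTIVE_CONFIG, ADAPTIVE_BROWNIAN,
            master_seed=master,
        )
        expected = flood_fill_nodes(
            landscape, seed_center,
            spacing=ADAPTIVE_CONFIG.spacing,
            limit=ADAPTIVE_CONFIG.creation_limit,
        )
        out.append({
            "name": name,
            "seed_center": seed_center,
            "run": run,
            "expected": expected,
        })
    return out


@pytest.fixture(scope="session")
def open_basin_runs():
    """Two independent adaptive runs on the soft open-mode map, seeded in
    the two outer wells -- the inputs of the run-combination study."""
    landscape = landscape_preset("open_basin")
    return [
        run_adaptive(landscape, seed_center, ADAPTIVE_CONFIG,
                     ADAPTIVE_BROWNIAN, master_seed=master)
        for seed_center, master in (((-1.5, 0.0), 200), ((1.5, 0.0), 201))
    ]
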