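"""Shared fixtures.

FDTD runs are the expensive part of the suite, so scenes that several
tests inspect (the coarse flat wall, the near-texture set) are simulated
once per session on coarse grids: 10 mm spacing with a 20 mm source for
arrival-time checks, 5 mm spacing with a 12 mm source where spectra
above 6 kHz matter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from echowall import abx_stats, click, fdtd, features, geometry, synthetic_data

COARSE = dict(spacing=0.01, margin=0.3)
COARSE_SIGMA = 0.02
FINE = dict(spacing=0.005, margin=0.3)
FINE_SIGMA = 0.012


@pytest.fixture(scope="session")
def sim_config():
    return fdtd.SimulationConfig(output_rate=48_000.0, source_sigma=COARSE_SIGMA)


@pytest.fixture(scope="session")
def flat_near(sim_config):
    """Coarse flat wall at 0.81 m: (scene, wall run, free run, bundle)."""
    scene = geometry.rasterize(geometry.make_texture("flat", 0.81), **COARSE)
    wall = fdtd.run_fdtd(scene, sim_config, 8e-3)
    free = fdtd.run_fdtd(scene.without_solids(), sim_config, 8e-3)
    bundle = fdtd.split_components(wall, free, fdtd.WINDOW_NEAR, texture="flat", distance=0.81)
    return scene, wall, free, bundle


@pytest.fixture(scope="session")
def flat_far(sim_config):
    """Coarse flat wall at 5.03 m with the 31.3 ms analysis window."""
    scene = geometry.rasterize(geometry.make_texture("flat", 5.03), **COARSE)
    wall = fdtd.run_fdtd(scene, sim_config, 33e-3)
    free = fdtd.run_fdtd(scene.without_solids(), sim_config, 33e-3)
    return fdtd.split_components(wall, free, fdtd.WINDOW_FAR, texture="flat", distance=5.03)


@pytest.fixture(scope="session")
def texture_bundles():
    """Near-distance bundles for four textures on the finer test grid."""
    cfg = fdtd.SimulationConfig(output_rate=48_000.0, source_sigma=FINE_SIGMA)
    out = {}
    for tex in ("flat", "aperture", "circular_convex", "parabolic_concave"):
        scene = geometry.rasterize(geometry.make_texture(tex, 0.81), **FINE)
        wall = fdtd.run_fdtd(scene, cfg, 8e-3)
        free = fdtd.run_fdtd(scene.without_solids(), cfg, 8e-3)
        out[tex] = fdtd.split_components(wall, free, fdtd.WINDOW_NEAR, texture=tex, distance=0.81)
    return out


@pytest.fixture(scope="session")
def default_click():
    return click.generate_click()


@pytest.fixture(scope="session")
def fixture_filters():
    return synthetic_data.make_fixture_filters(seed=7)


@pytest.fixture(scope="session")
def snq_design():
    """Synthetic full-design SNQ table: 15 pairs x 2 distances x 3 configs."""
    rng = np.random.default_rng(11)
    textures = list("abcdef")
    rows = []
    for dist in (0.81, 5.03):
        for conf in ("normal", "rdld_plus6", "reflections_only"):
            for i, a in enumerate(textures):
                for b in textures[i + 1 :]:
                    rows.append(
                        {
                            "pair_i": a,
                            "pair_j": b,
                            "distance": dist,
                            "configuration": conf,
                            "snq1": float(rng.uniform(0.001, 0.01)),
                            "snq2": float(rng.uniform(0.5, 6.0)),
                            "snq3": float(rng.uniform(0.05, 0.8)),
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture()
def scored_responses(snq_design):
    model = synthetic_data.ListenerModel(sensitivity=1.2, seed=5)
    trials = synthetic_data.simulate_experiment(model, snq_design)
    return abx_stats.score_trials(trials)
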