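import numpy as np
import pytest

from reefspec import scene_sim
from reefspec.core import coral_class_label

SIX_CLASSES = [
    coral_class_label(g, l)
    for g, l in [
        ("Acropora", 1),
        ("Acropora", 3),
        ("Acropora", 5),
        ("Porites massive", 2),
        ("Porites massive", 4),
        ("Porites massive", 6),
    ]
]


@pytest.fixture(scope="session")
def grid():
    return scene_sim.sensor_grid()


@pytest.fixture(scope="session")
def library(grid):
    return scene_sim.synth_endmembers(
        ["Acropora", "Porites massive"], range(1, 7), seed=7, grid=grid
    )


@pytest.fixture(scope="session")
def water(grid):
    return scene_sim.default_water_model(grid, max_depth=6.0)


@pytest.fixture(scope="session")
def reef_scene(library):
    """64x64 six-coral-class scene over sand, depth gradient 0-3 m."""
    return scene_sim.make_scene((64, 64), SIX_CLASSES, 3.0, seed=1, library=library)


def constant_depth_scene(cls, depth, library, shape=(6, 6), seed=3):
    return scene_sim.make_scene(
        shape, [cls], 3.0, seed=seed, library=library, constant_depth=depth
    )


def render_reflectance(truth, water, noise_sd=0.0, seed=0):
    from reefspec import radiometry

    cube, white = scene_sim.render_cube(truth, water, noise_sd=noise_sd, seed=seed)
    return radiometry.to_reflectance(cube, white)
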