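"""Shared fixtures: default parameters, fixture meshes, cached resting shape."""

import numpy as np
import pytest

from spinesim import (
    MembraneMesh, ModelParams, get_resting_mesh, init_spine_mesh,
)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def unit_square() -> MembraneMesh:
    pos = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return MembraneMesh(pos, np.zeros(4, bool), np.nan, np.nan, 0.03)


@pytest.fixture()
def pentagon() -> MembraneMesh:
    """Irregular convex pentagon used as a gradient-check fixture."""
    pos = np.array([
        [0.1, 0.0], [0.5, 0.1], [0.6, 0.55], [0.2, 0.7], [-0.1, 0.3],
    ])
    return MembraneMesh(pos, np.zeros(5, bool), np.nan, np.nan, 0.03)


def regular_polygon(n: int, r: float = 0.5) -> MembraneMesh:
    theta = 2.0 * np.pi * np.arange(n) / n
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return MembraneMesh(pos, np.zeros(n, bool), np.nan, np.nan, 0.03)


@pytest.fixture()
def circle_100() -> MembraneMesh:
    return regular_polygon(100)


@pytest.fixture(scope="session")
def resting(params):
    """Default resting shape, relaxed once per test session."""
    return get_resting_mesh(params)


@pytest.fixture()
def spine_mesh(params) -> MembraneMesh:
    return init_spine_mesh(params)
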