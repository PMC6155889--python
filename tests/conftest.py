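"""Shared fixtures.

The default octahedron cage and its full GNM/ANM spectra are expensive
(the level-3 ANM eigenproblem is 4968 x 4968), so they are computed once
per session and shared by the analysis and acceptance tests. Small
single-helix models cover everything that does not need the full cage.
"""
from __future__ import annotations

import numpy as np
import pytest

from nacage import (CageSpec, ENMConfig, build_cage, build_helix,
                    diagonalize, hessian, kirchhoff, select_nodes)


@pytest.fixture(scope="session")
def default_cage():
    return build_cage(CageSpec())

@pytest.fixture(scope="session")
def cage_with_O4():
    return build_cage(CageSpec(include_O4=True))


@pytest.fixture(scope="session")
def cage_nodes_l3(default_cage):
    return select_nodes(default_cage, 3)


@pytest.fixture(scope="session")
def cage_gnm_l3(cage_nodes_l3):
    cfg = ENMConfig(model="GNM")
    return diagonalize(kirchhoff(cage_nodes_l3, cfg), "GNM", cfg,
                       node_meta=cage_nodes_l3.node_meta)


@pytest.fixture(scope="session")
def cage_anm_l3(cage_nodes_l3):
    cfg = ENMConfig(model="ANM")
    return diagonalize(hessian(cage_nodes_l3, cfg), "ANM", cfg,
                       node_meta=cage_nodes_l3.node_meta)


@pytest.fixture(scope="session")
def helix18():
    return build_helix(18, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def helix_nodes(helix18):
    return select_nodes(helix18, 3)


@pytest.fixture(scope="session")
def helix_anm(helix_nodes):
    cfg = ENMConfig(model="ANM")
    return diagonalize(hessian(helix_nodes, cfg), "ANM", cfg,
                       node_meta=helix_nodes.node_meta)


@pytest.fixture(scope="session")
def helix_gnm(helix_nodes):
    cfg = ENMConfig(model="GNM")
    return diagonalize(kirchhoff(helix_nodes, cfg), "GNM", cfg,
                       node_meta=helix_nodes.node_meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
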