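"""Shared fixtures: geometry specs, meshes, and solved flow states.

Heavy solves are session-scoped so independent tests can share them; every
input is generated programmatically (no stored data files).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from lutflow import geometry as geo
from lutflow import meshing as msh
from lutflow.flow_solver import (BoundarySet, FluidProperties, NumericsConfig,
                                 solve_steady_flow)

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def cats_spec():
    return geo.cats_first()


@pytest.fixture(scope="session")
def cats_domain(cats_spec):
    return geo.assemble_domain(cats_spec)


@pytest.fixture(scope="session")
def cats_half_domain(cats_spec):
    return geo.assemble_domain(cats_spec, half=True)


@pytest.fixture(scope="session")
def array_specs():
    return geo.amplification_array()


@pytest.fixture(scope="session")
def poiseuille_state():
    """Creeping pressure-driven flow in a plane channel (laminar closed form).

    Channel 0.6 x 4 cm, driving pressure 1e-4 Pa: Reynolds number well below
    one, so the fully developed profile is the plane-Poiseuille parabola.
    """
    domain = geo.channel_domain(0.6, 4.0)
    mesh = msh.triangulate(domain, 5000)
    cfg = NumericsConfig(turbulence="laminar", max_iter=4000)
    bc = BoundarySet(inlet_gauge_pressure=1e-4)
    sol = solve_steady_flow(mesh, FluidProperties(), bc, cfg)
    return domain, mesh, sol, bc


@pytest.fixture(scope="session")
def cats_coarse_state(cats_spec, cats_half_domain):
    """The index case solved on the symmetric half-domain, coarse screening
    resolution (2.5k full-domain-equivalent elements)."""
    mesh = msh.triangulate(cats_half_domain, 1250)
    cfg = NumericsConfig(max_iter=3000)
    sol = solve_steady_flow(mesh, FluidProperties(), BoundarySet(), cfg)
    return mesh, sol


@pytest.fixture(scope="session")
def cats_full_coarse_state(cats_spec, cats_domain):
    """Full-domain coarse solve of the index case (mirror-symmetry checks)."""
    mesh = msh.triangulate(cats_domain, 2500)
    cfg = NumericsConfig(max_iter=3000)
    sol = solve_steady_flow(mesh, FluidProperties(), BoundarySet(), cfg)
    return mesh, sol
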