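"""Shared fixtures.

Full virtual-surgery runs are expensive, so they are executed lazily and
cached per session: the parametric study cases at the 2.5 mm desk-scale
mesh (the same conditions the reproduction script uses), material-variant
cases at 3.0 mm for ordering checks, and a few small meshes/solves for
unit-level oracles.
"""

from __future__ import annotations

import numpy as np
import pytest

from vpatch.geometry import ARTERY, VesselSpec, build_stenosed_tube
from vpatch.materials import get_material
from vpatch.pipeline import (default_config_path, load_config, parse_cases,
                             run_case)
from vpatch.shellfem import ShellModel, residual_prestress
from vpatch.surgery import IncisionSpec, cut_slit, open_gap, trace_incision
from vpatch.units import mmhg

CASE_MESH = {
    "Baseline": 2.5e-3, "Length_1": 2.5e-3, "Length_2": 2.5e-3,
    "Shape_2": 2.5e-3, "Pressure": 2.5e-3,
    "Material_1": 3.0e-3, "Material_2": 3.0e-3, "Material_3": 3.0e-3,
    "Shape_1": 3.0e-3, "Stenosis": 3.0e-3,
}


@pytest.fixture(scope="session")
def cases():
    """Lazy cache of full pipeline runs, keyed by case name."""
    raw = load_config(default_config_path())
    cache = {}

    def get(name):
        if name not in cache:
            cfg = parse_cases(raw, only=name,
                              mesh_edge_length=CASE_MESH[name])[0]
            cache[name] = run_case(cfg)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def cylinder_solution():
    """Intact healthy tube pressurized to 25 mmHg (membrane oracle)."""
    spec = VesselSpec(stenosis_fraction=0.0, mesh_edge_length=0.004)
    mesh = build_stenosed_tube(spec)
    model = ShellModel(mesh, {ARTERY: get_material("MPA artery 9yr")})
    state = model.solve(pressure=mmhg(25.0), n_increments=4)
    return spec, mesh, model, state


@pytest.fixture(scope="session")
def released_slit():
    """70% stenosed tube, prestressed, cut, released at zero lumen
    pressure with the dead residual-stress load held."""
    return _release(0.70, 0.0035)


@pytest.fixture(scope="session")
def opened_slit(released_slit):
    """The released slit opened to the standard 16 mm mid-slit gap."""
    spec, mesh, model, f_dead = released_slit
    opening = open_gap(model, mesh, 0.016, extra_force=f_dead)
    return spec, mesh, model, f_dead, opening


def _release(stenosis_fraction, h):
    spec = VesselSpec(stenosis_fraction=stenosis_fraction,
                      mesh_edge_length=h)
    mesh0 = build_stenosed_tube(spec)
    artery = get_material("MPA artery 9yr")
    model_a = ShellModel(mesh0, {ARTERY: artery})
    residual_prestress(model_a, mmhg(5.0))
    paths = trace_incision(mesh0, IncisionSpec(),
                           center_z=spec.stenosis_center)
    mesh = cut_slit(mesh0, paths[0])
    parent = mesh.parent_nodes
    f_src = model_a._pressure_forces(model_a.x, mmhg(5.0))
    counts = np.bincount(parent, minlength=mesh0.n_nodes)
    f_dead = f_src[parent] / counts[parent][:, None]
    model = ShellModel(mesh, {ARTERY: artery},
                       initial_positions=model_a.x[parent],
                       initial_triads=model_a.R[parent])
    f_dead6 = np.zeros((mesh.n_nodes, 6))
    f_dead6[:, :3] = f_dead
    f_ext0 = model.external_forces(model.x, 0.0, f_dead)
    f_int0, _, _, _ = model.internal_forces(model.x, model.R)
    hold6 = (f_int0 - f_ext0.reshape(-1)).reshape(-1, 6)
    model.solve(extra_force_start=hold6 + f_dead6, extra_force_end=f_dead6,
                n_increments=6)
    return spec, mesh, model, f_dead


@pytest.fixture(scope="session")
def release_factory():
    """Prestress + cut + release at a chosen stenosis level (cached)."""
    cache = {}

    def get(stenosis_fraction, h=0.0035):
        key = (stenosis_fraction, h)
        if key not in cache:
            cache[key] = _release(stenosis_fraction, h)
        return cache[key]

    return get
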