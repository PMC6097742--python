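"""Performance indices: centerline/area profile, residual stenosis,
tortuosity offset, stress summaries, suture-line mismatch."""

import numpy as np
import pytest

from vpatch.geometry import (ARTERY, PATCH, ShellMesh, VesselSpec,
                             build_stenosed_tube)
from vpatch.indices import (centerline_offset, extract_centerline,
                            residual_stenosis, stress_summary,
                            suture_stress_jump)
from vpatch.materials import MaterialModel
from vpatch.shellfem import FemState, ShellModel, von_mises


class TestCenterline:
    def test_straight_cylinder_profile(self):
        # fine enough that the faceting deficit of the sections is < 1%
        spec = VesselSpec(stenosis_fraction=0.0, mesh_edge_length=0.0015)
        mesh = build_stenosed_tube(spec)
        prof = extract_centerline(mesh, wall_thickness=spec.wall_thickness)
        r0 = spec.inner_radius
        assert np.all(np.abs(prof.areas - np.pi * r0 ** 2)
                      / (np.pi * r0 ** 2) < 0.01)
        assert np.linalg.norm(prof.centroids[:, :2], axis=1).max() < 1e-4
        assert residual_stenosis(prof) < 1.0

    def test_preop_stenosis_matches_construction(self):
        spec = VesselSpec(stenosis_fraction=0.70, mesh_edge_length=0.0025)
        mesh = build_stenosed_tube(spec)
        prof = extract_centerline(mesh, wall_thickness=spec.wall_thickness)
        assert residual_stenosis(prof) == pytest.approx(70.0, abs=2.0)

    def test_arclength_strictly_increasing(self):
        spec = VesselSpec(mesh_edge_length=0.003)
        mesh = build_stenosed_tube(spec)
        prof = extract_centerline(mesh)
        assert np.all(np.diff(prof.arclength) > 0)

    def test_residual_stenosis_rigid_transform_invariant(self):
        spec = VesselSpec(stenosis_fraction=0.70, mesh_edge_length=0.003)
        mesh = build_stenosed_tube(spec)
        s0 = residual_stenosis(extract_centerline(mesh))
        c, s = np.cos(np.radians(4.0)), np.sin(np.radians(4.0))
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        moved = mesh.nodes @ rot.T + np.array([0.002, -0.001, 0.003])
        s1 = residual_stenosis(extract_centerline(mesh, nodes=moved))
        assert s1 == pytest.approx(s0, abs=0.5)

    def test_offset_zero_for_undeformed_tube(self):
        spec = VesselSpec(stenosis_fraction=0.70, mesh_edge_length=0.003)
        mesh = build_stenosed_tube(spec)
        prof = extract_centerline(mesh)
        ref = prof.centroids.copy()
        ref[:, :2] = 0.0
        assert centerline_offset(prof, ref) < 2e-4

    def test_postop_profile_rises_and_falls(self, cases):
        prof = cases("Baseline").profile_postop
        sten = prof.local_stenosis_pct
        i = int(np.argmax(sten))
        assert 0 < i < len(sten) - 1          # interior maximum
        assert sten[i] > sten[0] and sten[i] > sten[-1]

    def test_postop_beats_preop_everywhere_it_matters(self, cases):
        r = cases("Baseline")
        assert r.report.postop_stenosis_pct < r.report.preop_stenosis_pct


def _uniform_state(mesh, vm_value):
    n = mesh.n_nodes
    return FemState(
        displacements=np.zeros((n, 6)),
        element_von_mises=np.full(mesh.n_elements, vm_value),
        reactions=np.zeros((n, 3)),
        converged=True,
        node_positions=mesh.nodes.copy())


class TestStressSummaries:
    def test_uniform_state_max_equals_mean(self):
        mesh = build_stenosed_tube(VesselSpec(mesh_edge_length=0.004))
        state = _uniform_state(mesh, 123.0)
        mx, mean = stress_summary(state, mesh, "artery")
        assert mx == pytest.approx(123.0)
        assert mean == pytest.approx(123.0)

    def test_empty_region_raises(self):
        mesh = build_stenosed_tube(VesselSpec(mesh_edge_length=0.004))
        with pytest.raises(ValueError, match="no patch"):
            stress_summary(_uniform_state(mesh, 1.0), mesh, "patch")

    def test_max_arterial_stress_is_near_the_suture(self, cases):
        r = cases("Baseline")
        mesh, st = r.postop_mesh, r.postop_state
        artery_sel = mesh.element_region == ARTERY
        hot = np.argmax(np.where(artery_sel, st.element_von_mises, -1))
        suture_nodes = set(int(v) for v in mesh.node_tags["suture_line"])
        hot_nodes = set(int(v) for v in mesh.tris[hot])
        hot_xy = st.node_positions[mesh.tris[hot]].mean(axis=0)
        d = min(np.linalg.norm(hot_xy - st.node_positions[v])
                for v in suture_nodes)
        assert (hot_nodes & suture_nodes) or d < 0.006


class TestSutureJump:
    def _strip_model(self, e_patch):
        """Flat two-material strip, uniformly stretched: closed-form
        membrane stresses on each side of the bonded mid-line."""
        nx, ny = 8, 4
        xs = np.linspace(0.0, 0.08, nx + 1)
        ys = np.linspace(0.0, 0.04, ny + 1)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(),
                                 np.zeros((nx + 1) * (ny + 1))])
        tris, region = [], []
        idx = lambda i, j: i * (ny + 1) + j
        for i in range(nx):
            for j in range(ny):
                a, b = idx(i, j), idx(i + 1, j)
                c, d = idx(i + 1, j + 1), idx(i, j + 1)
                tris += [(a, b, c), (a, c, d)]
                region += [ARTERY if i < nx // 2 else PATCH] * 2
        tris = np.asarray(tris)
        region = np.asarray(region)
        mesh = ShellMesh(nodes, tris, region,
                         np.full(len(tris), 1e-3),
                         node_tags={
                             "inlet_ring": np.array([idx(0, j)
                                                     for j in range(ny + 1)]),
                             "outlet_ring": np.array([idx(nx, j)
                                                      for j in range(ny + 1)]),
                             "suture_line": np.array(
                                 [idx(nx // 2, j) for j in range(ny + 1)]),
                         })
        artery = MaterialModel("a", 1.0e6, 0.0, 1e-3)
        patch = MaterialModel("p", e_patch, 0.0, 1e-3)
        model = ShellModel(mesh, {ARTERY: artery, PATCH: patch},
                           fixed_dofs=np.zeros((mesh.n_nodes, 6), bool))
        eps = 0.01
        stretched = nodes.copy()
        stretched[:, 0] *= (1.0 + eps)
        model.x = stretched
        d, _ = model._deformational(model.x, model.R)
        s = model.membrane_stress(d)
        vm = von_mises(s[:, 0], s[:, 1], s[:, 2])
        state = FemState(np.zeros((mesh.n_nodes, 6)), vm,
                         np.zeros((mesh.n_nodes, 3)), True,
                         node_positions=stretched)
        return mesh, state, eps

    def test_identical_materials_give_no_jump(self):
        mesh, state, _ = self._strip_model(1.0e6)
        # small residue from differing element orientations only
        assert suture_stress_jump(state, mesh) < 1e-3 * 1e4

    def test_bimaterial_strip_matches_closed_form(self):
        mesh, state, eps = self._strip_model(3.0e6)
        # uniaxial stretch with nu = 0: vm = E * eps on each side
        expected = abs(3.0e6 - 1.0e6) * eps
        assert suture_stress_jump(state, mesh) == pytest.approx(
            expected, rel=1e-6)

    def test_ptfe_patch_stress_below_porcine(self, cases):
        lo = cases("Baseline").report.max_patch_stress_kpa
        hi = cases("Material_2").report.max_patch_stress_kpa
        assert lo < hi
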