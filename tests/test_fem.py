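"""P1 assembly, solves, derived fields, currents and solver invariants."""

import numpy as np
import pytest

from ttfield import (
    ConductivityField,
    DEFAULT_TISSUE_TABLE,
    TISSUES,
    TissueTable,
    TumorSpec,
    assign_isotropic,
    assemble_system,
    build_slab_phantom,
    current_density,
    electrode_current,
    element_field,
    embed_tumor,
    fit_interior_field,
    rescale_to_target,
    solve_plates,
    solve_potential,
    sphere_in_uniform_field,
    uniform_field_drive,
)
from ttfield.fem import Solution
from ttfield.mesh import TetMesh
from ttfield.phantom import CsfSlot, build_box_phantom


def plates(mesh):
    lo = np.unique(mesh.boundary_patches["plate_lo"])
    hi = np.unique(mesh.boundary_patches["plate_hi"])
    return lo, hi


class TestAssembly:
    def test_row_sums_vanish_before_boundary_conditions(self, two_layer_slab):
        mesh, table = two_layer_slab
        system = assemble_system(mesh, assign_isotropic(mesh, table))
        assert np.abs(system.A.sum(axis=1)).max() < 1e-12

    def test_reference_tet_matches_hand_assembly(self):
        # unit tet (mm): vertices at origin and along each axis
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        mesh = TetMesh(nodes, [[0, 1, 2, 3]], [TISSUES["wm"]])
        system = assemble_system(mesh, assign_isotropic(mesh, TissueTable({"wm": 1.0})))
        # hand computation: grad(lambda) = [(-1,-1,-1), e1, e2, e3] / h, V = h^3/6
        h = 1e-3
        g = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]]) / h
        K = (h**3 / 6.0) * (g @ g.T)
        np.testing.assert_allclose(system.A.toarray(), K, rtol=1e-12)

    def test_scaling_tensors_scales_matrix_exactly(self, two_layer_slab):
        mesh, table = two_layer_slab
        fld = assign_isotropic(mesh, table)
        A1 = assemble_system(mesh, fld).A
        A2 = assemble_system(mesh, ConductivityField(2.0 * fld.tensors)).A
        assert (A2 != 2.0 * A1).nnz == 0

    def test_degenerate_element_rejected_with_index(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        mesh = TetMesh(nodes, [[0, 1, 2, 3]], [TISSUES["wm"]])
        with pytest.raises(ValueError, match="degenerate element 0"):
            assemble_system(mesh, assign_isotropic(mesh, TissueTable({"wm": 1.0})))


class TestSolvePotential:
    def test_homogeneous_slab_interior_potential_is_linear(self):
        mesh = build_slab_phantom([(10.0, "wm")], 20.0, 1.0)
        fld = assign_isotropic(mesh, TissueTable({"wm": 1.0}))
        sol = solve_plates(mesh, fld, delta_V=1.0)
        # exact P1 solution: V varies linearly from +0.5 (lo) to -0.5 (hi)
        want = 0.5 - mesh.nodes[:, 2] / 10.0
        assert np.abs(sol.V - want).max() < 1e-8

    def test_discrete_maximum_principle(self, two_layer_slab):
        mesh, table = two_layer_slab
        sol = solve_plates(mesh, assign_isotropic(mesh, table), delta_V=1.0)
        assert sol.V.min() >= -0.5 - 1e-12 and sol.V.max() <= 0.5 + 1e-12

    def test_two_layer_interface_potential(self, two_layer_slab):
        # series-resistor oracle: with sigma 1|2 over 5+5 mm the interface
        # sits at 2/3 of the drop from the sigma=1 side
        mesh, table = two_layer_slab
        system = assemble_system(mesh, assign_isotropic(mesh, table))
        lo, hi = plates(mesh)
        V = solve_potential(
            system,
            (np.concatenate([lo, hi]),
             np.concatenate([np.zeros(len(lo)), np.ones(len(hi))])),
        )
        interface = np.isclose(mesh.nodes[:, 2], 5.0)
        np.testing.assert_allclose(V[interface], 2.0 / 3.0, atol=1e-6)

    def test_single_potential_value_rejected(self, two_layer_slab):
        mesh, table = two_layer_slab
        system = assemble_system(mesh, assign_isotropic(mesh, table))
        lo, _ = plates(mesh)
        with pytest.raises(ValueError, match="two distinct"):
            solve_potential(system, (lo, np.zeros(len(lo))))

    def test_unknown_method_rejected(self, two_layer_slab):
        mesh, table = two_layer_slab
        system = assemble_system(mesh, assign_isotropic(mesh, table))
        lo, hi = plates(mesh)
        dirichlet = (np.concatenate([lo, hi]),
                     np.concatenate([np.zeros(len(lo)), np.ones(len(hi))]))
        with pytest.raises(ValueError, match="method"):
            solve_potential(system, dirichlet, method="amg")


class TestDerivedFields:
    def test_linear_potential_gives_unit_field(self, two_layer_slab):
        mesh, _ = two_layer_slab
        V = mesh.nodes[:, 0] * 1e-3  # V = x with x in metres
        E = element_field(mesh, V)
        np.testing.assert_allclose(E, np.tile([-1.0, 0, 0], (len(mesh.tets), 1)),
                                   atol=1e-9)

    def test_constant_potential_gives_zero_field(self, two_layer_slab):
        mesh, _ = two_layer_slab
        E = element_field(mesh, np.full(len(mesh.nodes), 3.7))
        np.testing.assert_allclose(E, 0.0, atol=1e-9)

    def test_layer_fields_match_series_oracle(self, two_layer_slab):
        mesh, table = two_layer_slab
        sol = solve_plates(mesh, assign_isotropic(mesh, table), delta_V=1.0)
        normE = sol.norm_E()
        e1 = normE[mesh.tet_label == TISSUES["gm"]]
        e2 = normE[mesh.tet_label == TISSUES["wm"]]
        np.testing.assert_allclose(e1, 400.0 / 3.0, rtol=1e-3)
        np.testing.assert_allclose(e2, 200.0 / 3.0, rtol=1e-3)

    def test_ohms_law_isotropic_and_anisotropic(self):
        E = np.array([[100.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        fld = ConductivityField(np.stack([2.0 * np.eye(3), np.diag([1.0, 2.0, 3.0])]))
        J = current_density(E, fld)
        np.testing.assert_array_equal(J[0], [200.0, 0.0, 0.0])
        np.testing.assert_array_equal(J[1], [1.0, 2.0, 3.0])

    def test_series_stack_has_continuous_normal_current(self, two_layer_slab):
        mesh, table = two_layer_slab
        sol = solve_plates(mesh, assign_isotropic(mesh, table), delta_V=1.0)
        jz = np.abs(sol.J[:, 2])
        np.testing.assert_allclose(
            jz[mesh.tet_label == TISSUES["gm"]].mean(),
            jz[mesh.tet_label == TISSUES["wm"]].mean(),
            rtol=1e-6,
        )

    def test_csf_slot_carries_far_higher_current_density(self):
        # parallel paths: the well-conducting CSF slot draws the current
        mesh = build_slab_phantom(
            [(20.0, "wm")], (30.0, 10.0), 1.0,
            slot=CsfSlot(x_range=(14.0, 16.0), depth=10.0),
        )
        sol = solve_plates(mesh, assign_isotropic(mesh), delta_V=1.0)
        normJ = np.linalg.norm(sol.J, axis=1)
        c = mesh.centroids()
        in_slot = mesh.tet_label == TISSUES["csf"]
        beside = (
            (mesh.tet_label == TISSUES["wm"])
            & (c[:, 2] > 12.0)
            & (np.abs(c[:, 0] - 15.0) > 3.0)
            & (np.abs(c[:, 0] - 15.0) < 8.0)
        )
        assert normJ[in_slot].mean() > 3.0 * normJ[beside].mean()


class TestCurrentsAndRescale:
    @pytest.fixture(scope="class")
    def unit_slab(self):
        mesh = build_slab_phantom([(10.0, "wm")], 20.0, 1.0)
        fld = assign_isotropic(mesh, TissueTable({"wm": 1.0}))
        return mesh, fld

    def test_slab_current_matches_analytic(self, unit_slab):
        mesh, fld = unit_slab
        sol = solve_plates(mesh, fld, delta_V=1.0)
        # I = sigma A dV / d = 1 * (20 mm)^2 * 1 V / 10 mm = 0.04 A
        assert sol.source_current_A == pytest.approx(0.04, rel=1e-6)

    def test_source_and_sink_currents_cancel(self, unit_slab):
        mesh, fld = unit_slab
        sol = solve_plates(mesh, fld, delta_V=1.0)
        rel = abs(sol.source_current_A + sol.sink_current_A) / abs(sol.source_current_A)
        assert rel < 1e-9

    def test_doubling_voltage_doubles_current_exactly(self, unit_slab):
        mesh, fld = unit_slab
        system = assemble_system(mesh, fld)
        s1 = solve_plates(mesh, fld, delta_V=1.0, system=system)
        s2 = solve_plates(mesh, fld, delta_V=2.0, system=system)
        assert s2.source_current_A == 2.0 * s1.source_current_A
        np.testing.assert_array_equal(s2.E, 2.0 * s1.E)

    def test_rescale_hits_target_exactly_and_is_idempotent(self, unit_slab):
        mesh, fld = unit_slab
        sol = solve_plates(mesh, fld, delta_V=1.0)
        scaled = rescale_to_target(sol, 0.9)
        assert abs(scaled.source_current_A - 0.9) / 0.9 < 1e-12
        again = rescale_to_target(scaled, 0.9)
        np.testing.assert_array_equal(again.V, scaled.V)
        np.testing.assert_array_equal(again.E, scaled.E)

    def test_rescale_requires_measured_current(self):
        sol = Solution(V=np.zeros(3), E=np.zeros((1, 3)), J=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            rescale_to_target(sol, 0.9)


class TestSolverInvariants:
    def test_reciprocity_swapping_plates_negates_potentials(self, two_layer_slab):
        mesh, table = two_layer_slab
        fld = assign_isotropic(mesh, table)
        system = assemble_system(mesh, fld)
        lo, hi = plates(mesh)
        idx = np.concatenate([lo, hi])
        v1 = np.concatenate([np.full(len(lo), 0.5), np.full(len(hi), -0.5)])
        V1 = solve_potential(system, (idx, v1))
        V2 = solve_potential(system, (idx, -v1))
        np.testing.assert_array_equal(V2, -V1)

    def test_isotropic_tensors_with_equal_eigenvalues_match_scalar_solve(
        self, two_layer_slab
    ):
        mesh, table = two_layer_slab
        iso = assign_isotropic(mesh, table)
        sol_iso = solve_plates(mesh, iso, delta_V=1.0)
        sol_tensor = solve_plates(mesh, ConductivityField(iso.tensors.copy()),
                                  delta_V=1.0)
        np.testing.assert_allclose(sol_tensor.V, sol_iso.V, atol=1e-9)

    def test_mirror_symmetry_reflects_field(self):
        slot = CsfSlot(x_range=(18.0, 21.0), depth=8.0)
        mesh = build_slab_phantom([(15.0, "wm")], (30.0, 9.0), 1.5, slot=slot)
        # mirror x -> 30 - x; swap two tet vertices to restore orientation
        mirrored = mesh.copy()
        mirrored.nodes = mesh.nodes * np.array([-1.0, 1.0, 1.0]) + np.array([30.0, 0, 0])
        mirrored.tets = mesh.tets[:, [0, 2, 1, 3]]
        mirrored = TetMesh(mirrored.nodes, mirrored.tets, mesh.tet_label.copy(),
                           boundary_patches=mesh.boundary_patches)
        fld = assign_isotropic(mesh)
        s1 = solve_plates(mesh, fld, delta_V=1.0)
        s2 = solve_plates(mirrored, fld, delta_V=1.0)
        scale = np.abs(s1.E).max()
        np.testing.assert_allclose(s2.E[:, 0], -s1.E[:, 0], atol=1e-6 * scale)
        np.testing.assert_allclose(s2.E[:, 1:], s1.E[:, 1:], atol=1e-6 * scale)

    def test_sphere_field_error_decreases_under_refinement(self):
        # Maxwell-sphere oracle: conductive 20 mm sphere in a weaker medium
        want = sphere_in_uniform_field(1.00, 0.24, 100.0)
        table = TissueTable({**DEFAULT_TISSUE_TABLE, "wm": 0.24, "tumor_shell": 1.00})
        errs = []
        for fine in (2.5, 1.5):
            box = build_box_phantom(
                110.0, "wm", resolution=6.0,
                refine_center=(0, 0, 0), refine_radius=13.0, fine_resolution=fine,
            )
            mesh = embed_tumor(box, TumorSpec((0, 0, 0), solid=True),
                               allowed_labels=("wm",))
            sol = uniform_field_drive(mesh, assign_isotropic(mesh, table), E0=100.0)
            got = fit_interior_field(mesh, sol.V, (0, 0, 0), 8.0)
            errs.append(abs(got - want) / want)
        assert errs[1] < errs[0]
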