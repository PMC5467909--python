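"""Phantom geometry: slabs, nested-ellipsoid head, tumours, fibre fields."""

import math

import numpy as np
import pytest

from ttfield import (
    TISSUES,
    TumorSpec,
    build_head_phantom,
    build_slab_phantom,
    embed_tumor,
    synth_fiber_field,
    validate_mesh,
)
from ttfield.phantom import CsfSlot, build_box_phantom

SPHERE_VOL_20MM = 4.0 / 3.0 * math.pi * 10.0**3  # 4188.79 mm^3


class TestSlabPhantom:
    def test_single_layer_volume_exact(self):
        mesh = build_slab_phantom([(10.0, "wm")], 20.0, 1.0)
        assert mesh.total_volume() == pytest.approx(4000.0, rel=1e-9)
        validate_mesh(mesh)

    def test_two_equal_layers_split_elements_evenly(self):
        mesh = build_slab_phantom([(5.0, "gm"), (5.0, "wm")], 20.0, 1.0)
        # brute-force oracle: classify every element by its centroid height
        cz = mesh.nodes[mesh.tets].mean(axis=1)[:, 2]
        expect_gm = (cz < 5.0).sum()
        assert (mesh.tet_label == TISSUES["gm"]).sum() == expect_gm
        assert (mesh.tet_label == TISSUES["gm"]).sum() == len(mesh.tets) // 2

    def test_empty_layers_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_slab_phantom([], 20.0, 1.0)

    def test_nonpositive_thickness_names_layer(self):
        with pytest.raises(ValueError, match="layer 1"):
            build_slab_phantom([(5.0, "gm"), (-1.0, "wm")], 20.0, 1.0)

    def test_plate_patches_cover_lateral_area(self):
        mesh = build_slab_phantom([(4.0, "wm")], (10.0, 20.0), 1.0)
        for name in ("plate_lo", "plate_hi"):
            tris = mesh.boundary_patches[name]
            p = mesh.nodes[tris]
            area = 0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
            ).sum()
            assert area == pytest.approx(200.0, rel=1e-12)

    def test_csf_slot_labels_expected_volume(self):
        mesh = build_slab_phantom(
            [(20.0, "wm")], (30.0, 10.0), 1.0,
            slot=CsfSlot(x_range=(14.0, 16.0), depth=10.0),
        )
        assert mesh.label_volume("csf") == pytest.approx(2.0 * 10.0 * 10.0, rel=1e-9)


class TestHeadPhantom:
    def test_total_volume_close_to_ellipsoid(self, head_symmetric):
        want = 4.0 / 3.0 * math.pi * 75.0 * 95.0 * 85.0
        assert head_symmetric.total_volume() == pytest.approx(want, rel=0.05)

    def test_exactly_five_tissues(self, head_symmetric):
        assert set(np.unique(head_symmetric.tet_label)) == {
            TISSUES[t] for t in ("skin", "bone", "csf", "gm", "wm")
        }

    def test_wm_centroids_inside_innermost_shell(self, head_symmetric):
        c = head_symmetric.centroids()[head_symmetric.tet_label == TISSUES["wm"]]
        r2 = ((c / np.array([55.0, 75.0, 65.0])) ** 2).sum(axis=1)
        assert np.all(r2 <= 1.0)

    def test_mesh_is_valid(self, head_refined):
        validate_mesh(head_refined)

    def test_non_nested_shells_rejected_naming_pair(self):
        bad = {
            "skin": (75.0, 95.0, 85.0),
            "bone": (69.0, 89.0, 79.0),
            "csf": (70.0, 82.0, 72.0),  # pokes out of bone along x
            "gm": (59.0, 79.0, 69.0),
            "wm": (55.0, 75.0, 65.0),
        }
        with pytest.raises(ValueError, match="csf"):
            build_head_phantom(semi_axes=bad, resolution=8.0)

    def test_compartment_volume_errors_decrease_with_resolution(self):
        # aggregate over shells: per-label signed errors cancel and
        # oscillate, but the summed misfit shrinks as the lattice refines
        from ttfield import DEFAULT_SEMI_AXES

        order = ("wm", "gm", "csf", "bone", "skin")
        totals = []
        for r in (12.0, 4.0):
            mesh = build_head_phantom(resolution=r)
            cum, err = 0.0, 0.0
            for lab in order:
                cum += mesh.label_volume(lab)
                a = DEFAULT_SEMI_AXES[lab]
                want = 4.0 / 3.0 * math.pi * a[0] * a[1] * a[2]
                err += abs(cum - want) / want
            totals.append(err)
        assert totals[1] < totals[0]


class TestEmbedTumor:
    @pytest.fixture(scope="class")
    def fine_box(self):
        return build_slab_phantom([(40.0, "wm")], 40.0, 1.25)

    def test_volume_within_3pct_of_sphere(self, fine_box):
        mesh = embed_tumor(fine_box, TumorSpec((20.0, 20.0, 20.0)))
        got = mesh.label_volume("tumor_shell") + mesh.label_volume("tumor_core")
        assert got == pytest.approx(SPHERE_VOL_20MM, rel=0.03)

    def test_core_fraction_matches_radius_cube(self, fine_box):
        mesh = embed_tumor(fine_box, TumorSpec((20.0, 20.0, 20.0)))
        total = mesh.label_volume("tumor_shell") + mesh.label_volume("tumor_core")
        frac = mesh.label_volume("tumor_core") / total
        assert frac == pytest.approx(0.343, abs=0.02)

    def test_solid_tumor_has_no_core(self, fine_box):
        mesh = embed_tumor(fine_box, TumorSpec((20.0, 20.0, 20.0), solid=True))
        assert (mesh.tet_label == TISSUES["tumor_core"]).sum() == 0

    def test_solid_embedding_idempotent(self, fine_box):
        spec = TumorSpec((20.0, 20.0, 20.0), solid=True)
        once = embed_tumor(fine_box, spec)
        twice = embed_tumor(once, spec)
        np.testing.assert_array_equal(once.tet_label, twice.tet_label)

    def test_tumor_volume_error_decreases_with_resolution(self):
        errs = []
        for r in (2.5, 1.25):
            box = build_slab_phantom([(40.0, "wm")], 40.0, r)
            mesh = embed_tumor(box, TumorSpec((20.0, 20.0, 20.0)))
            got = mesh.label_volume("tumor_shell") + mesh.label_volume("tumor_core")
            errs.append(abs(got - SPHERE_VOL_20MM) / SPHERE_VOL_20MM)
        assert errs[1] < errs[0]

    def test_placement_outside_brain_rejected(self, head_refined):
        with pytest.raises(ValueError, match="dural"):
            embed_tumor(head_refined, TumorSpec((70.0, 0.0, 0.0)))

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            TumorSpec((0, 0, 0), outer_diameter=10.0, core_diameter=12.0)


class TestFiberField:
    @pytest.fixture(scope="class")
    def box(self):
        return build_box_phantom(10.0, "wm", resolution=2.5)

    def test_fa_zero_gives_exact_identity(self, box):
        ff = synth_fiber_field(box, "uniform", fa=0.0, direction=(1.0, 0.0, 0.0))
        np.testing.assert_array_equal(
            ff.tensors, np.broadcast_to(np.eye(3), ff.tensors.shape)
        )

    def test_uniform_principal_direction_exact(self, box):
        d = np.array([0.0, 1.0, 0.0])
        ff = synth_fiber_field(box, "uniform", fa=0.5, direction=d)
        np.testing.assert_array_equal(ff.directions, np.tile(d, (len(box.tets), 1)))
        w, v = np.linalg.eigh(ff.tensors[0])
        assert abs(abs(v[:, -1] @ d) - 1.0) < 1e-12

    @pytest.mark.parametrize("fa", [0.3, 0.7, 0.95])
    def test_requested_fa_recovered_from_eigenvalues(self, box, fa):
        ff = synth_fiber_field(box, "uniform", fa=fa, direction=(1, 1, 1))
        w = np.linalg.eigvalsh(ff.tensors)
        num = ((w - w.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        got = np.sqrt(1.5 * num / (w**2).sum(axis=1))
        np.testing.assert_allclose(got, fa, atol=1e-10)

    @pytest.mark.parametrize("pattern", ["radial", "tangential_shells"])
    def test_patterned_fields_are_unit_norm_spd(self, box, pattern):
        ff = synth_fiber_field(box, pattern, fa=0.6)
        np.testing.assert_allclose(np.linalg.norm(ff.directions, axis=1), 1.0)
        assert np.linalg.eigvalsh(ff.tensors).min() > 0

    def test_fa_out_of_range_rejected(self, box):
        with pytest.raises(ValueError):
            synth_fiber_field(box, "uniform", fa=1.0, direction=(1, 0, 0))
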