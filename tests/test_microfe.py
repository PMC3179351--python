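"""Voxel micro-FE: meshing, solving, stiffness and von Mises stress."""

import numpy as np
import pytest

import vertload as v
from vertload.microfe import NoLoadPathError, hex8_stiffness


def solid_labels(n, vox=60.0):
    return v.LabeledVolume(np.ones((n, n, n), np.uint8), vox)


NO_PMMA = dict(pmma_layer_thickness_vox=0)


class TestBuildModel:
    def test_solid_cube_element_and_node_counts(self):
        model = v.build_fe_model(solid_labels(10), load=v.LoadCase(**NO_PMMA))
        assert model.n_elements == 1000
        assert model.n_nodes == 11**3

    def test_shell_removal_noop_without_shell_labels(self):
        m1 = v.build_fe_model(solid_labels(6), load=v.LoadCase(**NO_PMMA), include_shell=True)
        m2 = v.build_fe_model(solid_labels(6), load=v.LoadCase(**NO_PMMA), include_shell=False)
        assert m1.n_elements == m2.n_elements
        assert np.array_equal(m1.elem_nodes, m2.elem_nodes)

    def test_shell_removal_drops_exactly_shell_count(self, peeled_phantom):
        labels, gt = peeled_phantom
        lc = v.LoadCase(pmma_layer_thickness_vox=2)
        mi = v.build_fe_model(labels, load=lc, include_shell=True)
        mt = v.build_fe_model(labels, load=lc, include_shell=False)
        n_shell = int((labels.data == 2).sum())
        assert mi.n_removed_floating == 0 and mt.n_removed_floating == 0
        assert mi.n_elements - mt.n_elements == n_shell

    def test_pmma_layers_added_full_cross_section(self):
        model = v.build_fe_model(solid_labels(4), load=v.LoadCase(pmma_layer_thickness_vox=2))
        assert model.n_elements == 4**3 + 2 * 2 * 16
        assert (model.elem_mat == 1).sum() == 64

    def test_no_load_path_raises(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[2:4, 2:4, 0:3] = 1  # column not reaching the top
        with pytest.raises(NoLoadPathError):
            v.build_fe_model(v.LabeledVolume(data, 60.0), load=v.LoadCase(**NO_PMMA))


class TestSolve:
    def test_block_oracle_stiffness(self, solid_block_result):
        """Homogeneous 20^3 block at 60 µm, frictionless: K = E*A/L
        exactly (uniform strain is representable by trilinear bricks)."""
        model, res = solid_block_result
        L = 20 * 0.06
        expected = 10_000.0 * L**2 / L  # E*A/L in N/mm
        assert res.stiffness_n_per_mm == pytest.approx(expected, rel=1e-6)
        assert v.stiffness(res) == pytest.approx(expected / 1000.0, rel=1e-6)

    def test_equilibrium_of_reactions(self, solid_block_result):
        _, res = solid_block_result
        assert abs(res.reaction_top_n + res.reaction_bottom_n) <= 1e-5 * abs(res.reaction_top_n)

    def test_stiffness_linear_in_modulus_and_strain(self):
        labels = solid_labels(6)
        k = {}
        for e_mod, strain in [(10_000.0, 0.01), (20_000.0, 0.01), (10_000.0, 0.005)]:
            model = v.build_fe_model(
                labels, v.MaterialSpec(tissue_modulus_mpa=e_mod),
                v.LoadCase(apparent_strain=strain, **NO_PMMA),
            )
            k[(e_mod, strain)] = v.solve(model, rel_tol=1e-9).stiffness_n_per_mm
        assert k[(20_000.0, 0.01)] == pytest.approx(2 * k[(10_000.0, 0.01)], rel=1e-6)
        assert k[(10_000.0, 0.005)] == pytest.approx(k[(10_000.0, 0.01)], rel=1e-6)

    def test_block_oracle_resolution_independent(self):
        """Frictionless solid-block stiffness is exact at any mesh
        resolution; compare 6^3 against 12^3 of the same physical cube."""
        k = []
        for n, vox in [(6, 120.0), (12, 60.0)]:
            model = v.build_fe_model(solid_labels(n, vox), load=v.LoadCase(**NO_PMMA))
            k.append(v.solve(model, rel_tol=1e-9).stiffness_n_per_mm)
        assert k[0] == pytest.approx(k[1], rel=1e-6)

    def test_floating_fragments_do_not_change_stiffness(self):
        data = np.zeros((10, 10, 8), np.uint8)
        data[2:5, 2:5, :] = 1  # load-bearing column
        base = v.build_fe_model(v.LabeledVolume(data.copy(), 60.0), load=v.LoadCase(**NO_PMMA))
        k0 = v.solve(base, rel_tol=1e-9).stiffness_n_per_mm
        data[7:9, 7:9, 3:5] = 1  # floating island
        model = v.build_fe_model(v.LabeledVolume(data, 60.0), load=v.LoadCase(**NO_PMMA))
        assert model.n_removed_floating == 8
        assert v.solve(model, rel_tol=1e-9).stiffness_n_per_mm == pytest.approx(k0, rel=1e-9)

    def test_bonded_mode_is_stiffer_or_equal(self):
        labels = solid_labels(6)
        kf = v.solve(v.build_fe_model(labels, load=v.LoadCase(bc_mode="frictionless", **NO_PMMA))).stiffness_n_per_mm
        kb = v.solve(v.build_fe_model(labels, load=v.LoadCase(bc_mode="bonded", **NO_PMMA))).stiffness_n_per_mm
        assert kb >= kf * (1 - 1e-9)

    def test_removing_material_never_stiffens(self):
        """Displacement-controlled compression: deleting elements can
        only lower the apparent stiffness (checked on seeded phantoms
        via shell removal in the acceptance suite; here on a notch)."""
        data = np.ones((8, 8, 8), np.uint8)
        full = v.solve(v.build_fe_model(v.LabeledVolume(data.copy(), 60.0), load=v.LoadCase(**NO_PMMA))).stiffness_n_per_mm
        data[3:5, 3:5, 3:5] = 0
        notched = v.solve(v.build_fe_model(v.LabeledVolume(data, 60.0), load=v.LoadCase(**NO_PMMA))).stiffness_n_per_mm
        assert notched < full


class TestVonMises:
    def test_uniform_uniaxial_state(self, solid_block_result):
        """Frictionless uniaxial compression: von Mises equals |sigma| =
        E*strain in every element."""
        _, res = solid_block_result
        expected = 10_000.0 * 0.01
        assert np.allclose(res.von_mises_mpa, expected, rtol=1e-5)

    def test_hydrostatic_state_is_zero(self):
        """A pure volumetric displacement field has zero deviatoric
        stress; apply it directly through the element B-matrix path."""
        from vertload.microfe import _von_mises_all

        model = v.build_fe_model(solid_labels(3), load=v.LoadCase(**NO_PMMA))
        coords = model.node_coords.astype(float) * model.h_mm
        u = (1e-3 * coords).ravel()  # u = c*x -> eps = c*I
        vm = _von_mises_all(model, u)
        assert np.allclose(vm, 0.0, atol=1e-9)

    def test_single_column_carries_bar_stress(self):
        data = np.zeros((8, 8, 10), np.uint8)
        data[3:5, 3:5, :] = 1
        model = v.build_fe_model(v.LabeledVolume(data, 60.0), load=v.LoadCase(**NO_PMMA))
        res = v.solve(model, rel_tol=1e-9)
        expected = 10_000.0 * 0.01
        assert np.median(res.von_mises_mpa) == pytest.approx(expected, rel=0.02)


class TestElementStiffnessMatrix:
    def test_symmetric_positive_semidefinite_with_rigid_modes(self):
        ke = hex8_stiffness(10_000.0, 0.3, 0.06)
        assert np.allclose(ke, ke.T, atol=1e-9)
        evals = np.linalg.eigvalsh(ke)
        assert np.sum(np.abs(evals) < 1e-6 * evals.max()) == 6  # 3 translations + 3 rotations
        assert evals[evals > 1e-6 * evals.max()].min() > 0

    def test_rigid_translation_produces_no_force(self):
        ke = hex8_stiffness(1.0, 0.3, 1.0)
        u = np.tile([1.0, -2.0, 0.5], 8)
        assert np.allclose(ke @ u, 0.0, atol=1e-12)


class TestValidation:
    def test_bad_material_and_load_rejected(self):
        with pytest.raises(ValueError):
            v.MaterialSpec(tissue_poisson=0.5).validate()
        with pytest.raises(ValueError):
            v.LoadCase(apparent_strain=0.0).validate()
        with pytest.raises(ValueError):
            v.LoadCase(bc_mode="sticky").validate()
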