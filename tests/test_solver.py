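import numpy as np
import pytest

from conftest import uniform_conductivity
from tesfv.conductivity import AIR_SIGMA, TissueTable, isotropic_field
from tesfv.phantoms import ortho_box_mesh, slab_mesh
from tesfv.solver import (
    BoundarySpec,
    FieldSolution,
    SolverConfig,
    assemble,
    current_density,
    gradient_lsq,
    integrate_current,
    scale_solution,
    solve_potential,
    solve_tes,
)

TIGHT = SolverConfig(outer_tol=1e-13, max_outer=900)
BC10 = BoundarySpec({"zmin": 5.0, "zmax": -5.0})


def solve(mesh, cond, bc=BC10, cfg=TIGHT):
    system = assemble(mesh, cond, bc, cfg)
    phi = solve_potential(system)
    return system, phi


class TestAssembly:
    def test_orthogonal_mesh_has_zero_correction(self, ortho_slab):
        system = assemble(ortho_slab, uniform_conductivity(ortho_slab), BC10, SolverConfig())
        rng = np.random.default_rng(0)
        grad = rng.normal(size=(system.n, 3))
        corr = system.correction_rhs(grad, include_boundary=False)
        assert np.abs(corr).max() < 1e-10 * np.abs(grad).max()

    def test_interior_row_sums_vanish(self, uniform_slab):
        system = assemble(uniform_slab, uniform_conductivity(uniform_slab), BC10, SolverConfig())
        row_sums = np.asarray(system.M.sum(axis=1)).ravel()
        # rows of cells without Dirichlet faces must sum to zero (conservation)
        has_dirichlet = np.zeros(system.n, dtype=bool)
        has_dirichlet[system.cell_index[system.b_owner]] = True
        assert np.abs(row_sums[~has_dirichlet]).max() < 1e-10

    def test_matrix_is_symmetric(self, uniform_slab):
        system = assemble(uniform_slab, uniform_conductivity(uniform_slab), BC10, SolverConfig())
        assert abs(system.M - system.M.T).max() < 1e-12

    def test_scaling_conductivity_leaves_phi_unchanged(self, uniform_slab):
        _, phi1 = solve(uniform_slab, uniform_conductivity(uniform_slab, 1.0))
        _, phi2 = solve(uniform_slab, uniform_conductivity(uniform_slab, 2.0))
        np.testing.assert_allclose(phi1, phi2, atol=1e-10)

    def test_singular_tensor_reported(self, uniform_slab):
        cond = uniform_conductivity(uniform_slab)
        cond.tensors[3] = np.nan
        with pytest.raises(ValueError, match="cell 3"):
            assemble(uniform_slab, cond, BC10, SolverConfig())


class TestPotentialSolve:
    def test_linear_field_exact_on_nonorthogonal_mesh(self, uniform_slab):
        _, phi = solve(uniform_slab, uniform_conductivity(uniform_slab))
        z = uniform_slab.cell_centroids()[:, 2]
        exact = 5.0 - 10.0 * (z + 0.5) / 8.0
        assert np.abs(phi - exact).max() < 1e-10

    def test_two_layer_slab_matches_series_resistance(self):
        mesh = ortho_box_mesh((2, 2, 8), label_of_k=lambda k: np.where(k < 4, 1, 2))
        cond = isotropic_field(mesh, TissueTable({1: 1.0, 2: 0.5}))
        cfg = SolverConfig(face_interpolation="harmonic", outer_tol=1e-13, max_outer=400)
        system, phi = solve(mesh, cond, cfg=cfg)
        z = mesh.cell_centroids()[:, 2] + 0.5
        r1, r2 = 4.0 / 1.0, 4.0 / 0.5
        flux = 10.0 / (r1 + r2)
        exact = np.where(z < 4, 5 - flux * z, 5 - flux * 4 - (z - 4) * 2 * flux)
        assert np.abs(phi - exact).max() < 1e-8
        E = gradient_lsq(system, phi)
        interior1 = (mesh.cell_labels == 1) & (np.abs(z - 2) < 1.4)
        interior2 = (mesh.cell_labels == 2) & (np.abs(z - 6) < 1.4)
        ratio = np.abs(E[interior2, 2]).mean() / np.abs(E[interior1, 2]).mean()
        assert ratio == pytest.approx(2.0, abs=1e-8)

    def test_dirichlet_scaling_linearity(self, uniform_slab):
        cond = uniform_conductivity(uniform_slab)
        _, phi1 = solve(uniform_slab, cond)
        _, phi3 = solve(uniform_slab, cond, bc=BoundarySpec({"zmin": 15.0, "zmax": -15.0}))
        np.testing.assert_allclose(phi3, 3.0 * phi1, atol=1e-9)

    def test_maximum_principle(self, coarse_sphere_mesh):
        """The implicit 2-point scheme is an M-matrix: its solution obeys the
        discrete maximum principle strictly.  The explicit non-orthogonality
        correction may overshoot slightly on coarse, strongly non-orthogonal
        cells, so the corrected solve is only held to a small tolerance."""
        cond = isotropic_field(coarse_sphere_mesh, TissueTable({1: 0.465, 2: 0.01, 3: 0.33}))
        from tesfv.phantoms import tag_boundary_patch

        mesh = tag_boundary_patch(coarse_sphere_mesh, "north", lambda c, n: c[:, 2] > 85)
        mesh = tag_boundary_patch(mesh, "south", lambda c, n: c[:, 2] < -85)
        bc = BoundarySpec({"north": 5.0, "south": -5.0})
        _, phi = solve(mesh, cond, bc=bc, cfg=SolverConfig(correction="none"))
        assert phi.min() >= -5.0 - 1e-9
        assert phi.max() <= 5.0 + 1e-9
        _, phi_c = solve(mesh, cond, bc=bc, cfg=SolverConfig())
        assert phi_c.min() >= -5.0 * 1.10
        assert phi_c.max() <= 5.0 * 1.10

    def test_insulator_cells_are_excluded(self):
        mesh = slab_mesh((2, 2, 6), label_of_k=lambda k: np.where(k < 4, 1, 9))
        cond = isotropic_field(mesh, TissueTable({1: 1.0, 9: AIR_SIGMA}))
        bc = BoundarySpec({"zmin": 5.0})
        system = assemble(mesh, cond, bc, SolverConfig())
        assert system.n == (mesh.cell_labels == 1).sum()


class TestGradient:
    def test_linear_phi_gives_exact_gradient(self, ortho_slab):
        # the orthogonal box has full-rank face-neighbour stencils everywhere,
        # so no cell needs the zero-normal-gradient regularization that would
        # bias an arbitrary affine field
        uniform_slab = ortho_slab
        system = assemble(uniform_slab, uniform_conductivity(uniform_slab), BC10, TIGHT)
        c = uniform_slab.cell_centroids()
        a = np.array([0.7, -1.3, 2.1])
        phi_cells = c @ a + 4.0
        # impose consistent Dirichlet data so boundary pseudo-neighbours agree
        system.b_vals = system.geo.bnd_centroid[system.b_faces] @ a + 4.0
        g = system.gradient(phi_cells[system.active])
        np.testing.assert_allclose(g, np.broadcast_to(a, g.shape), atol=1e-12)

    def test_constant_phi_gives_zero(self, uniform_slab):
        system = assemble(uniform_slab, uniform_conductivity(uniform_slab), BC10, TIGHT)
        system.b_vals = np.full_like(system.b_vals, 3.0)
        g = system.gradient(np.full(system.n, 3.0))
        assert np.abs(g).max() < 1e-13

    def test_quadratic_phi_converges_first_order(self):
        errs = []
        for nz in (8, 16, 32):
            mesh = slab_mesh((2, 2, nz), spacing=8.0 / nz)
            system = assemble(mesh, uniform_conductivity(mesh), BC10, TIGHT)
            z = mesh.cell_centroids()[:, 2]
            phi = z**2
            system.b_vals = system.geo.bnd_centroid[system.b_faces, 2] ** 2
            g = system.gradient(phi[system.active])
            errs.append(np.abs(g[:, 2] - 2 * z).max())
        assert errs[0] > errs[1] > errs[2]
        order = np.log2(errs[1] / errs[2])
        assert order > 0.8


class TestCurrentAndScaling:
    def test_uniform_current_through_flat_patch(self, uniform_slab):
        J = np.tile([0.0, 0.0, 1.0], (uniform_slab.n_cells, 1))  # A/m^2
        I = integrate_current(uniform_slab, J, "zmax")  # 9 mm^2 patch
        assert I == pytest.approx(9e-6, rel=1e-12)

    def test_current_density_tensor_product(self):
        sigma = np.diag([0.3984470, 0.0398447, 0.0398447])
        from tesfv.conductivity import ConductivityField

        cond = ConductivityField(sigma[None])
        J = current_density(np.array([[0.0, 1.0, 0.0]]), cond)
        np.testing.assert_allclose(J, [[0.0, 0.0398447, 0.0]], atol=1e-12)

    def test_scale_solution_halves_for_double_current(self):
        sol = FieldSolution(
            phi=np.ones(4), E=np.ones((4, 3)), J=np.ones((4, 3)), I_measured=2e-3
        )
        out = scale_solution(sol, 1e-3)
        assert out.s == pytest.approx(0.5)
        np.testing.assert_allclose(out.phi, 0.5)

    def test_scale_identity_when_currents_match(self):
        sol = FieldSolution(phi=np.ones(4), E=np.ones((4, 3)), J=np.ones((4, 3)), I_measured=1e-3)
        out = scale_solution(sol, 1e-3)
        assert out.s == pytest.approx(1.0)

    def test_degenerate_zero_current_rejected(self):
        sol = FieldSolution(phi=np.ones(1), E=np.ones((1, 3)), J=np.ones((1, 3)), I_measured=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            scale_solution(sol, 1e-3)

    def test_solved_slab_conserves_current_between_end_patches(self, uniform_slab):
        cond = uniform_conductivity(uniform_slab, 2.0)
        system, phi = solve(uniform_slab, cond)
        E = gradient_lsq(system, phi)
        J = current_density(E, cond)
        I_in = integrate_current(uniform_slab, J, "zmin")
        I_out = integrate_current(uniform_slab, J, "zmax")
        assert abs(abs(I_in) - abs(I_out)) / abs(I_in) < 1e-6
        # analytic: J = sigma * dV/L = 2 * 10/8e-3 V/m over 9 mm^2
        assert abs(I_in) == pytest.approx(2 * (10 / 8e-3) * 9e-6, rel=1e-8)
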