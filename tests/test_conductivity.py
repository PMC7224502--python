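import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tesfv.conductivity import (
    AIR_SIGMA,
    ConductivityField,
    DiffusionTensorField,
    TissueTable,
    isotropic_field,
    read_tensor_field,
    spd_repair,
    tensors_to_cells,
    volume_constraint_tensor,
    write_tensor_field,
)
from tesfv.phantoms import slab_mesh

SIGMA_WM = 0.126


class TestIsotropicField:
    def test_table_values_fill_diagonal(self, uniform_slab):
        field = isotropic_field(uniform_slab, TissueTable({1: 0.33}))
        np.testing.assert_allclose(field.tensors, np.broadcast_to(0.33 * np.eye(3), field.tensors.shape))
        assert not field.anisotropic.any()

    def test_air_sentinel_remains_spd(self, uniform_slab):
        field = isotropic_field(uniform_slab, TissueTable({1: AIR_SIGMA}))
        assert np.linalg.eigvalsh(field.tensors).min() == pytest.approx(AIR_SIGMA)
        field.validate()

    def test_missing_label_reported(self, uniform_slab):
        with pytest.raises(KeyError, match=r"\[1\]"):
            isotropic_field(uniform_slab, TissueTable({2: 1.0}))


class TestVolumeConstraint:
    def test_axis_aligned_example(self):
        out = volume_constraint_tensor(np.diag([3.0, 1.0, 1.0]), SIGMA_WM, ratio=10)
        # solving sigma_wm^2 = s_main*s_aux with s_aux = s_main/10:
        # s_main = 0.126*sqrt(10), s_aux = 0.126/sqrt(10)
        np.testing.assert_allclose(
            np.diag(out), [0.39844697, 0.03984470, 0.03984470], atol=1e-7
        )
        np.testing.assert_allclose(out, np.diag(np.diag(out)), atol=1e-12)

    def test_eigenvalue_product_is_sigma_squared(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3))
        D = A @ A.T + 0.1 * np.eye(3)
        w = np.linalg.eigvalsh(volume_constraint_tensor(D, SIGMA_WM))
        assert w[-1] * w[0] == pytest.approx(SIGMA_WM**2, abs=1e-14)

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        D = np.diag([5.0, 2.0, 1.0])
        R = Rotation.from_euler("zyx", [30, 45, 60], degrees=True).as_matrix()
        out_rot = volume_constraint_tensor(R @ D @ R.T, SIGMA_WM)
        rot_out = R @ volume_constraint_tensor(D, SIGMA_WM) @ R.T
        np.testing.assert_allclose(out_rot, rot_out, atol=1e-10)

    def test_isotropic_input_gets_exact_eigenvalues(self):
        out = volume_constraint_tensor(np.eye(3), SIGMA_WM)
        w = np.sort(np.linalg.eigvalsh(out))
        s_main = SIGMA_WM * np.sqrt(10)
        s_aux = SIGMA_WM / np.sqrt(10)
        np.testing.assert_allclose(w, [s_aux, s_aux, s_main], atol=1e-14)

    def test_asymmetric_input_rejected(self):
        D = np.diag([3.0, 1.0, 1.0])
        D[0, 1] = 1e-3
        with pytest.raises(ValueError, match="not symmetric"):
            volume_constraint_tensor(D, SIGMA_WM)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_tensors_are_spd_with_fixed_anisotropy(self, seed):
        """Every output tensor: SPD, max/min eigenvalue ratio = the requested
        anisotropy ratio, geometric mean pinned to sigma_wm."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        D = 0.5 * (A + A.T)
        out = volume_constraint_tensor(D, SIGMA_WM, ratio=10)
        w = np.linalg.eigvalsh(out)
        assert w[0] > 0
        assert w[-1] / w[0] == pytest.approx(10.0, abs=1e-9)
        assert np.sqrt(w[-1] * w[0]) == pytest.approx(SIGMA_WM, abs=1e-12)
        np.testing.assert_allclose(out, out.T, atol=1e-15)


class TestSpdRepair:
    def test_nan_tensor_becomes_isotropic_fallback(self):
        out = spd_repair(np.full((3, 3), np.nan), fallback_sigma=SIGMA_WM)
        np.testing.assert_allclose(out, SIGMA_WM * np.eye(3))

    def test_spd_tensor_unchanged(self):
        D = np.diag([2.0, 1.0, 0.5])
        np.testing.assert_allclose(spd_repair(D), D, atol=1e-14)

    def test_negative_eigenvalues_clamped(self):
        D = np.diag([1.0, 0.0, -0.1])
        w = np.linalg.eigvalsh(spd_repair(D))
        assert w.min() >= 1e-12
        assert w.max() == pytest.approx(1.0)


class TestTensorTransfer:
    def make_uniform_field(self, n=10, spacing=2.0):
        T = np.tile(np.diag([3.0, 1.0, 1.0]), (n, n, n, 1, 1))
        origin = -spacing * (n - 1) / 2 * np.ones(3)
        return DiffusionTensorField(T, np.full(3, spacing), origin)

    def test_uniform_field_overwrites_only_wm(self):
        mesh = slab_mesh((4, 4, 6), label_of_k=lambda k: np.where(k < 3, 1, 3))
        iso = isotropic_field(mesh, TissueTable({1: 0.465, 3: SIGMA_WM}))
        field = DiffusionTensorField(
            np.tile(np.diag([3.0, 1.0, 1.0]), (8, 8, 8, 1, 1)), [1.0] * 3, [-1.0, -1.0, -1.0]
        )
        out, n_fb = tensors_to_cells(field, mesh, iso, wm_label=3, sigma_wm=SIGMA_WM)
        wm = mesh.cell_labels == 3
        expect = np.diag([SIGMA_WM * np.sqrt(10), SIGMA_WM / np.sqrt(10), SIGMA_WM / np.sqrt(10)])
        np.testing.assert_allclose(out.tensors[wm], np.broadcast_to(expect, out.tensors[wm].shape), atol=1e-12)
        np.testing.assert_allclose(out.tensors[~wm], np.broadcast_to(0.465 * np.eye(3), out.tensors[~wm].shape), atol=1e-15)
        assert out.anisotropic.sum() == wm.sum()
        assert n_fb == 0

    def test_out_of_grid_centroids_fall_back(self):
        mesh = slab_mesh((2, 2, 2))
        iso = isotropic_field(mesh, TissueTable({1: SIGMA_WM}))
        tiny = DiffusionTensorField(
            np.tile(np.eye(3), (2, 2, 2, 1, 1)), [0.1] * 3, [100.0, 100.0, 100.0]
        )
        out, n_fb = tensors_to_cells(tiny, mesh, iso, wm_label=1, sigma_wm=SIGMA_WM)
        assert n_fb == mesh.n_cells
        np.testing.assert_allclose(out.tensors, iso.tensors)

    def test_swirl_field_principal_axis_follows_azimuth(self):
        """Synthetic swirl: principal diffusion axis azimuthal around z; the
        mapped conductivity tensors must keep that axis to < 1 degree."""
        n, spacing = 16, 2.0
        origin = np.array([-2.0, -2.0, -2.0])  # grid covers the slab below
        idx = np.indices((n, n, n)).transpose(1, 2, 3, 0)
        xyz = origin + idx * spacing
        phi_dir = np.stack([-xyz[..., 1], xyz[..., 0], np.zeros_like(xyz[..., 0])], axis=-1)
        rho = np.linalg.norm(phi_dir, axis=-1, keepdims=True)
        phi_dir = phi_dir / np.where(rho > 0, rho, 1.0)
        T = np.eye(3) + 2.0 * phi_dir[..., :, None] * phi_dir[..., None, :]
        field = DiffusionTensorField(T, np.full(3, spacing), origin)

        mesh = slab_mesh((8, 8, 4), spacing=3.0, label_of_k=lambda k: np.full_like(k, 3))
        iso = isotropic_field(mesh, TissueTable({3: SIGMA_WM}))
        out, _ = tensors_to_cells(field, mesh, iso, wm_label=3, sigma_wm=SIGMA_WM)

        centroids = mesh.cell_centroids()
        # compare in the voxel the centroid actually sampled (piecewise-constant field)
        vox = np.rint((centroids - origin) / spacing).astype(int)
        ok = np.linalg.norm(centroids[:, :2], axis=1) > 4.0
        for cell in np.flatnonzero(ok)[::7]:
            w, V = np.linalg.eigh(out.tensors[cell])
            principal = V[:, np.argmax(w)]
            i, j, k = vox[cell]
            expect = phi_dir[i, j, k]
            cosang = abs(principal @ expect)
            assert np.degrees(np.arccos(min(cosang, 1.0))) < 1.0


class TestTensorIO:
    def test_nifti_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4, 4, 3, 3))
        T = 0.5 * (A + np.swapaxes(A, 3, 4))
        field = DiffusionTensorField(T, [1.0, 2.0, 3.0], [0.5, -1.0, 2.0])
        write_tensor_field(field, tmp_path / "t.nii")
        back = read_tensor_field(tmp_path / "t.nii")
        np.testing.assert_allclose(back.tensors, T, rtol=1e-12)
        np.testing.assert_allclose(back.spacing, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(back.origin, [0.5, -1.0, 2.0])
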