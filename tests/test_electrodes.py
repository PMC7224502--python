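import numpy as np
import pytest
import trimesh

from tesfv.electrodes import (
    ElectrodeSpec,
    FiducialSet,
    clip_patch,
    extrude_electrode,
    locate_1020,
    tag_electrode_on_mesh,
)
from tesfv.phantoms import generate_layered_sphere_mesh, three_layer_head_model
from tesfv.surface import TriSurface


def sphere_surface(radius=1.0, subdivisions=5):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces))


def plane_surface(extent=15.0, n=21):
    xs = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(xs, xs)
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
    return TriSurface(verts, np.array(tris))


CANONICAL_FID = FiducialSet(
    nasion=[0, 1, 0], inion=[0, -1, 0], tragus_left=[-1, 0, 0], tragus_right=[1, 0, 0]
)


def great_circle_point(colat_fraction, toward):
    a = colat_fraction * np.pi
    return np.array(toward, float) * np.sin(a) + np.array([0.0, 0.0, 1.0]) * np.cos(a)


@pytest.fixture(scope="module")
def positions():
    return locate_1020(sphere_surface(), CANONICAL_FID)


class TestTenTwenty:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Cz", [0.0, 0.0, 1.0]),
            ("C3", great_circle_point(0.2, [-1, 0, 0])),
            ("C4", great_circle_point(0.2, [1, 0, 0])),
            ("Oz", great_circle_point(0.4, [0, -1, 0])),
            ("Fpz", great_circle_point(0.4, [0, 1, 0])),
            ("Fz", great_circle_point(0.2, [0, 1, 0])),
            ("T3", great_circle_point(0.4, [-1, 0, 0])),
        ],
    )
    def test_unit_sphere_matches_great_circle_fractions(self, positions, name, expected):
        assert np.linalg.norm(positions[name] - expected) < 1e-3

    def test_left_right_mirror_symmetry(self, positions):
        for left, right in [("C3", "C4"), ("T3", "T4"), ("F7", "F8"), ("O1", "O2")]:
            mirrored = positions[left] * np.array([-1.0, 1.0, 1.0])
            assert np.linalg.norm(mirrored - positions[right]) < 1e-3

    def test_all_positions_lie_on_the_scalp(self, positions):
        # chordal offset of the faceted sphere is ~3e-4 at this subdivision;
        # the positions must sit on the triangulated surface itself
        surf = sphere_surface()
        from tesfv.electrodes import _closest_on_triangles

        for p in positions.values():
            q, _ = _closest_on_triangles(surf, p)
            assert np.linalg.norm(q - p) < 1e-6

    def test_open_scalp_rejected(self):
        surf = sphere_surface(subdivisions=3)
        broken = TriSurface(surf.vertices, surf.triangles[:-3])
        with pytest.raises(ValueError, match="closed"):
            locate_1020(broken, CANONICAL_FID)

    def test_parallel_fiducial_chords_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            FiducialSet([0, 1, 0], [0, -1, 0], [0, 0.5, 0], [0, -0.5, 0])


class TestClipPatch:
    def test_square_footprint_on_plane_exact(self):
        spec = ElectrodeSpec("e", "rect", (10.0, 10.0))
        patch = clip_patch(plane_surface(), spec, np.zeros(3))
        assert patch.area() == pytest.approx(100.0, abs=1e-6)

    def test_circle_footprint_chord_error(self):
        spec = ElectrodeSpec("e", "circle", (5.0,))
        patch = clip_patch(plane_surface(), spec, np.zeros(3), n_segments=64)
        assert patch.area() == pytest.approx(np.pi * 25, rel=0.005)

    def test_curved_scalp_patch_at_least_footprint_area(self):
        spec = ElectrodeSpec("e", "circle", (5.0,))
        patch = clip_patch(sphere_surface(radius=50.0, subdivisions=4), spec, np.array([0.0, 0.0, 50.0]))
        assert patch.area() >= np.pi * 25

    def test_missing_surface_rejected(self):
        spec = ElectrodeSpec("e", "circle", (5.0,))
        with pytest.raises(ValueError, match="not intersect"):
            clip_patch(plane_surface(extent=3.0), spec, np.array([100.0, 100.0, 0.0]))


@pytest.fixture(scope="module")
def flat_patch():
    spec = ElectrodeSpec("e", "rect", (10.0, 10.0))
    return clip_patch(plane_surface(), spec, np.zeros(3))


class TestExtrusion:
    def test_two_mm_gives_two_layers(self, flat_patch):
        solid, _ = extrude_electrode(flat_patch, 2.0)
        n_layers = len(solid.vertices) // len(flat_patch.vertices) - 1
        assert n_layers == 2

    def test_prism_volume_exact(self, flat_patch):
        solid, _ = extrude_electrode(flat_patch, 3.0)
        assert abs(solid.enclosed_volume()) == pytest.approx(300.0, abs=1e-6)

    def test_fractional_thickness_step_rule(self, flat_patch):
        solid, _ = extrude_electrode(flat_patch, 2.5)
        n_layers = len(solid.vertices) // len(flat_patch.vertices) - 1
        assert n_layers == 3
        assert abs(solid.enclosed_volume()) == pytest.approx(250.0, abs=1e-6)

    def test_result_watertight_with_tagged_outer_face(self, flat_patch):
        solid, outer = extrude_electrode(flat_patch, 2.0)
        assert solid.cleaned().is_watertight()
        # outer face set is the final offset copy of the patch
        assert len(outer) == len(flat_patch.triangles)
        assert np.allclose(solid.vertices[solid.triangles[outer]][..., 2], 2.0)

    def test_boundary_vertex_count_preserved(self, flat_patch):
        solid, _ = extrude_electrode(flat_patch, 2.0)
        n = len(flat_patch.vertices)
        base = solid.vertices[:n]
        np.testing.assert_allclose(base, flat_patch.vertices)


@pytest.fixture(scope="module")
def tagged():
    mesh = generate_layered_sphere_mesh(
        three_layer_head_model(numerical_outer=True),
        subdivisions=3, radial_layers=(2, 2, 6),
    )
    anode = ElectrodeSpec("anode", "circle", (10.0,), thickness=2.6)
    cathode = ElectrodeSpec("cathode", "circle", (10.0,), thickness=2.6)
    mesh = tag_electrode_on_mesh(mesh, anode, np.array([0.0, 0.0, 90.0]), 10)
    mesh = tag_electrode_on_mesh(mesh, cathode, np.array([0.0, 0.0, -90.0]), 11)
    return mesh


class TestTagOnMesh:
    def test_outer_patch_faces_point_polewards(self, tagged):
        tris = tagged.patches["anode_outer"]
        p = tagged.points
        n = np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
        assert (n[:, 2] > 0).all()

    def test_contact_separates_electrode_from_tissue(self, tagged):
        geo = tagged.geometry
        idx = geo.internal_face_indices("anode_contact")
        lo = tagged.cell_labels[geo.int_owner[idx]]
        ln = tagged.cell_labels[geo.int_neighbour[idx]]
        assert (((lo == 10) & (ln != 10)) | ((ln == 10) & (lo != 10))).all()

    def test_antipodal_electrodes_are_disjoint(self, tagged):
        a = set(map(tuple, np.sort(tagged.patches["anode_contact"], axis=1)))
        c = set(map(tuple, np.sort(tagged.patches["cathode_contact"], axis=1)))
        assert not (a & c)

    def test_contact_area_close_to_outer_area(self, tagged):
        def area(tris):
            p = tagged.points
            return 0.5 * np.linalg.norm(
                np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]]), axis=1
            ).sum()

        a_out = area(tagged.patches["anode_outer"])
        tris = tagged.patches["anode_contact"]
        p = tagged.points
        n = np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        floor = np.abs(n[:, 2]) > 0.5  # contact floor; side walls excluded
        a_floor = area(tris[floor])
        # thin stamped electrode: the contact floor mirrors the outer footprint
        assert a_floor == pytest.approx(a_out, rel=0.10)

    def test_footprint_missing_boundary_rejected(self, tagged):
        spec = ElectrodeSpec("x", "circle", (5.0,), thickness=2.0)
        with pytest.raises(ValueError, match="covers no boundary faces"):
            tag_electrode_on_mesh(tagged, spec, np.array([500.0, 0.0, 0.0]), 12)
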