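import numpy as np
import pytest
import trimesh

from hemocloud.geometry import (
    ar_high_risk,
    assemble_geometric_parameters,
    assign_regions,
    compute_ar,
    compute_neck_width,
    compute_sac_height,
    compute_sac_volume,
    compute_sr,
    compute_surface_area,
    compute_volume,
    neck_section_points,
)
from hemocloud.synthetic import make_sac_mesh
from hemocloud.types import NeckPlane, SurfaceMesh, ValidationError


def near_sphere(r=5.0, rings=48, segments=48):
    """Sac mesh that is a sphere except for a tiny neck opening."""
    return make_sac_mesh(r, r, r, 0.02 * r, 3.5, rings=rings, segments=segments)


class TestSacHeight:
    def test_hemisphere_height_is_radius(self):
        mesh, _ = near_sphere(5.0)
        equator = NeckPlane(origin=[0.0, 0.0, 0.0], normal=[0.0, 0.0, 1.0])
        relabeled = assign_regions(mesh, equator)
        assert compute_sac_height(relabeled, equator) == pytest.approx(5.0, abs=1e-9)

    def test_translation_invariance(self):
        mesh, plane = make_sac_mesh(3, 2.5, 4, 1.2, 3.5)
        h0 = compute_sac_height(mesh, plane)
        shift = np.array([10.0, -4.0, 2.5])
        moved = SurfaceMesh(mesh.vertices + shift, mesh.faces, mesh.face_regions)
        moved_plane = NeckPlane(plane.origin + shift, plane.normal)
        assert compute_sac_height(moved, moved_plane) == pytest.approx(h0, rel=1e-12)

    def test_matches_vertex_loop_oracle(self, rng):
        mesh, plane = make_sac_mesh(3.2, 2.7, 4.5, 1.4, 3.5)
        # independent brute force: explicit python loop over sac vertices
        sac_idx = np.unique(mesh.region_faces("sac"))
        best = max(
            float(np.dot(mesh.vertices[i] - plane.origin, plane.normal))
            for i in sac_idx
        )
        assert compute_sac_height(mesh, plane) == pytest.approx(best, rel=1e-15)


class TestNeckWidth:
    def test_circular_neck_diameter(self):
        mesh, plane = make_sac_mesh(3.0, 3.0, 3.0, 2.0, 3.5, rings=48, segments=64)
        assert compute_neck_width(mesh, plane) == pytest.approx(4.0, rel=0.01)

    def test_elliptical_neck_major_axis(self):
        # ellipsoid a=3, b=1 cut at the equator has section semi-axes (3, 1)
        mesh, _ = make_sac_mesh(3.0, 1.0, 2.0, 0.05, 3.5, rings=64, segments=64)
        equator = NeckPlane(origin=[0.0, 0.0, 0.0], normal=[0.0, 0.0, 1.0])
        relabeled = assign_regions(mesh, equator)
        assert compute_neck_width(relabeled, equator) == pytest.approx(6.0, rel=0.01)

    def test_matches_pairwise_loop_oracle(self):
        mesh, plane = make_sac_mesh(2.8, 2.2, 3.6, 1.1, 3.5, rings=16, segments=18)
        pts = neck_section_points(mesh, plane)
        best = 0.0
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                best = max(best, float(np.linalg.norm(pts[i] - pts[j])))
        assert compute_neck_width(mesh, plane) == pytest.approx(best, rel=1e-15)

    def test_no_intersection_error(self):
        mesh, plane = make_sac_mesh(3, 3, 3, 1.5, 3.5)
        far = NeckPlane(origin=plane.origin + [0, 0, 100.0], normal=plane.normal)
        with pytest.raises(ValidationError):
            compute_neck_width(mesh, far)


class TestRatios:
    def test_ar_examples(self):
        assert compute_ar(8.0, 4.0) == 2.0
        assert compute_ar(3.7, 3.7) == 1.0
        assert compute_sr(8.0, 4.0) == 2.0

    def test_zero_denominator(self):
        with pytest.raises(ValidationError):
            compute_ar(1.0, 0.0)
        with pytest.raises(ValidationError):
            compute_sr(1.0, 0.0)

    def test_high_risk_helper_threshold(self):
        # the conventional high-risk regime starts above AR = 1.6
        assert ar_high_risk(1.7)
        assert not ar_high_risk(1.5)


class TestAreaVolume:
    def test_single_triangle_area(self):
        mesh = SurfaceMesh(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            np.array([[0, 1, 2]]),
            np.array(["sac"]),
        )
        assert compute_surface_area(mesh) == pytest.approx(0.5, abs=1e-15)

    def test_icosphere_area_and_volume(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        mesh = SurfaceMesh(
            np.asarray(ico.vertices), np.asarray(ico.faces),
            np.full(len(ico.faces), "sac"),
        )
        assert compute_surface_area(mesh) == pytest.approx(4 * np.pi, rel=0.01)
        assert compute_volume(mesh.vertices, mesh.faces) == pytest.approx(
            4 * np.pi / 3, rel=0.01
        )

    def test_area_face_order_invariant(self, rng):
        mesh, _ = make_sac_mesh(3, 2.5, 4, 1.2, 3.5)
        base = compute_surface_area(mesh)
        order = rng.permutation(mesh.n_faces)
        shuffled = SurfaceMesh(mesh.vertices, mesh.faces[order], mesh.face_regions[order])
        assert compute_surface_area(shuffled) == pytest.approx(base, rel=1e-12)

    def test_unit_cube_volume(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert compute_volume(np.asarray(box.vertices), np.asarray(box.faces)) == pytest.approx(1.0, abs=1e-12)

    def test_volume_vertex_relabel_invariant(self, rng):
        box = trimesh.creation.box(extents=(1.0, 2.0, 3.0))
        v, f = np.asarray(box.vertices), np.asarray(box.faces)
        perm = rng.permutation(len(v))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(v))
        assert compute_volume(v[perm], inv[f]) == pytest.approx(6.0, abs=1e-12)

    def test_open_mesh_rejected(self):
        mesh = SurfaceMesh(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            np.array([[0, 1, 2]]),
            np.array(["sac"]),
        )
        with pytest.raises(ValidationError):
            compute_volume(mesh.vertices, mesh.faces)


class TestAssembled:
    def test_sphere_sv_ratio(self):
        mesh, plane = near_sphere(4.0)
        rec = assemble_geometric_parameters(mesh, plane, parent_diameter=3.5)
        assert rec.sv_ratio == pytest.approx(3.0 / 4.0, rel=0.02)

    def test_invariants_by_construction(self):
        mesh, plane = make_sac_mesh(3, 2.5, 4.2, 1.3, 3.6)
        rec = assemble_geometric_parameters(mesh, plane, 3.6, daughter_sac=1)
        assert rec.aspect_ratio == pytest.approx(rec.sac_height / rec.neck_width, rel=1e-14)
        assert rec.sv_ratio == pytest.approx(rec.surface_area / rec.volume, rel=1e-14)

    def test_rigid_motion_invariance(self, rng):
        mesh, plane = make_sac_mesh(3.1, 2.6, 4.0, 1.2, 3.5)
        base = assemble_geometric_parameters(mesh, plane, 3.5)
        # random rotation + translation applied to mesh and plane alike
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(size=3) * 10
        moved = SurfaceMesh(mesh.vertices @ q.T + shift, mesh.faces, mesh.face_regions)
        moved_plane = NeckPlane(plane.origin @ q.T + shift, plane.normal @ q.T)
        rec = assemble_geometric_parameters(moved, moved_plane, 3.5)
        for name in ("sac_height", "neck_width", "surface_area", "volume",
                     "aspect_ratio", "size_ratio", "sv_ratio"):
            assert getattr(rec, name) == pytest.approx(getattr(base, name), rel=1e-9)

    def test_uniform_scaling_laws(self):
        mesh, plane = make_sac_mesh(3, 2.5, 4, 1.2, 3.5)
        base = assemble_geometric_parameters(mesh, plane, 3.5)
        mesh2, plane2 = make_sac_mesh(6, 5, 8, 2.4, 7.0)
        scaled = assemble_geometric_parameters(mesh2, plane2, 7.0)
        assert scaled.sac_height == pytest.approx(2 * base.sac_height, rel=1e-9)
        assert scaled.surface_area == pytest.approx(4 * base.surface_area, rel=1e-9)
        assert scaled.volume == pytest.approx(8 * base.volume, rel=1e-9)
        assert scaled.aspect_ratio == pytest.approx(base.aspect_ratio, rel=1e-9)
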