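"""Morphometry of the aneurysm sac relative to an annotated neck plane.

All operations take a :class:`~hemocloud.types.SurfaceMesh` plus a
:class:`~hemocloud.types.NeckPlane` whose normal points toward the dome.

Definitions (standard in the aneurysm-morphometry literature):

* sac height  — maximum distance from the neck plane to any sac vertex;
* neck width  — maximal diameter of the neck cross-section;
* AR (aspect ratio)  = sac height / neck width;
* SR (size ratio)    = sac height / parent vessel diameter;
* S/V = sac lateral surface area / sac volume (sac closed at the neck plane).

An AR above about 1.6 and an SR above about 1.5 are widely reported high-risk
regimes; :func:`ar_high_risk` exposes the AR threshold as a helper but no
operation applies it automatically.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    REGION_NECK_CAP,
    REGION_PARENT,
    REGION_SAC,
    GeometricParameters,
    NeckPlane,
    SurfaceMesh,
    ValidationError,
)

#: aspect-ratio value above which rupture risk is conventionally flagged
AR_HIGH_RISK_THRESHOLD = 1.6


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    return 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )


def assign_regions(
    mesh: SurfaceMesh, neck_plane: NeckPlane, tol: float = 1e-6
) -> SurfaceMesh:
    """Label faces by the side of the neck plane their centroid falls on.

    Dome side -> ``sac``; on the plane (within ``tol``, relative to the mesh
    scale, matching STL single precision) -> ``neck_cap``; otherwise ->
    ``parent_vessel``.
    """
    scale = max(1.0, float(np.abs(mesh.vertices - neck_plane.origin).max()))
    tol = tol * scale
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    d = neck_plane.signed_distance(centroids)
    regions = np.where(d > tol, REGION_SAC, np.where(d < -tol, REGION_PARENT, REGION_NECK_CAP))
    return SurfaceMesh(mesh.vertices, mesh.faces, regions.astype("U16"))


def compute_sac_height(mesh: SurfaceMesh, neck_plane: NeckPlane) -> float:
    """Maximum signed distance of sac vertices from the neck plane (mm)."""
    faces = mesh.region_faces(REGION_SAC)
    if faces.size == 0:
        raise ValidationError("mesh has no sac faces")
    idx = np.unique(faces)
    d = neck_plane.signed_distance(mesh.vertices[idx])
    height = float(d.max())
    if height <= 0:
        raise ValidationError("no sac vertex lies on the dome side of the neck plane")
    return height


def neck_section_points(
    mesh: SurfaceMesh, neck_plane: NeckPlane, tol: float = 1e-6
) -> np.ndarray:
    """Points where sac-region edges meet the neck plane.

    Vertices lying on the plane (within ``tol`` of the sac bounding scale) are
    collected directly; edges that straddle the plane contribute the linear
    interpolation of their endpoints.
    """
    faces = mesh.region_faces(REGION_SAC, REGION_NECK_CAP)
    if faces.size == 0:
        raise ValidationError("mesh has no sac faces")
    idx = np.unique(faces)
    verts = mesh.vertices[idx]
    scale = max(1.0, float(np.abs(verts - neck_plane.origin).max()))
    d = neck_plane.signed_distance(mesh.vertices)
    on_plane = idx[np.abs(d[idx]) <= tol * scale]
    pts = [mesh.vertices[on_plane]] if on_plane.size else []

    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    da, db = d[edges[:, 0]], d[edges[:, 1]]
    crossing = (da * db) < -(tol * scale) ** 2
    if crossing.any():
        a = mesh.vertices[edges[crossing, 0]]
        b = mesh.vertices[edges[crossing, 1]]
        t = (da[crossing] / (da[crossing] - db[crossing]))[:, None]
        pts.append(a + t * (b - a))
    if not pts:
        raise ValidationError("no sac edge meets the neck plane")
    return np.concatenate(pts)


def compute_neck_width(mesh: SurfaceMesh, neck_plane: NeckPlane, tol: float = 1e-6) -> float:
    """Maximal pairwise distance among neck-section points (mm)."""
    pts = neck_section_points(mesh, neck_plane, tol=tol)
    if len(pts) < 2:
        raise ValidationError("neck section has fewer than 2 points")
    # O(k^2) pairwise maximum; neck sections are small (ring of mesh edges)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def compute_ar(sac_height: float, neck_width: float) -> float:
    """Aspect ratio = sac height / neck width."""
    if neck_width <= 0:
        raise ValidationError("neck width must be > 0")
    return sac_height / neck_width


def compute_sr(sac_height: float, parent_diameter: float) -> float:
    """Size ratio = sac height / parent vessel diameter."""
    if parent_diameter <= 0:
        raise ValidationError("parent vessel diameter must be > 0")
    return sac_height / parent_diameter


def ar_high_risk(ar: float, threshold: float = AR_HIGH_RISK_THRESHOLD) -> bool:
    """Whether the aspect ratio falls in the conventional high-risk regime."""
    return ar > threshold


def compute_surface_area(mesh: SurfaceMesh, region: str = REGION_SAC) -> float:
    """Sum of triangle areas over a region (mm^2)."""
    faces = mesh.region_faces(region)
    if faces.size == 0:
        raise ValidationError(f"mesh has no {region!r} faces")
    return float(triangle_areas(mesh.vertices, faces).sum())


def _edge_orientation_consistent(faces: np.ndarray) -> bool:
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    # consistent closed orientation: every directed edge appears exactly once
    _, counts = np.unique(directed, axis=0, return_counts=True)
    return bool((counts == 1).all())


def is_closed(vertices: np.ndarray, faces: np.ndarray) -> bool:
    """Every undirected edge shared by exactly two faces."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


def compute_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a closed triangle mesh via the divergence theorem (mm^3).

    Sums signed tetrahedron volumes det(v0, v1, v2)/6 and returns the absolute
    value; warns if the face winding is inconsistent.
    """
    faces = np.asarray(faces, dtype=np.int64)
    if not is_closed(vertices, faces):
        raise ValidationError("volume requires a closed mesh")
    if not _edge_orientation_consistent(faces):
        warnings.warn("inconsistent face winding; |volume| may be underestimated")
    tri = np.asarray(vertices, dtype=float)[faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def close_sac(mesh: SurfaceMesh, neck_plane: NeckPlane) -> tuple[np.ndarray, np.ndarray]:
    """Vertices/faces of the sac closed at the neck plane.

    If the mesh already carries ``neck_cap`` faces they are used; otherwise the
    neck section boundary is fan-triangulated about its centroid.
    """
    cap = mesh.region_faces(REGION_NECK_CAP)
    sac = mesh.region_faces(REGION_SAC)
    if sac.size == 0:
        raise ValidationError("mesh has no sac faces")
    if cap.size:
        faces = np.concatenate([sac, cap])
        if is_closed(mesh.vertices, faces):
            return mesh.vertices, faces
    # fan-cap the open boundary of the sac region
    edges = np.concatenate([sac[:, [0, 1]], sac[:, [1, 2]], sac[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if boundary.size == 0:
        return mesh.vertices, sac
    centroid = mesh.vertices[np.unique(boundary)].mean(axis=0)
    vertices = np.vstack([mesh.vertices, centroid])
    c = len(vertices) - 1
    # orient cap triangles opposite to the boundary's directed edges in sac
    directed = {tuple(e) for e in np.concatenate(
        [sac[:, [0, 1]], sac[:, [1, 2]], sac[:, [2, 0]]]).tolist()}
    cap_faces = []
    for a, b in boundary:
        if (a, b) in directed:
            cap_faces.append((b, a, c))
        else:
            cap_faces.append((a, b, c))
    faces = np.vstack([sac, np.asarray(cap_faces, dtype=np.int64)])
    return vertices, faces


def compute_sac_volume(mesh: SurfaceMesh, neck_plane: NeckPlane) -> float:
    """Volume of the sac closed at the neck plane (mm^3)."""
    vertices, faces = close_sac(mesh, neck_plane)
    return compute_volume(vertices, faces)


def assemble_geometric_parameters(
    mesh: SurfaceMesh,
    neck_plane: NeckPlane,
    parent_diameter: float,
    daughter_sac: int = 0,
    location_bifurcation: int = 0,
) -> GeometricParameters:
    """Compute the full morphometry record; invariants hold by construction."""
    height = compute_sac_height(mesh, neck_plane)
    neck = compute_neck_width(mesh, neck_plane)
    area = compute_surface_area(mesh, REGION_SAC)
    volume = compute_sac_volume(mesh, neck_plane)
    return GeometricParameters(
        sac_height=height,
        neck_width=neck,
        parent_vessel_diameter=parent_diameter,
        aspect_ratio=compute_ar(height, neck),
        size_ratio=compute_sr(height, parent_diameter),
        surface_area=area,
        volume=volume,
        sv_ratio=area / volume,
        daughter_sac=int(daughter_sac),
        location_bifurcation=int(location_bifurcation),
    ).validate()
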