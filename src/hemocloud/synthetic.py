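"""Synthetic aneurysm cohorts with label-linked morphology and wall fields.

The generator replaces the clinical DSA/CFD stages: each case is a truncated
ellipsoidal sac capped at an explicit neck plane and joined to an open
parent-vessel tube, a 3000-point area-uniform surface cloud carrying smooth
spatially correlated wall fields, and the tabular parameters recomputed from
that geometry/cloud via :mod:`hemocloud.geometry` and
:mod:`hemocloud.hemodynamics`.

Rupture (label 1) shifts the case distribution the way the clinical risk
literature describes: sacs become more elongated (higher aspect ratio), mean
log-WSS drops, the low-WSS patch grows, OSI concentrates, and the qualitative
streamline flags become more likely.  All effect sizes live in
:class:`EffectConfig`; :meth:`EffectConfig.null` zeroes every label-linked
difference, giving a cohort with no signal.

Spatial correlation is produced by radial-basis-function mixing of a few
random surface centres rather than a flow solve: smoothness is controllable
and generation is desk-scale.  The per-point "velocity" attribute is a
nonnegative near-wall speed proxy generated as an independent smooth field.

The whole cohort is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import assemble_geometric_parameters
from .hemodynamics import assemble_hemodynamic_parameters
from .io import get_logger, write_cloud_csv, write_mesh_stl, write_parameter_table
from .types import (
    REGION_NECK_CAP,
    REGION_PARENT,
    REGION_SAC,
    HemodynamicCloud,
    NeckPlane,
    SurfaceMesh,
    SyntheticCase,
    ValidationError,
)

logger = get_logger()


@dataclass(frozen=True)
class EffectConfig:
    """Cohort sizes, label-conditional distributions and effect sizes.

    Lengths in mm, WSS in Pa, pressure in Pa, velocity in m/s.  ``*_shift``
    fields are added for ruptured cases only.
    """

    n_unruptured: int = 109
    n_ruptured: int = 40

    # sac geometry: lognormal radii; c is the dome (height) axis
    sac_radius_log_mean: float = 1.05   # exp(1.05) ~ 2.86 mm equatorial radius
    sac_radius_log_sd: float = 0.12
    elongation_log_mean: float = 0.0    # log of c/a elongation factor
    elongation_log_sd: float = 0.15
    elongation_shift: float = 0.35      # ruptured sacs are more slender (higher AR)
    neck_frac_mean: float = 0.62        # neck radius as fraction of min(a, b)
    neck_frac_sd: float = 0.06
    neck_frac_shift: float = -0.06      # ruptured necks slightly narrower
    parent_diameter_mean: float = 3.5
    parent_diameter_sd: float = 0.35

    # wall fields
    log_wss_mean: float = 1.4           # exp(1.4) ~ 4 Pa
    log_wss_sd: float = 0.35            # smooth-field amplitude on log-WSS
    log_wss_shift: float = -0.6         # ruptured: lower mean WSS
    low_wss_patch_frac: float = 0.08    # area fraction of the depressed-WSS patch
    low_wss_patch_shift: float = 0.20   # ruptured: larger patch
    low_wss_patch_amplitude: float = 1.8
    osi_logit_mean: float = -2.5        # 0.5*sigmoid(-2.5) ~ 0.04
    osi_logit_sd: float = 1.0
    osi_shift: float = 1.2              # ruptured: OSI concentrates upward
    pressure_baseline: float = 13000.0
    pressure_gradient: float = 40.0     # Pa per mm along a random direction
    pressure_noise_sd: float = 120.0
    velocity_log_mean: float = -1.6     # exp(-1.6) ~ 0.2 m/s proxy
    velocity_log_sd: float = 0.3
    velocity_shift: float = 0.0

    # qualitative flag probabilities P(flag = 1 | label)
    p_flow_pattern_changed: tuple[float, float] = (0.25, 0.70)
    p_flow_complex: tuple[float, float] = (0.30, 0.72)
    p_inflow_jet_concentrated: tuple[float, float] = (0.28, 0.68)
    p_daughter_sac: tuple[float, float] = (0.20, 0.55)
    p_bifurcation: tuple[float, float] = (0.40, 0.55)

    # discretisation
    n_cloud_points: int = 3000
    mesh_rings: int = 24
    mesh_segments: int = 32
    n_field_centers: int = 12
    seed: int = 0

    def validate(self) -> "EffectConfig":
        if self.n_unruptured < 0 or self.n_ruptured < 0:
            raise ValidationError("cohort counts must be >= 0")
        for name in ("sac_radius_log_sd", "elongation_log_sd", "neck_frac_sd",
                     "parent_diameter_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("p_flow_pattern_changed", "p_flow_complex",
                     "p_inflow_jet_concentrated", "p_daughter_sac", "p_bifurcation"):
            for p in getattr(self, name):
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(f"{name} probabilities must lie in [0, 1]")
        if self.mesh_rings < 3 or self.mesh_segments < 3:
            raise ValidationError("mesh resolution must be >= 3 subdivisions")
        return self

    @classmethod
    def null(cls, **overrides) -> "EffectConfig":
        """A configuration with every label-linked effect removed (no signal)."""
        base = cls(
            elongation_shift=0.0,
            neck_frac_shift=0.0,
            log_wss_shift=0.0,
            low_wss_patch_shift=0.0,
            osi_shift=0.0,
            velocity_shift=0.0,
            p_flow_pattern_changed=(0.4, 0.4),
            p_flow_complex=(0.4, 0.4),
            p_inflow_jet_concentrated=(0.4, 0.4),
            p_daughter_sac=(0.3, 0.3),
            p_bifurcation=(0.45, 0.45),
        )
        return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# geometry


def make_sac_mesh(
    a: float,
    b: float,
    c: float,
    neck_radius: float,
    parent_diameter: float,
    rings: int = 24,
    segments: int = 32,
) -> tuple[SurfaceMesh, NeckPlane]:
    """Truncated-ellipsoid sac capped at the neck plane, joined to an open tube.

    The sac is the ellipsoid (a, b, c) truncated below the equator where the
    cross-section radius shrinks back to ``neck_radius`` (relative to the
    smaller equatorial semi-axis); the dome points along +z and the neck plane
    normal is +z.  The parent vessel is an open cylinder tangent to the neck
    plane, labelled separately; it shares no vertices with the sac.
    """
    if min(a, b, c) <= 0 or neck_radius <= 0 or parent_diameter <= 0:
        raise ValidationError("all radii must be > 0")
    if rings < 3 or segments < 3:
        raise ValidationError("resolution must be >= 3 subdivisions")
    s = neck_radius / min(a, b)
    if s >= 1.0:
        raise ValidationError("neck radius must be smaller than min(a, b) semi-axis")
    theta_max = np.pi - np.arcsin(s)  # neck sits below the equator
    z_neck = c * np.cos(theta_max)

    # lateral surface: apex + rings of vertices
    thetas = theta_max * np.arange(1, rings + 1) / rings
    phis = 2 * np.pi * np.arange(segments) / segments
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    ring_verts = np.column_stack(
        [
            (a * np.sin(tt) * np.cos(pp)).ravel(),
            (b * np.sin(tt) * np.sin(pp)).ravel(),
            (c * np.cos(tt)).ravel(),
        ]
    )
    apex = np.array([[0.0, 0.0, c]])
    vertices = np.vstack([apex, ring_verts])

    faces: list[tuple[int, int, int]] = []
    # apex fan (outward winding: counter-clockwise seen from outside/above)
    for j in range(segments):
        faces.append((0, 1 + j, 1 + (j + 1) % segments))
    # quad strips between rings
    for i in range(rings - 1):
        r0 = 1 + i * segments
        r1 = 1 + (i + 1) * segments
        for j in range(segments):
            jn = (j + 1) % segments
            faces.append((r0 + j, r1 + j, r1 + jn))
            faces.append((r0 + j, r1 + jn, r0 + jn))
    n_sac_faces = len(faces)

    # neck cap: fan about the section centroid, wound to close the sac outward
    center_idx = len(vertices)
    vertices = np.vstack([vertices, [[0.0, 0.0, z_neck]]])
    last = 1 + (rings - 1) * segments
    for j in range(segments):
        jn = (j + 1) % segments
        faces.append((last + jn, last + j, center_idx))
    n_cap_faces = len(faces) - n_sac_faces

    # open parent-vessel tube along x, tangent to the neck plane from below
    radius = parent_diameter / 2.0
    tube_z = z_neck - radius
    half_len = 2.0 * parent_diameter
    n_axial = max(4, segments // 4)
    xs = np.linspace(-half_len, half_len, n_axial)
    angs = 2 * np.pi * np.arange(segments) / segments
    tube_start = len(vertices)
    tube = np.array(
        [
            [x, radius * np.cos(t), tube_z + radius * np.sin(t)]
            for x in xs
            for t in angs
        ]
    )
    vertices = np.vstack([vertices, tube])
    for i in range(n_axial - 1):
        r0 = tube_start + i * segments
        r1 = tube_start + (i + 1) * segments
        for j in range(segments):
            jn = (j + 1) % segments
            faces.append((r0 + j, r1 + j, r1 + jn))
            faces.append((r0 + j, r1 + jn, r0 + jn))

    regions = np.array(
        [REGION_SAC] * n_sac_faces
        + [REGION_NECK_CAP] * n_cap_faces
        + [REGION_PARENT] * (len(faces) - n_sac_faces - n_cap_faces),
        dtype="U16",
    )
    mesh = SurfaceMesh(np.asarray(vertices), np.asarray(faces, dtype=np.int64), regions)
    plane = NeckPlane(origin=np.array([0.0, 0.0, z_neck]), normal=np.array([0.0, 0.0, 1.0]))
    return mesh.validate(), plane


def sample_surface_points(
    mesh: SurfaceMesh, n: int, rng: np.random.Generator,
    return_face_indices: bool = False,
):
    """Area-uniform sample of ``n`` points on the sac lateral surface.

    Faces are chosen proportionally to their area, then a uniform barycentric
    point is drawn in each.  Per-point weight = total sac area / n (mm^2).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    faces = mesh.region_faces(REGION_SAC)
    if faces.size == 0:
        raise ValidationError("mesh has no sac faces")
    tri = mesh.vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    total = areas.sum()
    chosen = rng.choice(len(faces), size=n, p=areas / total)
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1.0
    u[flip], v[flip] = 1.0 - u[flip], 1.0 - v[flip]
    t = tri[chosen]
    pts = t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])
    weights = np.full(n, total / n)
    if return_face_indices:
        return pts, weights, chosen
    return pts, weights


# ---------------------------------------------------------------------------
# wall fields


def _smooth_field(
    points: np.ndarray, rng: np.random.Generator, n_centers: int
) -> np.ndarray:
    """Standardised smooth field from RBF mixing of random surface centres."""
    centers = points[rng.choice(len(points), size=min(n_centers, len(points)), replace=False)]
    scale = np.sqrt(((points - points.mean(0)) ** 2).sum(1).mean())
    ell = max(0.8 * scale, 1e-6)
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    w = rng.normal(size=len(centers))
    f = np.exp(-d2 / (2 * ell**2)) @ w
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(len(points))


def synth_wall_fields(
    points: np.ndarray,
    label: int,
    config: EffectConfig,
    rng: np.random.Generator,
    areas: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Smooth, spatially correlated wall fields with label-linked shifts.

    log-WSS is a Gaussian smooth field shifted down for ruptured cases, with a
    multiplicative low-WSS patch whose footprint grows with the label; OSI is
    0.5 * logistic(field) clipped to [0, 0.5]; pressure is baseline + linear
    trend + smooth noise; velocity is a nonnegative lognormal speed proxy.
    """
    config.validate()
    n = len(points)
    shift = int(label)

    log_wss = config.log_wss_mean + shift * config.log_wss_shift
    log_wss = log_wss + config.log_wss_sd * _smooth_field(points, rng, config.n_field_centers)
    patch_frac = config.low_wss_patch_frac + shift * config.low_wss_patch_shift
    if patch_frac > 0 and config.low_wss_patch_amplitude > 0:
        center = points[rng.integers(n)]
        if areas is not None:
            total_area = float(np.sum(areas))
        else:
            total_area = 4 * np.pi * ((points - points.mean(0)) ** 2).sum(1).mean()
        patch_radius = np.sqrt(max(patch_frac, 1e-9) * total_area / np.pi)
        d2 = ((points - center) ** 2).sum(1)
        log_wss = log_wss - config.low_wss_patch_amplitude * np.exp(-d2 / (2 * patch_radius**2))
    wss = np.exp(log_wss)

    osi_field = config.osi_logit_mean + shift * config.osi_shift
    osi_field = osi_field + config.osi_logit_sd * _smooth_field(points, rng, config.n_field_centers)
    osi = np.clip(0.5 / (1.0 + np.exp(-osi_field)), 0.0, 0.5)

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pressure = (
        config.pressure_baseline
        + config.pressure_gradient * (points @ direction)
        + config.pressure_noise_sd * _smooth_field(points, rng, config.n_field_centers)
    )

    log_v = (
        config.velocity_log_mean
        + shift * config.velocity_shift
        + config.velocity_log_sd * _smooth_field(points, rng, config.n_field_centers)
    )
    velocity = np.exp(log_v)

    return {"wss": wss, "osi": osi, "pressure": pressure, "velocity": velocity}


# ---------------------------------------------------------------------------
# cases and cohorts


def _draw_geometry(config: EffectConfig, label: int, rng: np.random.Generator):
    shift = int(label)
    a = float(np.exp(rng.normal(config.sac_radius_log_mean, config.sac_radius_log_sd)))
    b = float(np.exp(rng.normal(config.sac_radius_log_mean, config.sac_radius_log_sd)))
    elong = float(
        np.exp(
            rng.normal(
                config.elongation_log_mean + shift * config.elongation_shift,
                config.elongation_log_sd,
            )
        )
    )
    c = 0.5 * (a + b) * elong
    frac = float(
        np.clip(
            rng.normal(config.neck_frac_mean + shift * config.neck_frac_shift,
                       config.neck_frac_sd),
            0.2,
            0.9,
        )
    )
    neck_radius = frac * min(a, b)
    parent = float(
        max(1.0, rng.normal(config.parent_diameter_mean, config.parent_diameter_sd))
    )
    return a, b, c, neck_radius, parent


def generate_case(
    config: EffectConfig,
    label: int,
    case_id: str,
    rng: np.random.Generator,
) -> SyntheticCase:
    """One fully assembled case: mesh, 3000-point cloud and tabular parameters."""
    config.validate()
    a, b, c, neck_radius, parent = _draw_geometry(config, label, rng)
    mesh, plane = make_sac_mesh(
        a, b, c, neck_radius, parent,
        rings=config.mesh_rings, segments=config.mesh_segments,
    )
    pts, weights = sample_surface_points(mesh, config.n_cloud_points, rng)
    fields = synth_wall_fields(pts, label, config, rng, areas=weights)
    cloud = HemodynamicCloud.from_arrays(
        case_id, pts, fields["wss"], fields["osi"], fields["pressure"],
        fields["velocity"], area_weight=weights,
    )
    shift = int(label)
    flags = {
        "flow_pattern_changed": int(rng.random() < config.p_flow_pattern_changed[shift]),
        "flow_complex": int(rng.random() < config.p_flow_complex[shift]),
        "inflow_jet_concentrated": int(
            rng.random() < config.p_inflow_jet_concentrated[shift]
        ),
    }
    geo = assemble_geometric_parameters(
        mesh,
        plane,
        parent_diameter=parent,
        daughter_sac=int(rng.random() < config.p_daughter_sac[shift]),
        location_bifurcation=int(rng.random() < config.p_bifurcation[shift]),
    )
    hemo = assemble_hemodynamic_parameters(cloud, flags, weights=weights)
    return SyntheticCase(
        case_id=case_id, label=int(label), mesh=mesh, neck_plane=plane,
        cloud=cloud, geometric=geo, hemodynamic=hemo,
    )


def generate_cohort(config: EffectConfig) -> list[SyntheticCase]:
    """The full labelled cohort, a pure function of the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cases = []
    labels = [0] * config.n_unruptured + [1] * config.n_ruptured
    for i, label in enumerate(labels):
        case_id = f"case_{i + 1:04d}"
        cases.append(generate_case(config, label, case_id, rng))
    logger.info(
        "generated cohort: %d unruptured + %d ruptured (seed %d)",
        config.n_unruptured, config.n_ruptured, config.seed,
    )
    return cases


def cohort_tables(cases: list[SyntheticCase]) -> pd.DataFrame:
    """One row per case: label + geometry block + hemodynamics block."""
    rows = []
    for case in cases:
        row = {"case_id": case.case_id, "label": case.label}
        row.update(case.geometric.to_dict())
        row.update(case.hemodynamic.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cases: list[SyntheticCase], outdir) -> pd.DataFrame:
    """Persist per-case STL + cloud CSV and the manifest/parameter table."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "meshes").mkdir(parents=True, exist_ok=True)
    (outdir / "clouds").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for case in cases:
        mesh_path = outdir / "meshes" / f"{case.case_id}.stl"
        cloud_path = outdir / "clouds" / f"{case.case_id}.csv"
        write_mesh_stl(case.mesh, mesh_path)
        write_cloud_csv(case.cloud, cloud_path)
        manifest_rows.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                "mesh_path": str(mesh_path.relative_to(outdir)),
                "cloud_path": str(cloud_path.relative_to(outdir)),
                "neck_origin_x": case.neck_plane.origin[0],
                "neck_origin_y": case.neck_plane.origin[1],
                "neck_origin_z": case.neck_plane.origin[2],
                "neck_normal_x": case.neck_plane.normal[0],
                "neck_normal_y": case.neck_plane.normal[1],
                "neck_normal_z": case.neck_plane.normal[2],
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    write_parameter_table(cohort_tables(cases), outdir / "parameters.csv")
    return manifest
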