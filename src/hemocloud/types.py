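"""Core domain containers for aneurysm surface data and per-case parameters.

A *hemodynamic cloud* is a surface point cloud in which every point carries
its 3D coordinates plus four wall-field scalars (wall shear stress, oscillatory
shear index, pressure and a near-wall velocity proxy).  Meshes are plain
triangle soups with per-face region labels; the neck plane is an explicit
annotation separating the aneurysm sac from its parent vessel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order for cloud tables (coordinates in mm, wss/pressure in
#: Pa, velocity in m/s, osi dimensionless in [0, 0.5])
CLOUD_COLUMNS = ("x", "y", "z", "wss", "osi", "pressure", "velocity")

#: recognised per-face region labels
REGION_SAC = "sac"
REGION_NECK_CAP = "neck_cap"
REGION_PARENT = "parent_vessel"
REGIONS = (REGION_SAC, REGION_NECK_CAP, REGION_PARENT)


class ValidationError(ValueError):
    """Raised when an on-disk artifact or in-memory container violates its contract."""


@dataclass
class HemodynamicCloud:
    """N surface points x 7 attributes, optionally with per-point area weights (mm^2)."""

    case_id: str
    data: pd.DataFrame  # columns CLOUD_COLUMNS (+ optional "area_weight")

    @property
    def n_points(self) -> int:
        return len(self.data)

    @property
    def matrix(self) -> np.ndarray:
        """(N, 7) float array in canonical column order."""
        return self.data.loc[:, list(CLOUD_COLUMNS)].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray | None:
        if "area_weight" in self.data.columns:
            return self.data["area_weight"].to_numpy(dtype=float)
        return None

    def validate(self) -> "HemodynamicCloud":
        missing = [c for c in CLOUD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"cloud {self.case_id!r}: missing columns {missing}")
        if self.n_points < 1:
            raise ValidationError(f"cloud {self.case_id!r}: empty cloud")
        mat = self.data.loc[:, list(CLOUD_COLUMNS)]
        for col in CLOUD_COLUMNS:
            vals = pd.to_numeric(mat[col], errors="coerce").to_numpy()
            bad = np.flatnonzero(~np.isfinite(vals))
            if bad.size:
                raise ValidationError(
                    f"cloud {self.case_id!r}: non-finite or non-numeric value "
                    f"in column {col!r} at row {int(bad[0])}"
                )
        osi = mat["osi"].to_numpy(dtype=float)
        bad = np.flatnonzero((osi < 0.0) | (osi > 0.5))
        if bad.size:
            raise ValidationError(
                f"cloud {self.case_id!r}: osi outside [0, 0.5] at row {int(bad[0])} "
                f"(value {osi[bad[0]]:g})"
            )
        for col in ("wss", "velocity"):
            vals = mat[col].to_numpy(dtype=float)
            bad = np.flatnonzero(vals < 0.0)
            if bad.size:
                raise ValidationError(
                    f"cloud {self.case_id!r}: negative {col} at row {int(bad[0])}"
                )
        return self

    @classmethod
    def from_arrays(
        cls,
        case_id: str,
        xyz: np.ndarray,
        wss: np.ndarray,
        osi: np.ndarray,
        pressure: np.ndarray,
        velocity: np.ndarray,
        area_weight: np.ndarray | None = None,
    ) -> "HemodynamicCloud":
        df = pd.DataFrame(
            {
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
                "wss": wss,
                "osi": osi,
                "pressure": pressure,
                "velocity": velocity,
            }
        )
        if area_weight is not None:
            df["area_weight"] = area_weight
        return cls(case_id=case_id, data=df).validate()


@dataclass
class SurfaceMesh:
    """Triangle mesh (mm) with per-face region labels."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    face_regions: np.ndarray  # (F,) str, values in REGIONS

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.face_regions = np.asarray(self.face_regions, dtype="U16")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def region_faces(self, *regions: str) -> np.ndarray:
        """Face rows belonging to any of the given regions."""
        mask = np.isin(self.face_regions, list(regions))
        return self.faces[mask]

    def validate(self) -> "SurfaceMesh":
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValidationError("face index out of range")
        if len(self.face_regions) != self.n_faces:
            raise ValidationError("face_regions length mismatch")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        bad = np.flatnonzero(areas <= 0.0)
        if bad.size:
            raise ValidationError(f"zero-area facets at indices {bad.tolist()[:10]}")
        return self


@dataclass
class NeckPlane:
    """Plane separating sac from parent vessel; normal points toward the dome."""

    origin: np.ndarray  # (3,) mm
    normal: np.ndarray  # (3,) unit vector

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if abs(nrm - 1.0) > 1e-9:
            if nrm == 0:
                raise ValidationError("neck plane normal has zero norm")
            self.normal = self.normal / nrm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive on the dome (sac) side."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.normal


@dataclass
class GeometricParameters:
    """Morphometric features of one aneurysm (the tabular Group-A geometry block)."""

    sac_height: float  # mm
    neck_width: float  # mm
    parent_vessel_diameter: float  # mm
    aspect_ratio: float  # height / neck width
    size_ratio: float  # height / parent vessel diameter
    surface_area: float  # mm^2, sac lateral surface
    volume: float  # mm^3, sac closed at the neck plane
    sv_ratio: float  # surface_area / volume, 1/mm
    daughter_sac: int  # {0, 1}
    location_bifurcation: int  # 0 sidewall, 1 bifurcation

    FIELDS = (
        "sac_height",
        "neck_width",
        "parent_vessel_diameter",
        "aspect_ratio",
        "size_ratio",
        "surface_area",
        "volume",
        "sv_ratio",
        "daughter_sac",
        "location_bifurcation",
    )

    def validate(self) -> "GeometricParameters":
        for name in (
            "sac_height",
            "neck_width",
            "parent_vessel_diameter",
            "surface_area",
            "volume",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if abs(self.aspect_ratio - self.sac_height / self.neck_width) > 1e-12 * max(
            1.0, self.aspect_ratio
        ):
            raise ValidationError("aspect_ratio inconsistent with height/neck width")
        if abs(self.sv_ratio - self.surface_area / self.volume) > 1e-12 * max(
            1.0, self.sv_ratio
        ):
            raise ValidationError("sv_ratio inconsistent with area/volume")
        for name in ("daughter_sac", "location_bifurcation"):
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"{name} must be 0 or 1")
        return self

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


#: the four streamline-judgment indicators, stored as 0/1 annotations
QUALITATIVE_FLAGS = (
    "flow_pattern_changed",
    "flow_complex",
    "inflow_jet_concentrated",
    "impingement_concentrated",
)

_HEMO_ATTRS = ("wss", "osi", "pressure", "velocity")
_HEMO_STATS = ("max", "mean", "min")


@dataclass
class HemodynamicParameters:
    """Summary statistics and area fractions of the wall fields (Group-A hemo block)."""

    stats: dict = field(default_factory=dict)  # {"wss_max": ..., ...}
    lsa: float = 0.0  # low-shear area fraction
    hoa: float = 0.0  # high-OSI area fraction
    impingement_fraction: float = 0.0
    flags: dict = field(default_factory=dict)  # QUALITATIVE_FLAGS -> {0,1}

    FIELDS = tuple(
        f"{a}_{s}" for a in _HEMO_ATTRS for s in _HEMO_STATS
    ) + ("lsa", "hoa", "impingement_fraction") + QUALITATIVE_FLAGS

    def validate(self) -> "HemodynamicParameters":
        for attr in _HEMO_ATTRS:
            lo, mid, hi = (self.stats[f"{attr}_{s}"] for s in ("min", "mean", "max"))
            if not (lo <= mid + 1e-12 and mid <= hi + 1e-12):
                raise ValidationError(f"{attr}: min <= mean <= max violated")
        for name in ("lsa", "hoa", "impingement_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} outside [0, 1]")
        for flag in QUALITATIVE_FLAGS:
            if self.flags.get(flag) not in (0, 1):
                raise ValidationError(f"flag {flag} must be 0 or 1")
        return self

    def to_dict(self) -> dict:
        out = dict(self.stats)
        out.update(
            lsa=self.lsa, hoa=self.hoa, impingement_fraction=self.impingement_fraction
        )
        out.update({f: self.flags[f] for f in QUALITATIVE_FLAGS})
        return out


@dataclass
class SyntheticCase:
    """One generated aneurysm: geometry, wall fields and the derived tabular features."""

    case_id: str
    label: int  # 0 unruptured, 1 ruptured
    mesh: SurfaceMesh
    neck_plane: NeckPlane
    cloud: HemodynamicCloud
    geometric: GeometricParameters
    hemodynamic: HemodynamicParameters


def as_dataclass_dict(obj) -> dict:
    return dataclasses.asdict(obj)
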