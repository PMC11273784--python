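"""Readers and writers for every on-disk artifact.

Conventions: CSV is comma-separated, '.' decimal, UTF-8, header mandatory;
STL coordinates are millimetres (STL carries no unit metadata, so this is a
documented convention); clouds are stored one case per file as
``<case_id>.csv``.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .types import (
    CLOUD_COLUMNS,
    QUALITATIVE_FLAGS,
    GeometricParameters,
    HemodynamicCloud,
    HemodynamicParameters,
    NeckPlane,
    SurfaceMesh,
    ValidationError,
)

logger = logging.getLogger("hemocloud")


def get_logger() -> logging.Logger:
    return logger


# ---------------------------------------------------------------------------
# hemodynamic cloud CSV


def read_cloud_csv(path: str | Path, case_id: str | None = None) -> HemodynamicCloud:
    """Read one cloud file; row order is preserved and every row validated."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CLOUD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    cols = list(CLOUD_COLUMNS) + (["area_weight"] if "area_weight" in df.columns else [])
    cloud = HemodynamicCloud(
        case_id=case_id or path.stem, data=df.loc[:, cols].reset_index(drop=True)
    )
    return cloud.validate()


def write_cloud_csv(cloud: HemodynamicCloud, path: str | Path) -> Path:
    """Write in canonical column order at full float precision (repr round-trip)."""
    cloud.validate()
    path = Path(path)
    cols = list(CLOUD_COLUMNS) + (
        ["area_weight"] if "area_weight" in cloud.data.columns else []
    )
    cloud.data.loc[:, cols].to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# STL meshes


def _merge_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (snap-to-grid); drop degenerate faces."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first]
    remapped = inverse[faces]
    keep = (
        (remapped[:, 0] != remapped[:, 1])
        & (remapped[:, 1] != remapped[:, 2])
        & (remapped[:, 0] != remapped[:, 2])
    )
    return merged, remapped[keep]


def read_mesh_stl(
    path: str | Path,
    neck_plane: NeckPlane | None = None,
    merge_tol: float = 1e-6,
) -> SurfaceMesh:
    """Read a binary or ASCII STL.

    Duplicate vertices within ``merge_tol`` mm are merged into shared indices and
    face winding is preserved.  STL stores no region labels; when a neck plane is
    given the regions are re-derived from it (see :func:`hemocloud.geometry.assign_regions`),
    otherwise every face is labelled ``sac``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = trimesh.load(str(path), file_type="stl", process=False)
    vertices, faces = _merge_vertices(
        np.asarray(raw.vertices, dtype=float),
        np.asarray(raw.faces, dtype=np.int64),
        tol=merge_tol,
    )
    tri = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    zero = np.flatnonzero(areas <= 0.0)
    if zero.size:
        raise ValidationError(f"{path.name}: zero-area facets at indices {zero.tolist()[:10]}")
    regions = np.full(len(faces), "sac", dtype="U16")
    mesh = SurfaceMesh(vertices, faces, regions)
    if neck_plane is not None:
        from .geometry import assign_regions

        mesh = assign_regions(mesh, neck_plane)
    return mesh.validate()


def write_mesh_stl(mesh: SurfaceMesh, path: str | Path, ascii_format: bool = False) -> Path:
    """Export to STL (binary by default); face winding is preserved."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = trimesh.exchange.stl.export_stl_ascii(tm) if ascii_format else trimesh.exchange.stl.export_stl(tm)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# parameter tables

_GEO_COLS = list(GeometricParameters.FIELDS)
_HEMO_COLS = list(HemodynamicParameters.FIELDS)
_FLAG_COLS = ["daughter_sac", "location_bifurcation", *QUALITATIVE_FLAGS]


def write_parameter_table(df: pd.DataFrame, path: str | Path) -> Path:
    """One row per case_id: geometry block, hemo block, rupture label."""
    if df["case_id"].duplicated().any():
        dup = df.loc[df["case_id"].duplicated(), "case_id"].iloc[0]
        raise ValidationError(f"duplicate case_id {dup!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "case_id" not in df.columns:
        raise ValidationError("parameter table lacks case_id column")
    if df["case_id"].duplicated().any():
        dup = df.loc[df["case_id"].duplicated(), "case_id"].iloc[0]
        raise ValidationError(f"duplicate case_id {dup!r}")
    for col in _FLAG_COLS + (["label"] if "label" in df.columns else []):
        if col in df.columns:
            vals = df[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                bad = vals[~np.isin(vals, (0, 1))][0]
                raise ValidationError(f"flag column {col!r} has non-binary value {bad!r}")
            df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# run configuration (YAML, nested keys)


def read_config_file(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return cfg


def write_config_file(cfg: dict, path: str | Path) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return Path(path)


def config_hash(cfg: dict) -> str:
    """Stable short hash used to tag every log line and output directory."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
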