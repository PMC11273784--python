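"""End-to-end orchestration: simulate -> parameters -> features -> classify.

Every stage reads its inputs from disk and writes its outputs back, so stages
can be rerun in isolation; all randomness derives from the single seed in
:class:`RunConfig` via a named seed sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ALGORITHMS, GROUP_DIMS, run_experiment_grid
from .geometry import assemble_geometric_parameters
from .hemodynamics import (
    DEFAULT_CONCENTRATION_CUTOFF,
    DEFAULT_HOA_THRESHOLD,
    DEFAULT_IMPINGEMENT_CUT,
    DEFAULT_LSA_REL_THRESHOLD,
    assemble_hemodynamic_parameters,
)
from .io import (
    config_hash,
    get_logger,
    read_cloud_csv,
    read_config_file,
    read_mesh_stl,
    read_parameter_table,
    write_config_file,
    write_parameter_table,
)
from .pointnet import ExtractorConfig
from .synthetic import EffectConfig, generate_cohort, write_cohort
from .types import NeckPlane, ValidationError

logger = get_logger()


@dataclass
class RunConfig:
    """One-file configuration of a full run."""

    seed: int = 0
    n_unruptured: int = 109
    n_ruptured: int = 40
    channels: tuple[int, int, int, int] = (8, 8, 16, 16)
    epochs: int = 20
    algorithms: tuple[str, ...] = ALGORITHMS
    groups: tuple[str, ...] = ("A", "B4")
    folds: int = 10
    lsa_rel_threshold: float = DEFAULT_LSA_REL_THRESHOLD
    hoa_threshold: float = DEFAULT_HOA_THRESHOLD
    impingement_cut: float = DEFAULT_IMPINGEMENT_CUT
    concentration_cutoff: float = DEFAULT_CONCENTRATION_CUTOFF
    outdir: str = "runs/default"
    effect: dict = field(default_factory=dict)  # overrides for EffectConfig

    def validate(self) -> "RunConfig":
        for name in ("lsa_rel_threshold", "hoa_threshold", "impingement_cut",
                     "concentration_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        for g in self.groups:
            if g not in GROUP_DIMS:
                raise ValidationError(f"unknown group {g!r}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(d["channels"])
        d["algorithms"] = list(d["algorithms"])
        d["groups"] = list(d["groups"])
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = read_config_file(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channels", "algorithms", "groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def effect_config(self) -> EffectConfig:
        base = EffectConfig(
            n_unruptured=self.n_unruptured, n_ruptured=self.n_ruptured, seed=self.seed
        )
        return dataclasses.replace(base, **self.effect) if self.effect else base

    def extractor_config(self, group_dim: int | None = None) -> ExtractorConfig:
        channels = self.channels
        if group_dim is not None:
            from .pointnet import CHANNEL_PRESETS

            channels = CHANNEL_PRESETS[group_dim]
        return ExtractorConfig(channels=channels, epochs=self.epochs, seed=self.seed)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> Path:
    """Generate and persist the synthetic cohort; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    write_config_file(cfg_dict, outdir / "config.yaml")
    logger.info("simulate: seed %d config %s", config.seed, config_hash(cfg_dict))
    cases = generate_cohort(config.effect_config())
    write_cohort(cases, outdir)
    return outdir


def _load_manifest(outdir: Path) -> pd.DataFrame:
    manifest = pd.read_csv(outdir / "manifest.csv")
    for _, row in manifest.iterrows():
        for col in ("mesh_path", "cloud_path"):
            if not (outdir / row[col]).exists():
                raise ValidationError(f"manifest references missing file {row[col]}")
    return manifest


def _neck_plane(row: pd.Series) -> NeckPlane:
    return NeckPlane(
        origin=np.array([row.neck_origin_x, row.neck_origin_y, row.neck_origin_z]),
        normal=np.array([row.neck_normal_x, row.neck_normal_y, row.neck_normal_z]),
    )


def stage_parameters(config: RunConfig) -> pd.DataFrame:
    """Recompute the geometry + hemodynamics table from the on-disk cohort."""
    outdir = Path(config.outdir)
    manifest = _load_manifest(outdir)
    params = read_parameter_table(outdir / "parameters.csv")
    rows = []
    for _, row in manifest.iterrows():
        plane = _neck_plane(row)
        mesh = read_mesh_stl(outdir / row.mesh_path, neck_plane=plane)
        cloud = read_cloud_csv(outdir / row.cloud_path, case_id=row.case_id)
        stored = params.set_index("case_id").loc[row.case_id]
        geo = assemble_geometric_parameters(
            mesh, plane,
            parent_diameter=float(stored["parent_vessel_diameter"]),
            daughter_sac=int(stored["daughter_sac"]),
            location_bifurcation=int(stored["location_bifurcation"]),
        )
        hemo = assemble_hemodynamic_parameters(
            cloud,
            {k: int(stored[k]) for k in
             ("flow_pattern_changed", "flow_complex", "inflow_jet_concentrated")},
            weights=cloud.weights,
            lsa_rel_threshold=config.lsa_rel_threshold,
            hoa_threshold=config.hoa_threshold,
            impingement_cut=config.impingement_cut,
            concentration_cutoff=config.concentration_cutoff,
        )
        out = {"case_id": row.case_id, "label": int(row.label)}
        out.update(geo.to_dict())
        out.update(hemo.to_dict())
        rows.append(out)
    table = pd.DataFrame(rows)
    write_parameter_table(table, outdir / "parameters.csv")
    return table


def stage_classify(config: RunConfig) -> pd.DataFrame:
    """Run the algorithms x groups benchmark on the persisted cohort."""
    outdir = Path(config.outdir)
    manifest = _load_manifest(outdir)
    tabular = read_parameter_table(outdir / "parameters.csv")
    clouds = [
        read_cloud_csv(outdir / row.cloud_path, case_id=row.case_id)
        for _, row in manifest.iterrows()
    ]
    report, rocs = run_experiment_grid(
        tabular, clouds, groups=config.groups, algorithms=config.algorithms,
        extractor_config=config.extractor_config(), folds=config.folds,
        seed=config.seed,
    )
    report.to_csv(outdir / "report.csv", index=False, float_format="%.4f")
    roc_dir = outdir / "roc"
    roc_dir.mkdir(exist_ok=True)
    for (algo, group), roc in rocs.items():
        pd.DataFrame(roc, columns=["fpr", "tpr"]).to_csv(
            roc_dir / f"{algo}_{group}.csv", index=False
        )
    return report


def full_run(config: RunConfig) -> pd.DataFrame:
    """simulate -> parameters -> classify, with every intermediate persisted."""
    stage_simulate(config)
    stage_parameters(config)
    return stage_classify(config)
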