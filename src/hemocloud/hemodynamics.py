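"""Wall-field statistics on hemodynamic clouds.

Area fractions (LSA, HOA, impingement) are computed with per-point area
weights when available, otherwise every point counts equally.  Thresholds are
deliberately configuration, not constants: the literature does not agree on a
single low-shear cutoff, so the defaults used by the pipeline are a relative
low-WSS cutoff (10 % of the cloud mean WSS) and an OSI cutoff of 0.01.

OSI is computed from a time-resolved wall-shear vector series with the
standard definition

    OSI = 0.5 * (1 - ||integral tau dt|| / integral ||tau|| dt)

using trapezoidal integration over one cycle; it is 0 for steady unidirectional
shear and 0.5 for perfect reversal.  Synthetic clouds carry OSI directly, so
this operation exists for users bringing their own time-resolved data.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    QUALITATIVE_FLAGS,
    HemodynamicCloud,
    HemodynamicParameters,
    ValidationError,
)

_ATTRS = ("wss", "osi", "pressure", "velocity")

#: default thresholds used by the pipeline (all configurable)
DEFAULT_LSA_REL_THRESHOLD = 0.1   # fraction of mean WSS
DEFAULT_HOA_THRESHOLD = 0.01      # OSI cutoff
DEFAULT_IMPINGEMENT_CUT = 0.8     # fraction of max WSS
DEFAULT_CONCENTRATION_CUTOFF = 0.5  # impingement fraction below which the zone counts as concentrated


def _weights(cloud: HemodynamicCloud, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        weights = cloud.weights
    if weights is None:
        return np.full(cloud.n_points, 1.0 / cloud.n_points)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (cloud.n_points,):
        raise ValidationError("weights length must match cloud size")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("weights must have positive total")
    return weights / total


def summarize_cloud(
    cloud: HemodynamicCloud, weights: np.ndarray | None = None
) -> dict[str, float]:
    """Per-attribute (max, mean, min); the mean is area-weighted when weights exist."""
    out: dict[str, float] = {}
    if weights is None and cloud.weights is None:
        w = None
    else:
        w = _weights(cloud, weights)
    for attr in _ATTRS:
        vals = cloud.data[attr].to_numpy(dtype=float)
        mean = float(vals.mean()) if w is None else float((w * vals).sum())
        out[f"{attr}_max"] = float(vals.max())
        out[f"{attr}_mean"] = mean
        out[f"{attr}_min"] = float(vals.min())
    return out


def compute_osi(tau: np.ndarray, times: np.ndarray) -> np.ndarray:
    """OSI per point from wall-shear vectors ``tau`` of shape (N, T, 3) over ``times``.

    Values are clipped to [0, 0.5] after a 1e-12 tolerance; an all-zero series
    is defined as OSI 0 with a warning.
    """
    tau = np.asarray(tau, dtype=float)
    times = np.asarray(times, dtype=float)
    if tau.ndim != 3 or tau.shape[2] != 3 or tau.shape[1] < 2:
        raise ValidationError("tau must have shape (N, T>=2, 3)")
    if not np.isfinite(tau).all():
        raise ValidationError("non-finite shear values")
    mean_vec = np.trapezoid(tau, times, axis=1)  # (N, 3)
    mag = np.trapezoid(np.linalg.norm(tau, axis=2), times, axis=1)  # (N,)
    osi = np.zeros(tau.shape[0])
    zero = mag <= 0.0
    if zero.any():
        warnings.warn("all-zero shear series; OSI defined as 0")
    nz = ~zero
    osi[nz] = 0.5 * (1.0 - np.linalg.norm(mean_vec[nz], axis=1) / mag[nz])
    osi[np.abs(osi) < 1e-12] = 0.0
    osi[np.abs(osi - 0.5) < 1e-12] = 0.5
    return np.clip(osi, 0.0, 0.5)


def compute_lsa(
    cloud: HemodynamicCloud,
    wss_threshold: float,
    weights: np.ndarray | None = None,
) -> float:
    """Low shear area: fraction of sac area with WSS strictly below the threshold."""
    if wss_threshold <= 0:
        raise ValidationError("wss_threshold must be > 0")
    w = _weights(cloud, weights)
    wss = cloud.data["wss"].to_numpy(dtype=float)
    return float(np.clip(w[wss < wss_threshold].sum(), 0.0, 1.0))


def compute_hoa(
    cloud: HemodynamicCloud,
    osi_threshold: float,
    weights: np.ndarray | None = None,
) -> float:
    """High-OSI area: fraction of sac area with OSI strictly above the threshold."""
    if not (0.0 < osi_threshold < 0.5):
        raise ValidationError("osi_threshold must lie in (0, 0.5)")
    w = _weights(cloud, weights)
    osi = cloud.data["osi"].to_numpy(dtype=float)
    return float(np.clip(w[osi > osi_threshold].sum(), 0.0, 1.0))


def impingement_zone(
    cloud: HemodynamicCloud,
    weights: np.ndarray | None = None,
    relative_cut: float = DEFAULT_IMPINGEMENT_CUT,
    concentration_cutoff: float = DEFAULT_CONCENTRATION_CUTOFF,
) -> tuple[float, int]:
    """Impingement-zone area fraction and its concentration flag.

    The zone is where WSS >= ``relative_cut`` x max(WSS) on the sac (inclusive,
    so a uniform field yields fraction 1).  The flag is 1 (concentrated) when
    the fraction is below ``concentration_cutoff``.
    """
    if not (0.0 < relative_cut <= 1.0):
        raise ValidationError("relative_cut must lie in (0, 1]")
    w = _weights(cloud, weights)
    wss = cloud.data["wss"].to_numpy(dtype=float)
    frac = float(np.clip(w[wss >= relative_cut * wss.max()].sum(), 0.0, 1.0))
    return frac, int(frac < concentration_cutoff)


def encode_qualitative_flags(annotations: dict) -> dict[str, int]:
    """Validate the four streamline-judgment indicators as strict {0, 1} codes."""
    flags: dict[str, int] = {}
    for name in QUALITATIVE_FLAGS:
        if name not in annotations:
            raise ValidationError(f"missing qualitative flag {name!r}")
        val = annotations[name]
        if val not in (0, 1, 0.0, 1.0) or isinstance(val, bool):
            raise ValidationError(f"flag {name!r} must be 0 or 1, got {val!r}")
        flags[name] = int(val)
    return flags


def assemble_hemodynamic_parameters(
    cloud: HemodynamicCloud,
    annotations: dict,
    weights: np.ndarray | None = None,
    lsa_threshold: float | None = None,
    lsa_rel_threshold: float = DEFAULT_LSA_REL_THRESHOLD,
    hoa_threshold: float = DEFAULT_HOA_THRESHOLD,
    impingement_cut: float = DEFAULT_IMPINGEMENT_CUT,
    concentration_cutoff: float = DEFAULT_CONCENTRATION_CUTOFF,
) -> HemodynamicParameters:
    """Full per-case hemodynamic record.

    ``lsa_threshold`` is absolute (Pa); when omitted it defaults to
    ``lsa_rel_threshold`` times the (weighted) mean WSS of the cloud.
    """
    stats = summarize_cloud(cloud, weights)
    if lsa_threshold is None:
        lsa_threshold = lsa_rel_threshold * stats["wss_mean"]
    frac, conc_flag = impingement_zone(
        cloud, weights, relative_cut=impingement_cut,
        concentration_cutoff=concentration_cutoff,
    )
    flags = encode_qualitative_flags(
        {**annotations, "impingement_concentrated": annotations.get(
            "impingement_concentrated", conc_flag)}
    )
    return HemodynamicParameters(
        stats=stats,
        lsa=compute_lsa(cloud, lsa_threshold, weights),
        hoa=compute_hoa(cloud, hoa_threshold, weights),
        impingement_fraction=frac,
        flags=flags,
    ).validate()
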