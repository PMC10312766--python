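"""Per-vesicle biophysical quantities: detected marker count and diameter.

Marker counting uses the blinking calibration: one bound fluorescent
tetraspanin antibody yields on average ``L`` localizations over an
acquisition (default 14), so a cluster of ``n_loc`` localizations carries an
estimated ``n_loc / L`` detected markers. The count is kept real-valued;
integers appear only in formatted reports.

Diameter estimation inverts the spherical-shell projection: antibodies sit
on the vesicle surface (radius R), and a uniform point on a sphere
orthographically projected to the plane has mean squared radial distance
``E[r²] = 2R²/3`` from the center. Gaussian localization noise of sd σ per
axis adds ``2σ²``, hence

    R̂² = 1.5 · max(0, m2 − 2σ²),   D̂ = 2·R̂,

where m2 is the mean squared distance of member localizations from the
cluster centroid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AssayConfig, ConfigurationError
from .voronoi import EvCluster

log = logging.getLogger(__name__)


@dataclass
class EvMeasurement:
    cluster_id: int
    roi_id: str
    n_loc: int
    markers: float  # detected tetraspanins = n_loc / L
    diameter_nm: float
    mean_r2: float  # nm², mean squared radial distance from centroid


class UndefinedMeasurementError(ValueError):
    pass


def marker_count(n_loc: int, L: float) -> float:
    """Detected markers for a cluster of ``n_loc`` localizations."""
    if L <= 0:
        raise ConfigurationError("L: must be > 0")
    if n_loc < 0:
        raise ValueError("n_loc must be >= 0")
    return n_loc / L


def estimate_diameter(positions: np.ndarray, sigma: float | np.ndarray) -> float:
    """Diameter (nm) from member localization positions.

    ``sigma`` is the localization precision, either a scalar or one value
    per localization (its squared mean enters the correction). Returns 0
    when the precision correction exceeds the observed spread.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or len(positions) < 2:
        raise UndefinedMeasurementError("diameter needs at least 2 localizations")
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be >= 0")
    centroid = positions.mean(axis=0)
    m2 = float(np.mean(np.sum((positions - centroid) ** 2, axis=1)))
    r2 = 1.5 * max(0.0, m2 - 2.0 * float(np.mean(sigma**2)))
    return 2.0 * np.sqrt(r2)


def _cluster_sigma(members: pd.DataFrame, cfg: AssayConfig) -> np.ndarray | float:
    """Precision source order: per-localization column → ROI median → default."""
    if "sigma" in members.columns and members["sigma"].notna().all():
        return members["sigma"].to_numpy(dtype=float)
    if "sigma" in members.columns and members["sigma"].notna().any():
        return float(members["sigma"].median())
    return cfg.sigma_default


def measure_clusters(
    locs: pd.DataFrame, clusters: list[EvCluster], cfg: AssayConfig
) -> list[EvMeasurement]:
    """Measure every detected cluster of one ROI.

    ``locs`` is the ROI localization table the clusters were detected in
    (columns ``id, x, y[, sigma]``).
    """
    indexed = locs.set_index("id")
    out = []
    for cl in clusters:
        members = indexed.loc[sorted(cl.member_loc_ids)]
        pos = members[["x", "y"]].to_numpy(dtype=float)
        centroid = pos.mean(axis=0)
        m2 = float(np.mean(np.sum((pos - centroid) ** 2, axis=1)))
        out.append(
            EvMeasurement(
                cluster_id=cl.cluster_id,
                roi_id=cl.roi_id,
                n_loc=cl.n_loc,
                markers=marker_count(cl.n_loc, cfg.L),
                diameter_nm=estimate_diameter(pos, _cluster_sigma(members, cfg)),
                mean_r2=m2,
            )
        )
    return out


def measurements_frame(measurements: list[EvMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": m.cluster_id,
                "roi_id": m.roi_id,
                "n_loc": m.n_loc,
                "markers": m.markers,
                "diameter_nm": m.diameter_nm,
            }
            for m in measurements
        ],
        columns=["cluster_id", "roi_id", "n_loc", "markers", "diameter_nm"],
    )


def summarize_ev_metrics(measurements: list[EvMeasurement]) -> dict[str, float]:
    """Cohort-level vesicle summaries: TSPAN/EV_Av, D_Av and their CVs.

    CV = sample sd / mean; undefined (NaN, with a warning) for a single
    vesicle.
    """
    if not measurements:
        raise UndefinedMeasurementError("cannot summarize an empty measurement list")
    markers = np.array([m.markers for m in measurements], dtype=float)
    diam = np.array([m.diameter_nm for m in measurements], dtype=float)

    def _cv(v: np.ndarray) -> float:
        if len(v) < 2:
            warnings.warn("CV undefined for a single vesicle", stacklevel=3)
            return float("nan")
        mean = v.mean()
        return float(v.std(ddof=1) / mean) if mean != 0 else float("nan")

    return {
        "tspan_ev_av": float(markers.mean()),
        "d_av": float(diam.mean()),
        "cv_markers": _cv(markers),
        "cv_diameter": _cv(diam),
        "n_ev": len(measurements),
    }
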