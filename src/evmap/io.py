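"""Readers and writers for localization tables and experiment manifests.

Localization tables are plain CSV in a ThunderSTORM-compatible dialect with
header ``id, frame, x [nm], y [nm], sigma [nm], intensity, channel``; on read
the common variants (``x_nm``, bare ``x``, arbitrary case) are accepted.
Coordinates are continuous nanometres with the origin at the ROI lower-left
corner and y increasing upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WRITE_HEADER = ["id", "frame", "x [nm]", "y [nm]", "sigma [nm]", "intensity", "channel"]
_CANONICAL = {
    "id": "id",
    "frame": "frame",
    "x [nm]": "x",
    "x_nm": "x",
    "x": "x",
    "y [nm]": "y",
    "y_nm": "y",
    "y": "y",
    "sigma [nm]": "sigma",
    "sigma_nm": "sigma",
    "sigma": "sigma",
    "uncertainty [nm]": "sigma",
    "intensity": "intensity",
    "intensity [photon]": "intensity",
    "channel": "channel",
}


class FormatError(ValueError):
    """Raised when a localization table is structurally unreadable."""


@dataclass
class RegionOfInterest:
    """One imaged field of a capture coverslip: the unit of replication."""

    roi_id: str
    width: float  # nm
    height: float  # nm
    locs: pd.DataFrame = field(default_factory=pd.DataFrame)
    coverslip_id: str = ""
    n_rejected: int = 0

    @property
    def n_loc(self) -> int:
        return len(self.locs)


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table with the canonical CSV header.

    Positions are formatted at 3 decimal places (sub-picometre, far below
    localization precision), which makes write→read a lossless round trip at
    that resolution.
    """
    out = df.copy()
    for col in ("sigma", "intensity", "channel"):
        if col not in out.columns:
            out[col] = np.nan
    out = out[["id", "frame", "x", "y", "sigma", "intensity", "channel"]]
    out.columns = WRITE_HEADER
    out.to_csv(path, index=False, float_format="%.3f")


def read_localization_table(
    path: str | Path, width: float, height: float, roi_id: str = "", coverslip_id: str = ""
) -> RegionOfInterest:
    """Read one per-ROI localization CSV, rejecting malformed rows.

    Rows with missing/non-finite coordinates or positions outside the ROI
    rectangle are dropped and counted in ``n_rejected`` (with a logged
    reason); accepted + rejected always equals the file's row count.
    """
    roi_id = roi_id or Path(path).stem
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        log.warning("%s: empty localization file", path)
        return RegionOfInterest(roi_id, width, height, _empty_table(), coverslip_id)
    if raw.empty and raw.columns.empty:
        log.warning("%s: empty localization file", path)
        return RegionOfInterest(roi_id, width, height, _empty_table(), coverslip_id)

    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in _CANONICAL:
            rename[col] = _CANONICAL[key]
    df = raw.rename(columns=rename)
    for mandatory in ("x", "y"):
        if mandatory not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {mandatory!r}")

    n_total = len(df)
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    bad_coord = ~(np.isfinite(df["x"]) & np.isfinite(df["y"]))
    out_of_bounds = ~bad_coord & ~(
        (df["x"] >= 0) & (df["x"] <= width) & (df["y"] >= 0) & (df["y"] <= height)
    )
    keep = ~(bad_coord | out_of_bounds)
    if bad_coord.any():
        log.warning("%s: rejected %d rows with unparseable coordinates", path, int(bad_coord.sum()))
    if out_of_bounds.any():
        log.warning("%s: rejected %d out-of-bounds localizations", path, int(out_of_bounds.sum()))
    df = df.loc[keep].reset_index(drop=True)

    if "id" not in df.columns:
        df["id"] = np.arange(len(df))
    elif df["id"].duplicated().any():
        log.warning("%s: duplicate localization ids re-keyed", path)
        df["id"] = np.arange(len(df))
    if "frame" not in df.columns:
        df["frame"] = 0
    if "sigma" in df.columns:
        df["sigma"] = pd.to_numeric(df["sigma"], errors="coerce")

    cols = ["id", "frame", "x", "y"] + [c for c in ("sigma", "intensity", "channel") if c in df.columns]
    roi = RegionOfInterest(roi_id, width, height, df[cols], coverslip_id)
    roi.n_rejected = n_total - len(df)
    return roi


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({"id": pd.Series(dtype=int), "frame": pd.Series(dtype=int),
                         "x": pd.Series(dtype=float), "y": pd.Series(dtype=float)})


def read_roi_manifest(path: str | Path) -> pd.DataFrame:
    """Read an ROI manifest CSV: ``roi_id, path, width_nm, height_nm[, coverslip_id]``."""
    man = pd.read_csv(path)
    for col in ("roi_id", "path", "width_nm", "height_nm"):
        if col not in man.columns:
            raise FormatError(f"{path}: ROI manifest missing column {col!r}")
    if "coverslip_id" not in man.columns:
        man["coverslip_id"] = ""
    return man


def read_localizations(manifest_path: str | Path) -> list[RegionOfInterest]:
    """Read all ROIs named by a manifest, in manifest order.

    Relative table paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    man = read_roi_manifest(manifest_path)
    rois = []
    for row in man.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        rois.append(
            read_localization_table(
                p, float(row.width_nm), float(row.height_nm),
                roi_id=str(row.roi_id), coverslip_id=str(row.coverslip_id),
            )
        )
    return rois


def write_roi_dir(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, width: float, height: float
) -> Path:
    """Write per-ROI CSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for roi_id, df in tables.items():
        fname = f"{roi_id}.csv"
        write_localizations(df, out_dir / fname)
        rows.append({"roi_id": roi_id, "path": fname, "width_nm": width, "height_nm": height,
                     "coverslip_id": ""})
    manifest = out_dir / "rois.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest pairing assay conditions with ROI manifests.

    Columns: ``animal_id, cohort (test|control), fluid (plasma|CSF),
    capture_target, stain, path, volume_raw_ul``.
    """
    man = pd.read_csv(path)
    required = ("animal_id", "cohort", "fluid", "capture_target", "stain", "path", "volume_raw_ul")
    for col in required:
        if col not in man.columns:
            raise FormatError(f"{path}: cohort manifest missing column {col!r}")
    bad = set(man["cohort"]) - {"test", "control"}
    if bad:
        raise FormatError(f"{path}: cohort must be test|control, got {sorted(bad)}")
    return man
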