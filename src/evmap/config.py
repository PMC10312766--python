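"""Assay and simulation configuration objects.

The assay configuration carries the two calibration constants of the counting
pipeline: ``L``, the average number of localizations produced by one bound
fluorescent tetraspanin antibody over an acquisition (default 14), and ``M``,
the minimum number of localizations a Voronoi cluster must contain before it
is counted as a vesicle (default 40, i.e. roughly three detected marker
proteins at the default ``L``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Marker species recognised by the pipeline. ``HsCD81`` is the tracer
#: (human CD81 fused to mNeonGreen, expressed only in Cre-activated cells);
#: the mouse tetraspanins are the constitutive exosome markers.
SPECIES = ("MmCD9", "MmCD63", "MmCD81", "HsCD81")
TRACER = "HsCD81"

#: Detection-antibody panels used in the capture/stain experiments.
MOUSE_PANEL = frozenset({"MmCD9", "MmCD63", "MmCD81"})
HUMAN_STAIN = frozenset({"HsCD81"})
FULL_PANEL = frozenset(SPECIES)


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its invariants."""


@dataclass
class AssayConfig:
    """Parameters of one capture/stain qSMLM counting run.

    Parameters
    ----------
    capture_target
        Species the coverslip antibody binds (immobilization epitope).
    stain_panel
        Species detected by the fluorophore-labeled staining antibodies.
    volume_raw_ul
        Raw biofluid volume (μL) incubated on the coverslip; per-ROI counts
        are divided by this to give EV/μL.
    L
        Mean localizations per bound detection antibody (blinking calibration).
    M
        Minimum localizations per cluster for a vesicle to be counted.
    alpha
        Voronoi density threshold: keep localizations whose cell area is at
        most ``alpha`` times the median cell area of the ROI.
    sigma_default
        Localization precision (nm) used for diameter correction when the
        table carries no per-localization ``sigma`` column.
    exclude_boundary_clusters
        Drop clusters whose cells touch the ROI edge (truncation bias).
    """

    capture_target: str = "MmCD81"
    stain_panel: frozenset[str] = MOUSE_PANEL
    volume_raw_ul: float = 1.0
    L: float = 14.0
    M: int = 40
    alpha: float = 0.5
    sigma_default: float = 12.0
    exclude_boundary_clusters: bool = True
    boundary_guard_nm: float = 100.0

    def __post_init__(self) -> None:
        self.stain_panel = frozenset(self.stain_panel)
        if self.capture_target not in SPECIES:
            raise ConfigurationError(
                f"capture_target: unknown species {self.capture_target!r}"
            )
        unknown = self.stain_panel - set(SPECIES)
        if unknown:
            raise ConfigurationError(f"stain_panel: unknown species {sorted(unknown)}")
        if not self.stain_panel:
            raise ConfigurationError("stain_panel: must not be empty")
        if not self.volume_raw_ul > 0:
            raise ConfigurationError("volume_raw_ul: must be > 0")
        if not self.L > 0:
            raise ConfigurationError("L: must be > 0")
        if self.M < 1:
            raise ConfigurationError("M: must be >= 1")
        if not self.alpha > 0:
            raise ConfigurationError("alpha: must be > 0")
        if self.sigma_default < 0:
            raise ConfigurationError("sigma_default: must be >= 0")
        if self.boundary_guard_nm < 0:
            raise ConfigurationError("boundary_guard_nm: must be >= 0")


def read_assay_config(path: str | Path, **overrides) -> AssayConfig:
    """Load an :class:`AssayConfig` from a flat-key YAML file.

    Absent optional keys take their defaults (``L=14``, ``M=40``,
    ``alpha=0.5`` ...). Keyword ``overrides`` (e.g. from CLI flags) take
    precedence over file values.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping of config keys")
    known = set(AssayConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    raw.update(overrides)
    if "stain_panel" in raw:
        raw["stain_panel"] = frozenset(raw["stain_panel"])
    return AssayConfig(**raw)


def write_assay_config(cfg: AssayConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["stain_panel"] = sorted(cfg.stain_panel)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimulationConfig:
    """Forward-model parameters for the synthetic capture/stain assay.

    Copy numbers per species are Poisson with mean
    ``marker_mean_per_species[s] * (diameter / 80 nm)**2`` — surface proteins
    scale with membrane area. Tracer-positive vesicles (probability
    ``fraction_tracer_positive``) draw their HsCD81 copies from the
    zero-truncated version of that Poisson law; tracer-negative vesicles carry
    none. Each bound antibody blinks a geometric number of times (support
    ``{1, 2, ...}``) with mean ``localizations_per_antibody_mean``.
    """

    n_ev: int = 4000
    fraction_tracer_positive: float = 0.15
    diameter_median: float = 80.0
    diameter_log_sd: float = 0.3
    marker_mean_per_species: dict[str, float] = field(
        default_factory=lambda: {
            "MmCD9": 7.0,
            "MmCD63": 7.0,
            "MmCD81": 7.0,
            "HsCD81": 20.0,
        }
    )
    label_prob: float = 0.7
    capture_prob_per_copy: float = 0.9
    localizations_per_antibody_mean: float = 14.0
    localization_sigma: float = 10.0
    background_density: float = 1.0  # localizations per μm²
    roi_width: float = 50_000.0  # nm
    roi_height: float = 50_000.0  # nm
    n_roi: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_tracer_positive", "label_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: {v} not in [0, 1]")
        if not 0.0 < self.capture_prob_per_copy <= 1.0:
            raise ConfigurationError("capture_prob_per_copy: must be in (0, 1]")
        if self.n_ev <= 0:
            raise ConfigurationError("n_ev: must be positive")
        if self.n_roi <= 0:
            raise ConfigurationError("n_roi: must be positive")
        if not self.diameter_median > 0:
            raise ConfigurationError("diameter_median: must be > 0")
        if self.diameter_log_sd < 0:
            raise ConfigurationError("diameter_log_sd: must be >= 0")
        for name in (
            "localizations_per_antibody_mean",
            "localization_sigma",
            "background_density",
            "roi_width",
            "roi_height",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.localizations_per_antibody_mean < 1:
            raise ConfigurationError(
                "localizations_per_antibody_mean: geometric blink law needs mean >= 1"
            )
        unknown = set(self.marker_mean_per_species) - set(SPECIES)
        if unknown:
            raise ConfigurationError(
                f"marker_mean_per_species: unknown species {sorted(unknown)}"
            )
        if any(v < 0 for v in self.marker_mean_per_species.values()):
            raise ConfigurationError("marker_mean_per_species: means must be >= 0")


def read_simulation_config(path: str | Path, **overrides) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping of config keys")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    raw.update(overrides)
    return SimulationConfig(**raw)


def write_simulation_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
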