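"""Forward simulator of the single-vesicle capture/stain dSTORM assay.

The generative model, stage by stage:

1. **Population** — ``n_ev`` vesicles with log-normal diameters (median
   ``diameter_median``, shape ``diameter_log_sd``). Per-species tetraspanin
   copy numbers are Poisson with mean proportional to membrane area,
   ``mean_s * (d / 80 nm)**2``. A fraction ``f`` of vesicles is
   tracer-positive and draws its HsCD81 copies from the zero-truncated
   Poisson (so tracer-positive ⇔ at least one HsCD81 copy); the rest carry
   none.
2. **Capture** — a vesicle with ``k`` copies of the coverslip antibody's
   target is immobilized with probability ``1 - (1 - p_cap)**k``; in
   addition a Poisson number of vesicles per ROI sticks non-specifically.
   Captured vesicles land uniformly at random inside their ROI.
3. **Staining and blinking** — each copy of each stained species is bound by
   a labeled antibody with probability ``label_prob``; each bound antibody
   sits at a uniform point of the vesicle's spherical surface
   (orthographically projected onto the coverslip plane) and emits a
   geometric number of localizations (support ≥ 1, mean ``L_sim``), each
   jittered by isotropic Gaussian noise of sd ``localization_sigma`` per
   axis. Uniform background localizations are added as a spatial Poisson
   process.

Every emitted localization is linked to its source vesicle (or background)
in a truth table, so the detection and estimation stages downstream can be
validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SPECIES, TRACER, ConfigurationError, SimulationConfig

#: frames in a simulated acquisition (only used to stamp a frame index).
N_FRAMES = 20_000

LOC_COLUMNS = ["id", "frame", "x", "y", "sigma", "intensity", "channel"]
TRUTH_COLUMNS = ["roi_id", "loc_id", "ev_id", "species"]


@dataclass
class TrueEV:
    """Ground-truth vesicle record."""

    id: int
    diameter: float  # nm
    marker_copies: dict[str, int]
    center_xy: tuple[float, float] | None = None  # nm, set at capture
    roi_id: str | None = None
    captured: bool = False
    nonspecific: bool = False

    @property
    def source_label(self) -> str:
        return "tracer-positive" if self.marker_copies.get(TRACER, 0) >= 1 else "tracer-negative"


def _rng(cfg: SimulationConfig, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *salt]))


def _zero_truncated_poisson(mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample Poisson(mu) conditioned on being >= 1, element-wise."""
    mu = np.asarray(mu, dtype=float)
    p0 = np.exp(-mu)
    u = p0 + rng.random(mu.shape) * (1.0 - p0)
    k = stats.poisson.ppf(u, mu).astype(int)
    return np.maximum(k, 1)


def simulate_ev_population(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TrueEV]:
    """Draw the ground-truth vesicle population of one experiment."""
    rng = _rng(cfg, 1) if rng is None else rng
    n = cfg.n_ev
    diam = rng.lognormal(np.log(cfg.diameter_median), cfg.diameter_log_sd, size=n)
    area_scale = (diam / 80.0) ** 2

    tracer_pos = rng.random(n) < cfg.fraction_tracer_positive
    copies: dict[str, np.ndarray] = {}
    for sp in SPECIES:
        mean = cfg.marker_mean_per_species.get(sp, 0.0)
        if sp == TRACER:
            k = np.zeros(n, dtype=int)
            if tracer_pos.any():
                mu = np.maximum(mean * area_scale[tracer_pos], 1e-12)
                k[tracer_pos] = _zero_truncated_poisson(mu, rng)
            copies[sp] = k
        else:
            copies[sp] = rng.poisson(mean * area_scale)

    return [
        TrueEV(
            id=i,
            diameter=float(diam[i]),
            marker_copies={sp: int(copies[sp][i]) for sp in SPECIES},
        )
        for i in range(n)
    ]


def roi_ids(n_roi: int) -> list[str]:
    return [f"roi{r:03d}" for r in range(n_roi)]


def simulate_capture(
    population: list[TrueEV],
    capture_target: str,
    p_cap: float,
    nonspecific_rate: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[TrueEV]:
    """Immobilize vesicles on the antibody-functionalized coverslip.

    Returns copies of the captured subset with ``roi_id`` and ``center_xy``
    assigned. ``nonspecific_rate`` is the expected number of vesicles per ROI
    that stick regardless of composition (assay noise floor).
    """
    if capture_target not in SPECIES:
        raise ConfigurationError(f"unknown capture target {capture_target!r}")
    rng = _rng(cfg, 2) if rng is None else rng

    k = np.array([ev.marker_copies.get(capture_target, 0) for ev in population])
    p_specific = 1.0 - (1.0 - p_cap) ** k  # k = 0 -> 0 exactly
    specific = rng.random(len(population)) < p_specific

    # non-specific sticking: Poisson(nonspecific_rate) per ROI, drawn from the
    # vesicles not already captured
    nonspecific = np.zeros(len(population), dtype=bool)
    roi_of_nonspecific: dict[int, int] = {}
    if nonspecific_rate > 0:
        free = np.flatnonzero(~specific)
        rng.shuffle(free)
        cursor = 0
        for r in range(cfg.n_roi):
            n_stick = rng.poisson(nonspecific_rate)
            take = free[cursor : cursor + n_stick]
            cursor += n_stick
            nonspecific[take] = True
            for i in take:
                roi_of_nonspecific[int(i)] = r

    captured: list[TrueEV] = []
    names = roi_ids(cfg.n_roi)
    for i, ev in enumerate(population):
        if not (specific[i] or nonspecific[i]):
            continue
        r = roi_of_nonspecific[i] if nonspecific[i] else int(rng.integers(cfg.n_roi))
        x = float(rng.uniform(0.0, cfg.roi_width))
        y = float(rng.uniform(0.0, cfg.roi_height))
        captured.append(
            TrueEV(
                id=ev.id,
                diameter=ev.diameter,
                marker_copies=dict(ev.marker_copies),
                center_xy=(x, y),
                roi_id=names[r],
                captured=True,
                nonspecific=bool(nonspecific[i] and not specific[i]),
            )
        )
    return captured


def sample_projected_shell(
    n: int, radius: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Project ``n`` uniform points on a sphere of ``radius`` to the plane,
    with isotropic Gaussian localization noise of sd ``sigma`` per axis.

    For this model ``E[r²] = 2R²/3 + 2σ²`` about the true center, the
    identity inverted by :func:`evmap.metrics.estimate_diameter`.
    """
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    xy = radius * v[:, :2]
    if sigma > 0:
        xy = xy + rng.normal(scale=sigma, size=xy.shape)
    return xy


def simulate_localizations(
    captured: list[TrueEV],
    stain_panel: frozenset[str] | set[str],
    cfg: SimulationConfig,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Stain captured vesicles and emit per-ROI localization tables.

    Returns ``(tables, truth)`` where ``tables`` maps roi_id to a localization
    DataFrame (columns ``id, frame, x, y, sigma, intensity, channel``) and
    ``truth`` links every localization to its vesicle (``ev_id = -1`` for
    background). Each ROI uses an independent random stream derived from the
    master seed, so ROIs can be generated in any order.
    """
    stain_panel = frozenset(stain_panel)
    if not stain_panel:
        raise ConfigurationError("stain panel must not be empty")
    unknown = stain_panel - set(SPECIES)
    if unknown:
        raise ConfigurationError(f"stain panel: unknown species {sorted(unknown)}")
    if cfg.roi_width <= 0 or cfg.roi_height <= 0:
        raise ConfigurationError("ROI dimensions must be positive")
    seed = cfg.seed if seed is None else seed

    by_roi: dict[str, list[TrueEV]] = {name: [] for name in roi_ids(cfg.n_roi)}
    for ev in captured:
        if ev.roi_id is None or ev.center_xy is None:
            raise ValueError(f"EV {ev.id} has no assigned ROI/center; run capture first")
        by_roi.setdefault(ev.roi_id, []).append(ev)

    tables: dict[str, pd.DataFrame] = {}
    truth_parts: list[pd.DataFrame] = []
    for r, roi_id in enumerate(roi_ids(cfg.n_roi)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3, r]))
        xs, ys, ev_of, sp_of = [], [], [], []

        for ev in by_roi[roi_id]:
            radius = ev.diameter / 2.0
            for sp in sorted(stain_panel):
                n_ab = rng.binomial(ev.marker_copies.get(sp, 0), cfg.label_prob)
                if n_ab == 0:
                    continue
                anchors = ev.center_xy + sample_projected_shell(n_ab, radius, 0.0, rng)
                blinks = rng.geometric(1.0 / cfg.localizations_per_antibody_mean, n_ab)
                pts = np.repeat(anchors, blinks, axis=0)
                if cfg.localization_sigma > 0:
                    pts = pts + rng.normal(scale=cfg.localization_sigma, size=pts.shape)
                xs.append(pts[:, 0])
                ys.append(pts[:, 1])
                ev_of.append(np.full(len(pts), ev.id))
                sp_of.extend([sp] * len(pts))

        area_um2 = cfg.roi_width * cfg.roi_height * 1e-6
        n_bg = rng.poisson(cfg.background_density * area_um2)
        if n_bg:
            xs.append(rng.uniform(0.0, cfg.roi_width, n_bg))
            ys.append(rng.uniform(0.0, cfg.roi_height, n_bg))
            ev_of.append(np.full(n_bg, -1))
            sp_of.extend(["background"] * n_bg)

        if xs:
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            ev_arr = np.concatenate(ev_of).astype(int)
            sp_arr = np.array(sp_of)
        else:
            x = y = np.empty(0)
            ev_arr = np.empty(0, dtype=int)
            sp_arr = np.empty(0, dtype=object)

        # localizations whose fitted position falls outside the imaged field
        # are not recorded
        inside = (x >= 0) & (x <= cfg.roi_width) & (y >= 0) & (y <= cfg.roi_height)
        x, y, ev_arr, sp_arr = x[inside], y[inside], ev_arr[inside], sp_arr[inside]

        n = len(x)
        frame = rng.integers(0, N_FRAMES, n)
        order = np.lexsort((np.arange(n), frame))
        df = pd.DataFrame(
            {
                "id": np.arange(n),
                "frame": frame[order],
                "x": x[order],
                "y": y[order],
                "sigma": np.full(n, cfg.localization_sigma),
                "intensity": np.round(rng.lognormal(7.0, 0.4, n), 1),
                "channel": np.ones(n, dtype=int),
            }
        )
        tables[roi_id] = df
        truth_parts.append(
            pd.DataFrame(
                {
                    "roi_id": roi_id,
                    "loc_id": np.arange(n),
                    "ev_id": ev_arr[order],
                    "species": sp_arr[order],
                }
            )
        )

    truth = (
        pd.concat(truth_parts, ignore_index=True)
        if truth_parts
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    return tables, truth
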