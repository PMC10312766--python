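"""End-to-end drivers: simulate an assay, detect, count, and estimate.

The scenario presets mirror the two study designs the pipeline targets:

* ``plasma`` — hepatocyte-scale tracer fraction f = 0.15; 20 ROIs per
  condition; ~200 vesicles reach each ROI per μL of plasma; reference
  capture (anti-MmCD81) incubates 1 μL, tracer capture (anti-HsCD81) 5 μL.
* ``csf`` — neuron-scale tracer fraction f = 0.01; 10 ROIs; ~40 vesicles
  per ROI per μL of CSF; 1 μL on the reference coverslip, 6 μL on the
  tracer coverslip.

Each scenario simulates four cohorts (test and tracer-negative control on
both coverslips, all stained with the mouse tetraspanin panel), runs the
Voronoi detection pipeline on every ROI, and computes the capture-based
contribution with background correction — a full parameter-recovery loop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MOUSE_PANEL, AssayConfig, SimulationConfig
from .evaluate import DetectionScore, pool_scores, score_detection
from .io import RegionOfInterest
from .metrics import EvMeasurement, measure_clusters
from .quant import (
    ContributionEstimate,
    RoiCount,
    background_and_correct,
    count_rois,
    summarize_cohort,
)
from .simulate import (
    roi_ids,
    simulate_capture,
    simulate_ev_population,
    simulate_localizations,
)
from .voronoi import detect_clusters


@dataclass
class ConditionResult:
    """Everything measured in one capture/stain condition."""

    name: str
    assay: AssayConfig
    tables: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    counts: list[RoiCount]
    measurements: list[EvMeasurement]
    scores: list[DetectionScore] = field(default_factory=list)

    @property
    def summary(self):
        return summarize_cohort(self.counts, condition=self.name)

    @property
    def detection(self) -> DetectionScore:
        return pool_scores(self.scores)


def analyze_tables(
    tables: dict[str, pd.DataFrame],
    assay: AssayConfig,
    width: float,
    height: float,
    truth: pd.DataFrame | None = None,
    min_true_loc: int | None = None,
) -> tuple[list[RoiCount], list[EvMeasurement], list[DetectionScore]]:
    """Run detection + measurement over per-ROI localization tables."""
    n_per_roi: dict[str, int] = {}
    measurements: list[EvMeasurement] = []
    scores: list[DetectionScore] = []
    for roi_id, df in tables.items():
        roi = RegionOfInterest(roi_id, width, height, df)
        extraction = detect_clusters(roi, assay)
        n_per_roi[roi_id] = len(extraction.clusters)
        measurements.extend(measure_clusters(df, extraction.clusters, assay))
        if truth is not None:
            scores.append(
                score_detection(
                    extraction.clusters,
                    truth,
                    roi_id,
                    min_true_loc=assay.M if min_true_loc is None else min_true_loc,
                )
            )
    counts = count_rois(n_per_roi, assay.volume_raw_ul)
    return counts, measurements, scores


def simulate_condition(
    name: str,
    sim: SimulationConfig,
    assay: AssayConfig,
    nonspecific_rate: float,
    seed: int,
) -> ConditionResult:
    """Simulate one capture/stain condition and analyze it end to end."""
    sim = dataclasses.replace(sim, seed=seed)
    population = simulate_ev_population(sim)
    captured = simulate_capture(
        population, assay.capture_target, sim.capture_prob_per_copy,
        nonspecific_rate, sim,
    )
    tables, truth = simulate_localizations(captured, assay.stain_panel, sim)
    counts, measurements, scores = analyze_tables(
        tables, assay, sim.roi_width, sim.roi_height, truth
    )
    return ConditionResult(name, assay, tables, truth, counts, measurements, scores)


@dataclass
class ScenarioSpec:
    """Study-condition preset for a full capture/stain experiment."""

    fraction_tracer_positive: float
    n_roi: int
    ev_per_roi_ul: float  # vesicles reaching one ROI per μL incubated
    volume_reference_ul: float
    volume_tracer_ul: float
    nonspecific_rate: float  # non-specifically stuck vesicles per ROI


SCENARIOS: dict[str, ScenarioSpec] = {
    "plasma": ScenarioSpec(
        fraction_tracer_positive=0.15,
        n_roi=20,
        ev_per_roi_ul=200.0,
        volume_reference_ul=1.0,
        volume_tracer_ul=5.0,
        nonspecific_rate=0.5,
    ),
    "csf": ScenarioSpec(
        fraction_tracer_positive=0.01,
        n_roi=10,
        ev_per_roi_ul=40.0,
        volume_reference_ul=1.0,
        volume_tracer_ul=6.0,
        nonspecific_rate=0.2,
    ),
}


@dataclass
class ExperimentResult:
    scenario: str
    true_fraction: float
    conditions: dict[str, ConditionResult]
    estimate: ContributionEstimate

    def condition_summaries(self) -> pd.DataFrame:
        rows = []
        for name, cond in self.conditions.items():
            s = cond.summary
            rows.append(
                {"condition": name, "n_roi": s.n_roi, "mean": s.mean,
                 "median": s.median, "sem": s.sem, "cv": s.cv}
            )
        return pd.DataFrame(rows)


def _condition_configs(
    spec: ScenarioSpec, base: SimulationConfig
) -> dict[str, tuple[SimulationConfig, AssayConfig, float]]:
    """(simulation cfg, assay cfg, tracer fraction) for the four cohorts."""
    out = {}
    for cohort, f in (("test", spec.fraction_tracer_positive), ("control", 0.0)):
        for role, capture, vol in (
            ("reference", "MmCD81", spec.volume_reference_ul),
            ("tracer", "HsCD81", spec.volume_tracer_ul),
        ):
            n_ev = max(1, round(spec.ev_per_roi_ul * vol * spec.n_roi))
            sim = dataclasses.replace(
                base,
                n_ev=n_ev,
                fraction_tracer_positive=f,
                n_roi=spec.n_roi,
            )
            assay = AssayConfig(
                capture_target=capture,
                stain_panel=MOUSE_PANEL,
                volume_raw_ul=vol,
            )
            out[f"{cohort}_{role}"] = (sim, assay, f)
    return out


def run_contribution_experiment(
    scenario: str,
    seed: int,
    base: SimulationConfig | None = None,
    n_boot: int = 2000,
) -> ExperimentResult:
    """Simulate a full paired capture experiment and recover the tracer
    fraction with the capture-based estimator.

    ``seed`` drives every random stage; condition sub-seeds are derived from
    it so the four cohorts are independent.
    """
    spec = SCENARIOS[scenario]
    base = base or SimulationConfig()
    sub = np.random.SeedSequence(seed).generate_state(5)

    conditions: dict[str, ConditionResult] = {}
    for i, (name, (sim, assay, _f)) in enumerate(_condition_configs(spec, base).items()):
        conditions[name] = simulate_condition(
            name, sim, assay, spec.nonspecific_rate, seed=int(sub[i]) % (2**31)
        )

    from .quant import contribution_capture

    f_raw = contribution_capture(
        conditions["test_tracer"].summary, conditions["test_reference"].summary
    )
    estimate = background_and_correct(
        f_raw,
        test_num=conditions["test_tracer"].counts,
        test_den=conditions["test_reference"].counts,
        ctrl_num=conditions["control_tracer"].counts,
        ctrl_den=conditions["control_reference"].counts,
        n_boot=n_boot,
        rng=int(sub[4]) % (2**31),
    )
    return ExperimentResult(scenario, spec.fraction_tracer_positive, conditions, estimate)


def simulate_planted_rois(
    n_roi: int,
    evs_per_roi: int,
    seed: int,
    roi_width: float = 20_000.0,
    roi_height: float = 20_000.0,
    min_separation: float = 2_000.0,
    margin: float = 1_000.0,
    base: SimulationConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SimulationConfig]:
    """Plant well-separated vesicles on a grid of ROIs (clustering oracle).

    Centers are rejection-sampled to enforce ``min_separation`` and kept
    ``margin`` away from the ROI edge so no cluster is boundary-truncated.
    """
    base = base or SimulationConfig()
    cfg = dataclasses.replace(
        base,
        n_ev=n_roi * evs_per_roi,
        fraction_tracer_positive=0.0,
        roi_width=roi_width,
        roi_height=roi_height,
        n_roi=n_roi,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    population = simulate_ev_population(cfg, rng)
    names = roi_ids(n_roi)
    captured = []
    idx = 0
    for r in range(n_roi):
        centers: list[tuple[float, float]] = []
        while len(centers) < evs_per_roi:
            x = rng.uniform(margin, roi_width - margin)
            y = rng.uniform(margin, roi_height - margin)
            if all(np.hypot(x - cx, y - cy) >= min_separation for cx, cy in centers):
                centers.append((x, y))
        for c in centers:
            ev = population[idx]
            idx += 1
            captured.append(
                dataclasses.replace(
                    ev, center_xy=c, roi_id=names[r], captured=True
                )
            )
    tables, truth = simulate_localizations(captured, MOUSE_PANEL, cfg)
    return tables, truth, cfg
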