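#!/usr/bin/env python
"""Simulate a small capture/stain dSTORM experiment and write its tables.

Produces per-ROI localization CSVs (ThunderSTORM-compatible header), the
ground-truth table linking localizations to vesicles, and the echoed
simulation manifest, under scratch/sim_demo/ (localization tables are bulky
regenerable artifacts, so they stay out of the tracked results). The scale
is deliberately small (4 ROIs, ~50 vesicles per ROI); the full-scale study
conditions live in evmap.pipeline.SCENARIOS.
"""

import argparse
from pathlib import Path

from evmap.config import MOUSE_PANEL, SimulationConfig, write_simulation_config
from evmap.io import write_roi_dir
from evmap.simulate import simulate_capture, simulate_ev_population, simulate_localizations

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim_demo"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = SimulationConfig(n_ev=200, fraction_tracer_positive=0.15, n_roi=4,
                           seed=args.seed)
    population = simulate_ev_population(cfg)
    captured = simulate_capture(population, "MmCD81", cfg.capture_prob_per_copy,
                                nonspecific_rate=0.5, cfg=cfg)
    tables, truth = simulate_localizations(captured, MOUSE_PANEL, cfg)

    manifest = write_roi_dir(tables, OUT, cfg.roi_width, cfg.roi_height)
    truth.to_csv(OUT / "truth.csv", index=False)
    write_simulation_config(cfg, OUT / "sim.yaml")

    n_loc = sum(len(df) for df in tables.values())
    n_pos = sum(ev.source_label == "tracer-positive" for ev in captured)
    print(f"simulated {len(population)} vesicles, captured {len(captured)} "
          f"({n_pos} tracer-positive), {n_loc} localizations in {len(tables)} ROIs")
    print(f"tables + truth + manifest -> {OUT}")
    print(f"ROI manifest: {manifest}")


if __name__ == "__main__":
    main()
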