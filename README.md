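# evmap

Single-vesicle quantitative single-molecule localization microscopy (qSMLM)
analysis of biofluid exosome populations: which cell types contribute how
many of the extracellular vesicles circulating in blood and CSF?

## The problem

In a tracer mouse, Cre-marked cells of one type (hepatocytes, neurons, …)
decorate their exosomes with human CD81 while every mouse exosome carries
mouse CD81. Incubating raw plasma or CSF on coverslips functionalized with
anti-mouse-CD81 (capturing all exosomes) or anti-human-CD81 (capturing only
tracer-marked ones), staining with fluorophore-labeled anti-tetraspanin
antibodies, and imaging by dSTORM turns each immobilized vesicle into a
dense clump of single-molecule localizations. Counting those clumps per
region of interest (ROI), normalized to the incubated biofluid volume,
gives the cell type's contribution as a ratio of cohort means:

    f_capture = EV/μL (tracer capture, panel stain) / EV/μL (reference capture, panel stain)
    f_stain   = EV/μL (reference capture, tracer stain) / EV/μL (reference capture, panel stain)

corrected by the same ratio measured in a tracer-negative control animal.

`evmap` implements the full chain:

* **Detection** — Voronoi-tessellation density clustering of localization
  tables: cells clipped exactly to the ROI, first-rank (neighborhood-median)
  density threshold at `alpha = 0.5` relative to the ROI mean cell area,
  connected components, and a hard floor of `M = 40` localizations per
  reported vesicle.
* **Per-vesicle metrics** — detected tetraspanins `n_loc / L` with the
  blinking calibration `L = 14` localizations per bound antibody, and a
  precision-corrected spherical-projection diameter
  `D̂ = 2·sqrt(1.5·max(0, m2 − 2σ²))`.
* **Quantification** — per-ROI EV/μL counts, cohort mean/median/SEM/CV,
  paired capture/stain contribution estimators with background correction
  and bootstrap confidence intervals, and log-transformed group tests.
* **Simulation** — a forward model of the entire assay (log-normal vesicle
  sizes, area-scaled Poisson marker copies, per-copy capture, geometric
  antibody blinking, Gaussian localization noise, Poisson background) with
  a ground-truth table, so every stage is validated by parameter recovery.

## Worked example

Simulate a plasma-scale paired experiment (tracer fraction 0.15 planted in
the test animal, four cohorts of 20 ROIs) and recover the contribution:

```python
from evmap.pipeline import run_contribution_experiment

res = run_contribution_experiment("plasma", seed=0)
e = res.estimate
print(f"planted {res.true_fraction:.3f}, recovered {e.f_corrected:.4f} "
      f"(95% CI {e.ci_low:.4f}-{e.ci_high:.4f}, background {e.f_background:.4f})")
```

prints (≈2 minutes):

```
planted 0.150, recovered 0.1494 (95% CI 0.1419-0.1577, background 0.0005)
```

i.e. the capture-based estimator recovers the planted 15% hepatocyte-like
contribution as 14.9% with a tight bootstrap interval and a ~0.05%
control-animal background. The bundled published cohort tables reproduce
the reported headline figures the same way:

```bash
python analysis/01_reported_ratios.py
```

```
hepatocyte contribution to plasma exosomes (stain-based)    11.39 %
hepatocyte contribution to plasma exosomes (capture-based)  17.52 %
neuronal contribution to plasma exosomes (capture-based)     1.27 %
neuronal contribution to CSF exosomes (capture-based)        0.95 %
```

(stain-based positivity requires ~3 detected markers = 40 localizations,
so it is the conservative bound; capture needs a single tracer copy).

## Repository layout

    src/evmap/          library: config, simulate, io, voronoi, metrics,
                        quant, evaluate, pipeline, datasets, cli
    analysis/           numbered drivers writing tables under results/
      01_reported_ratios.py        contribution fractions from published tables
      02_simulate_assay.py         small demo simulation (to scratch/)
      03_detection_validation.py   planted-vesicle precision/recall
      04_diameter_recovery.py      diameter estimator bias grid
      05_contribution_recovery.py  end-to-end fraction recovery, both scales
    tests/              pytest suite incl. acceptance checks
    docs/methods.md     model, estimators, simulator defaults, limitations

A `evmap` console script exposes `simulate`, `cluster`, `quantify` and
`contribution` subcommands over the same library (`evmap --help`).

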