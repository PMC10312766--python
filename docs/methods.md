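# Methods

`evmap` quantifies single extracellular vesicles (EVs) immobilized on
antibody-functionalized coverslips and imaged by direct stochastic optical
reconstruction microscopy (dSTORM). The pipeline consumes per-ROI
single-molecule localization tables — it does not touch camera frames — and
produces per-vesicle marker counts and diameters, volume-normalized vesicle
counts, and paired-cohort estimates of the fraction of biofluid exosomes
contributed by a tracer-labeled cell type.

## The assay being modeled

A raw biofluid sample (plasma or CSF, a few μL) is incubated overnight on a
coverslip carrying either an anti-mouse-CD81 antibody (the *reference*
capture, binding essentially every mouse exosome) or an anti-human-CD81
antibody (the *tracer* capture, binding only vesicles that carry the
HsCD81-mNeonGreen tracer expressed in one Cre-marked cell type). Captured
vesicles are stained with AF647-labeled antibodies against the exosomal
tetraspanins (mouse CD9/CD63/CD81 and/or human CD81) and imaged; repeated
fluorophore blinking turns each bound antibody into a clump of
localizations.

Two calibration constants anchor all counting:

* **L = 14** — the average number of localizations one bound fluorescent
  tetraspanin antibody contributes over an acquisition. Detected markers per
  vesicle are `n_loc / L`.
* **M = 40** — the minimum localizations for a cluster to be counted as a
  vesicle, i.e. roughly three detected marker proteins. This positivity
  floor is what makes the *stain-based* estimator a practical lower bound
  (a vesicle carrying one or two tracer molecules stains below the floor),
  while the *capture-based* estimator needs only a single surface tracer
  copy for immobilization and avoids that bias.

## Vesicle detection

Per ROI (coordinates in nm, origin at the lower-left corner):

1. **Tessellation.** One Voronoi cell per localization, clipped exactly to
   the ROI rectangle by mirror-point reflection: the point set is reflected
   across each edge before tessellating, so every interior cell is finite
   and the cells partition the ROI area to floating-point accuracy (the
   implementation checks the partition to 1 part in 10⁹ and falls back
   from an adaptive mirror margin to a full mirror if it fails). Exact
   duplicate coordinates are merged first, with multiplicity counted toward
   cluster size. Adjacency is a shared polygon edge of positive length;
   vertex-only contact does not connect.
2. **Density threshold.** A localization is retained when the *median* area
   over its own cell and its edge-sharing neighbors is at most
   `alpha × (ROI area / n)`, with `alpha = 0.5` by default — i.e. its
   first-rank neighborhood is at least twice as dense as the ROI average.
   The neighborhood median is used rather than the single-cell area because
   the outermost cells of a genuine cluster flare into the surrounding
   empty space and would otherwise be discarded, shaving members off every
   cluster; the median (unlike the mean) is also not dragged up by one huge
   background neighbor, and (unlike a raw-area rule referenced to the ROI
   *median* cell area) the reference to the ROI *mean* cell area stays
   meaningful when most localizations sit inside clusters. A single closing
   pass then annexes any cell at least half of whose neighbors were
   retained; annexation is monotone and cannot percolate through sparse
   background (an isolated annexed background cell remains a singleton and
   is dropped by the size floor).
3. **Clusters.** Connected components of the retained set, with two guards:
   an adjacency edge is cut when the two localizations are farther apart
   than `sqrt(alpha × mean cell area)` — the linear scale of the density
   threshold — which prevents a handful of retained background points from
   bridging distinct vesicles; and components with fewer than `M`
   localizations are discarded. Clusters whose localizations come within
   `boundary_guard_nm` (default 100 nm, about a vesicle radius plus
   localization noise) of the ROI edge are excluded from counting as
   possibly truncated, and the exclusion count is logged. Flagging by
   member-cell contact with the edge was rejected: in sparse background the
   flaring rim cell of a cluster a full micrometre from the edge can reach
   the rectangle, and cell-contact flagged ~6% of planted vesicles that
   were nowhere near truncation.

At `alpha = 0.5` a pure Poisson background retains ~10–15% of its
localizations, far below the site-percolation threshold of the Delaunay
graph (~0.5), so chance background clusters of ≥40 localizations
effectively never occur.

## Per-vesicle quantities

* **Detected markers** = `n_loc / L`, kept real-valued; integers appear
  only in formatted reports.
* **Diameter.** Antibodies bind the vesicle surface, a sphere of radius R
  viewed in orthographic projection (vesicle radius ≪ TIRF depth; the
  antibody linker adds <10 nm and is folded into the localization noise).
  For uniform sphere-surface sampling `E[r²] = 2R²/3` about the center, and
  isotropic Gaussian localization noise of sd σ per axis adds 2σ², so

      R̂² = 1.5 · max(0, m2 − 2σ²),  D̂ = 2·R̂,

  with m2 the mean squared distance of member localizations from the
  cluster centroid. The estimator returns 0 when the noise correction
  exceeds the observed spread. σ comes from the per-localization `sigma`
  column when present, else the ROI median sigma, else the configured
  default (12 nm). The estimator is exact for the forward model and
  recovers a log-normal diameter population (median 80 nm) with <5% bias on
  the cohort mean at 500 vesicles; whether the original experiments applied
  a comparable precision correction is not stated, so absolute diameter
  comparisons to published values are treated as range checks only.

## Counting and contribution estimators

Per-ROI cluster counts are divided by the incubated raw biofluid volume
(EV/μL); cohort statistics are the mean, median, SEM (sample sd/√n) and CV
(sample sd/mean) over ROIs. Contribution fractions are **ratios of cohort
means**, not means of per-ROI ratios — matching how the published tables
are divided (e.g. 0.8/517) and avoiding instability when a per-ROI
denominator is small:

* stain-based  f = mean(reference-capture, tracer-stain) / mean(reference-capture, panel-stain)
* capture-based f = mean(tracer-capture, panel-stain) / mean(reference-capture, panel-stain)

Background is the identical ratio measured in a tracer-negative control
animal; the corrected fraction is `max(0, f − f_background)`, and both raw
and corrected values are always reported. Uncertainty is a seeded
nonparametric bootstrap (default 2000 resamples) over ROIs, all cohorts
resampled independently, percentile 95% interval. Group comparisons of
diameters or marker counts use a natural-log transform (right-skewed
distributions; zeros excluded with a logged count), Welch's t-test for two
groups and one-way ANOVA for more.

The identity `n = (cv · mean / sem)²` is exposed as a consistency check on
tabulated cohort statistics; on the reference plasma cohort it returns
≈20.5, consistent with a ~20-ROI design.

## The forward simulator

The synthetic module generates the full assay with ground truth so every
stage is validated by parameter recovery rather than against unavailable
raw data. Defaults define the simulated study conditions and were fixed
once:

| parameter | default | rationale |
|---|---|---|
| diameter law | log-normal, median 80 nm, log-sd 0.3 | exosome size range, CV ≈ 0.3 as in published per-vesicle histograms |
| copy scaling | ∝ (d/80 nm)² | surface proteins scale with membrane area |
| mean copies at 80 nm | 7 per mouse tetraspanin, 20 HsCD81 | with labeling 0.7 gives ~14–15 detected markers/EV on the 3-antibody mouse panel and ~14 on the single anti-HsCD81 stain, matching the reported 9–18 range; a single per-species mean cannot fit both panel and single-stain averages, so the tracer mean is set separately |
| tracer copies | zero-truncated Poisson | tracer-positive ⇔ ≥1 copy, by construction |
| labeling probability | 0.7 | plausible antibody occupancy; not measured in the source experiments |
| capture probability per copy | 0.9 | high-affinity covalent-antibody capture; reference capture efficiency ≈ 1 |
| blink law | geometric on {1,2,…}, mean L = 14 | memoryless blinking, simplest law matching the stated mean |
| localization noise | σ = 10 nm/axis | typical dSTORM precision |
| background | 1 localization/μm² | sparse nonspecific blinking |
| non-specific sticking | 0.5 EV/ROI (plasma), 0.2 (CSF) | reproduces sub-percent control backgrounds |
| ROI | 50 × 50 μm | field size not stated upstream; manifest-supplied for real data |

Scenario presets mirror the two study designs: plasma (tracer fraction
0.15, 20 ROIs, ~200 vesicles/ROI/μL, 1 μL reference vs 5 μL tracer
incubation) and CSF (0.01, 10 ROIs, ~40 vesicles/ROI/μL, 1 vs 6 μL). One
master seed drives everything; each ROI uses an independent derived stream,
so identical configurations yield byte-identical output tables.

What the simulator does *not* emulate: camera-frame formation and fitting
artifacts (multi-emitter fits, drift), epitope accessibility and antibody
steric competition, vesicle aggregation, z-dependent TIRF intensity, and
animal-to-animal variation (each scenario is one virtual animal, as in the
single-animal-per-condition design it mirrors). Passing recovery tests
therefore demonstrate the correctness of the detection/estimation chain
under the stated forward model, not robustness to every real-data artifact.

## Validation summary

Computed by the test suite and `scripts/acceptance.py` at run time:

* published-table ratio arithmetic (stain-based ~11%, capture-based ~17.5%,
  backgrounds 0.15–0.43%) and the 40/14 ≈ 3-marker calibration identity;
* planted tracer fractions recovered within ±0.03 (plasma scale) and ±0.01
  (CSF scale), estimates inside their own bootstrap CIs;
* detection precision and recall ≥ 0.99 on 200 ROIs of planted,
  well-separated vesicles, with no reported cluster under 40 localizations;
* shell diameter 80 ± 2 nm recovered from 10⁴ localizations at σ = 10 nm;
* Voronoi cells partition every ROI to ≤10⁻⁶ relative area defect.

Problem sizes for the recovery runs follow the scenario presets above
(~3 × 10⁶ simulated localizations for the plasma scenario); the whole
validation completes in a few minutes on one CPU.

## Known limitations

* The density threshold, annexation and edge-pruning rules are this
  package's concrete choices within the Voronoi-segmentation family; the
  upstream analysis cites its tessellation method without formulas, so
  equivalence is established by parameter recovery, not code comparison.
* Vesicles closer together than roughly the threshold length scale
  (~150–350 nm depending on density) merge into one cluster; at the
  simulated densities this biases counts by ~1% and mostly cancels in
  contribution ratios.
* Diameters assume spherical vesicles and uniformly accessible surface
  epitopes.
* EV/μL is counts per ROI normalized to incubated volume, not an absolute
  concentration; no calibration against nanoparticle tracking analysis is
  attempted.
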