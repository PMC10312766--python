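"""Reference cohort summaries distributed with the package.

These are the published per-condition EV/μL statistics (mean, median, SEM,
CV over ROIs) from the transgenic-mouse capture/stain qSMLM experiments the
pipeline models: a hepatocyte-tracer plasma study, a pan-neuronal-tracer
plasma study, and the matching CSF study. Each test animal expresses the
HsCD81 tracer in the named cell type; controls are tracer-transgene carriers
without Cre activation. They serve as inputs to the ratio estimators (the
raw localization data behind them is not publicly deposited) and as ground
for internal-consistency checks.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .quant import CohortSummary

_REPORTED = """\
study,fluid,cohort,capture,stain,mean,median,sem,cv,volume_raw_ul
hepatocyte,plasma,test,MmCD81,mouse_panel,202,198,5.8,0.13,1
hepatocyte,plasma,test,MmCD81,hCD81,23.0,22.0,1.4,0.28,1
hepatocyte,plasma,test,HsCD81,mouse_panel,35.4,32.4,2.6,0.33,5
hepatocyte,plasma,test,HsCD81,hCD81,4.9,5.1,0.4,0.33,5
hepatocyte,plasma,control,MmCD81,mouse_panel,517,535,19.9,0.17,1
hepatocyte,plasma,control,MmCD81,hCD81,0.7,0.0,0.2,1.16,1
hepatocyte,plasma,control,HsCD81,mouse_panel,0.8,0.7,0.1,0.70,5
hepatocyte,plasma,control,HsCD81,hCD81,0.5,0.3,0.1,1.13,5
neuron,plasma,test,MmCD81,full_panel,259,254,7.1,0.12,1
neuron,plasma,test,HsCD81,full_panel,3.3,3.2,0.2,0.28,5
neuron,plasma,control,MmCD81,full_panel,648,654,29,0.20,1
neuron,plasma,control,HsCD81,full_panel,1.7,1.3,0.2,0.60,5
neuron,csf,test,MmCD81,full_panel,42,43,3.1,0.24,1
neuron,csf,test,HsCD81,full_panel,0.4,0.3,0.1,0.71,6
neuron,csf,control,MmCD81,full_panel,161,156,15,0.29,1
neuron,csf,control,HsCD81,full_panel,0.7,0.7,0.1,0.36,6
"""


def reported_cohort_counts() -> pd.DataFrame:
    """The published EV/μL cohort summaries as a tidy DataFrame."""
    return pd.read_csv(StringIO(_REPORTED))


def reported_summary(
    study: str, fluid: str, cohort: str, capture: str, stain: str
) -> CohortSummary:
    """Look up one published condition as a :class:`CohortSummary`."""
    df = reported_cohort_counts()
    row = df[
        (df["study"] == study)
        & (df["fluid"] == fluid)
        & (df["cohort"] == cohort)
        & (df["capture"] == capture)
        & (df["stain"] == stain)
    ]
    if len(row) != 1:
        raise KeyError(f"no unique condition {study}/{fluid}/{cohort}/{capture}/{stain}")
    r = row.iloc[0]
    return CohortSummary.from_stats(
        condition=f"{study}:{fluid}:{cohort}:{capture}:{stain}",
        mean=float(r["mean"]),
        median=float(r["median"]),
        sem=float(r["sem"]),
        cv=float(r["cv"]),
    )
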