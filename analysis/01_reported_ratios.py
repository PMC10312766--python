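#!/usr/bin/env python
"""Cell-type contribution fractions from the published cohort tables.

Computes the stain-based and capture-based hepatocyte contributions to
plasma exosomes, the neuronal contributions to plasma and CSF exosomes,
and their control backgrounds, from the bundled per-condition EV/μL means.
Writes results/reported_contributions.csv.
"""

from pathlib import Path

import pandas as pd

from evmap.datasets import reported_summary
from evmap.quant import contribution_capture, contribution_stain

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    hep = lambda cohort, cap, stain: reported_summary("hepatocyte", "plasma", cohort, cap, stain)
    neu = lambda fluid, cohort, cap: reported_summary("neuron", fluid, cohort, cap, "full_panel")

    rows = [
        {
            "quantity": "hepatocyte contribution to plasma exosomes (stain-based)",
            "fraction": contribution_stain(hep("test", "MmCD81", "hCD81"),
                                           hep("test", "MmCD81", "mouse_panel")),
        },
        {
            "quantity": "hepatocyte contribution to plasma exosomes (capture-based)",
            "fraction": contribution_capture(hep("test", "HsCD81", "mouse_panel"),
                                             hep("test", "MmCD81", "mouse_panel")),
        },
        {
            "quantity": "hepatocyte assay background (control animal)",
            "fraction": contribution_capture(hep("control", "HsCD81", "mouse_panel"),
                                             hep("control", "MmCD81", "mouse_panel")),
        },
        {
            "quantity": "neuronal contribution to plasma exosomes (capture-based)",
            "fraction": contribution_capture(neu("plasma", "test", "HsCD81"),
                                             neu("plasma", "test", "MmCD81")),
        },
        {
            "quantity": "neuronal plasma background (control animal)",
            "fraction": contribution_capture(neu("plasma", "control", "HsCD81"),
                                             neu("plasma", "control", "MmCD81")),
        },
        {
            "quantity": "neuronal contribution to CSF exosomes (capture-based)",
            "fraction": contribution_capture(neu("csf", "test", "HsCD81"),
                                             neu("csf", "test", "MmCD81")),
        },
        {
            "quantity": "neuronal CSF background (control animal)",
            "fraction": contribution_capture(neu("csf", "control", "HsCD81"),
                                             neu("csf", "control", "MmCD81")),
        },
    ]
    df = pd.DataFrame(rows)
    df["percent"] = (100 * df["fraction"]).round(2)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "reported_contributions.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nHepatocytes account for ~11% (stain-based) to ~18% (capture-based) of"
        "\nplasma exosomes over a ~0.2% assay background; neurons account for"
        "\n~1.3% of plasma and ~1.0% of CSF exosomes over ~0.3-0.4% backgrounds."
    )


if __name__ == "__main__":
    main()
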