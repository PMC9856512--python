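"""BH3-profiling priming summary and dose-response potencies.

Normalizes the simulated TMRE readouts to the DMSO/FCCP controls per
condition, summarizes priming per peptide, and refits four-parameter
logistic curves to noise-free viability tables generated at the measured
venetoclax IC50s to confirm parameter recovery; AUCs summarize each curve.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import venetomics.io as vio
from venetomics.pharmaco import auc_viability, fit_four_pl, summarize_priming
from venetomics.pipeline import DEFAULT_CONFIG
from venetomics.simulate import simulate_dose_response

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    measurements = vio.read_table(SCRATCH / "bh3_measurements.tsv")
    priming = summarize_priming(measurements)
    vio.write_table(priming.round(3), RESULTS / "bh3_priming.tsv")
    wide = priming.pivot_table(
        index=["peptide", "concentration_um"], columns="condition",
        values="mean_depolarization",
    ).round(1)
    print("mean % depolarization (DMSO = 0, FCCP = 100):")
    print(wide.to_string())

    rows = []
    for entry in DEFAULT_CONFIG["simulation"]["dose_response"]:
        curve = simulate_dose_response(
            ic50=entry["ic50"], hill=entry.get("hill", 1.0),
            doses=np.logspace(-3, 2, 9),
        )
        fit = fit_four_pl(curve["dose"], curve["response"])
        rows.append(
            {
                "label": entry["label"],
                "true_ic50_um": entry["ic50"],
                "fit_ic50_um": round(fit.ic50, 4),
                "hill": round(fit.hill, 3),
                "auc": round(auc_viability(curve["dose"], curve["response"]), 4),
            }
        )
    table = pd.DataFrame(rows)
    vio.write_table(table, RESULTS / "dose_response.tsv")
    print("\ndose-response refits:")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
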