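"""Differential expression between resistant and parental replicates.

Runs the NB Wald stand-in on the simulated counts (median-of-ratios
normalization, pooled moment dispersion, BH adjustment, |log2FC| > 1 and
p_adj < 0.05) and compares the calls to the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

import venetomics.io as vio
from venetomics.transcriptome import run_de

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    counts = vio.read_matrix(SCRATCH / "counts.tsv")
    groups = pd.read_csv(SCRATCH / "groups.tsv", sep="\t", index_col=0).iloc[:, 0]
    de = run_de(counts, groups)
    vio.write_matrix(de, SCRATCH / "de_results.tsv")

    # reload the gene-level truth table serialized by the simulator
    truth_genes = pd.DataFrame(
        json.loads((SCRATCH / "truth_genes.json").read_text())["genes"]["data"]
    ).set_index("gene")

    n_up = int((de["label"] == "up").sum())
    n_down = int((de["label"] == "down").sum())
    planted = truth_genes["de_direction"] != "none"
    recall = (de.loc[truth_genes.index[planted], "label"]
              == truth_genes.loc[planted, "de_direction"]).mean()
    summary = {"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down,
               "planted_recall": round(float(recall), 4)}
    (RESULTS / "de_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"DE calls: {n_up} up, {n_down} down, {n_up + n_down} total "
          f"(planted recall {recall:.1%})")


if __name__ == "__main__":
    main()
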