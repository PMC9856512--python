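"""Probe QC and accessibility/methylation differentials.

Reads the paired β matrices from scratch/cohort/, removes SNP-overlapping,
cross-reactive, sex-chromosome and detection-failing probes, computes
per-probe ΔAcc/ΔMeth between resistant and parental groups, flags
|Δ| ≥ 0.15, and writes the per-probe differential table plus a QC report.
"""

import json
from pathlib import Path

import venetomics.io as vio
from venetomics.accessibility import epi_differential
from venetomics.qc import filter_probes

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    sssi = vio.read_matrix(SCRATCH / "beta_sssi.tsv")
    noe = vio.read_matrix(SCRATCH / "beta_noe.tsv")
    manifest = vio.read_matrix(SCRATCH / "manifest.tsv")
    manifest["gene"] = manifest["gene"].fillna("")
    detection = vio.read_matrix(SCRATCH / "detection.tsv")

    sssi_f, noe_f, qc = filter_probes(sssi, noe, manifest, detection)
    group_a = [s for s in sssi.columns if s.startswith("parental")]
    group_b = [s for s in sssi.columns if s.startswith("resistant")]
    diff = epi_differential(sssi_f, noe_f, group_a, group_b)

    vio.write_matrix(diff.table, SCRATCH / "epi_differential.tsv")
    (RESULTS / "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=2) + "\n")

    n_acc = int(diff.table["sig_acc"].sum())
    n_meth = int(diff.table["sig_meth"].sum())
    print(f"QC: retained {qc.n_retained}/{qc.n_input} probes "
          f"(snp {qc.removed_snp}, cross-reactive {qc.removed_crossreactive}, "
          f"sex {qc.removed_sex_chromosome}, detection {qc.removed_detection})")
    print(f"significant probes at |delta| >= 0.15: {n_acc} accessibility, {n_meth} methylation")
    print(diff.table["direction"].value_counts().to_string())


if __name__ == "__main__":
    main()
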