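"""Acquired-variant filter cascade on the simulated VCFs.

Subtracts parental/long-term background, keeps gnomAD-rare (< 0.001) and
HIGH-impact variants, and intersects the two resistant lines' survivors.
"""

import json
from pathlib import Path

from venetomics.variants import read_vcf, run_cascade, write_vcf

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    recs = {
        name: read_vcf(SCRATCH / f"{name}.vcf")
        for name in ("vr_a", "vr_b", "parental_a", "longterm_a", "parental_b", "longterm_b")
    }
    shared, report = run_cascade(
        recs["vr_a"], recs["vr_b"], recs["parental_a"], recs["longterm_a"],
        recs["parental_b"], recs["longterm_b"],
    )
    write_vcf(shared, SCRATCH / "shared_pass.vcf")
    (RESULTS / "cascade_report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")

    print(f"input: {report.input_a} (line A), {report.input_b} (line B)")
    print(f"after background subtraction: {report.after_background_a} / {report.after_background_b}")
    print(f"after gnomAD < 0.001:         {report.after_af_a} / {report.after_af_b}")
    print(f"after HIGH impact:            {report.after_impact_a} / {report.after_impact_b}")
    print(f"shared by both resistant lines: {report.n_shared}")


if __name__ == "__main__":
    main()
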