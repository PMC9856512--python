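"""Probe exclusion rules for paired methylation-array β matrices.

Before any differential computation, probes are removed when they overlap
a SNP, are cross-reactive, sit on a sex chromosome, or fail detection
(detection p-value above the threshold) in any sample.  A probe may fail
several rules; it is removed once but counted under each rule it fails.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .exceptions import InputError

SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})


@dataclass
class QcReport:
    n_input: int
    removed_snp: int
    removed_crossreactive: int
    removed_sex_chromosome: int
    removed_detection: int
    n_removed: int  # size of the union of failing probes
    n_retained: int

    def to_dict(self) -> dict:
        return asdict(self)


def filter_probes(
    beta_sssi: pd.DataFrame,
    beta_noe: pd.DataFrame,
    manifest: pd.DataFrame,
    detection: pd.DataFrame,
    detection_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, QcReport]:
    """Apply the four exclusion rules; return filtered arms and a report.

    Detection failure is "p strictly above threshold" in *any* sample
    (minfi-style conservative convention); a probe at exactly the
    threshold is retained.
    """
    if not 0.0 < detection_threshold < 1.0:
        raise InputError(f"detection_threshold {detection_threshold} outside (0, 1)")
    probes = beta_sssi.index
    for name, other in (
        ("beta_noe", beta_noe.index),
        ("manifest", manifest.index),
        ("detection", detection.index),
    ):
        if not probes.equals(other):
            if set(probes) == set(other):
                raise InputError(f"{name} probes are ordered differently")
            raise InputError(f"{name} probe identifiers do not match the SssI arm")

    snp = manifest["snp_flag"].astype(bool)
    xreact = manifest["crossreactive_flag"].astype(bool)
    sex = manifest["chromosome"].isin(SEX_CHROMOSOMES)
    det_fail = (detection > detection_threshold).any(axis=1)

    failing = snp | xreact | sex | det_fail
    retained = ~failing

    report = QcReport(
        n_input=len(probes),
        removed_snp=int(snp.sum()),
        removed_crossreactive=int(xreact.sum()),
        removed_sex_chromosome=int(sex.sum()),
        removed_detection=int(det_fail.sum()),
        n_removed=int(failing.sum()),
        n_retained=int(retained.sum()),
    )
    return beta_sssi.loc[retained], beta_noe.loc[retained], report
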