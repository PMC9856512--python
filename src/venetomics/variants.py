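"""Acquired-variant filter cascade.

Somatic variant calls from a resistant sample are reduced to candidate
resistance drivers in four steps: (1) subtract background variants seen
in the matched parental and long-term-cultured controls, (2) keep only
variants rare in the population (gnomAD allele frequency strictly below
0.001; a missing frequency is treated as novel and kept), (3) keep only
variants with a HIGH predicted impact (a missing impact cannot be
certified and is removed), and (4) intersect the survivors of the two
independently derived resistant lines.

Variant identity is allele-exact: (chromosome, position, ref, alt) after
multi-allelic splitting and left-trimming of shared allele context.
Genotype and zygosity are ignored — presence in a sample's table is
membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import InputError

AF_THRESHOLD = 0.001
IMPACT_LEVELS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    gnomad_af: float | None = None  # None = absent from the population database
    impact: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


def normalize_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a single ref/alt pair: trim shared suffix, then shared
    prefix (keeping at least one base each), adjusting the position."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def _keys(variants: Iterable[VariantRecord]) -> set[tuple]:
    return {v.key for v in variants}


def subtract_background(
    vr: Iterable[VariantRecord],
    parental: Iterable[VariantRecord],
    longterm: Iterable[VariantRecord],
    mode: str = "union",
) -> list[VariantRecord]:
    """Remove control-sample variants from a resistant sample's set.

    ``mode="union"`` (default) removes a variant present in either
    control; ``mode="intersection"`` removes only variants present in
    both controls.
    """
    pk, lk = _keys(parental), _keys(longterm)
    if mode == "union":
        background = pk | lk
    elif mode == "intersection":
        background = pk & lk
    else:
        raise InputError(f"unknown background mode {mode!r}")
    return [v for v in vr if v.key not in background]


def filter_af(
    variants: Iterable[VariantRecord], af_threshold: float = AF_THRESHOLD
) -> list[VariantRecord]:
    """Keep population-rare variants: AF strictly below the threshold, or
    absent from the population database (treated as novel)."""
    if not 0.0 < af_threshold < 1.0:
        raise InputError("af_threshold must lie in (0, 1)")
    kept = []
    for v in variants:
        af = v.gnomad_af
        if af is not None and not (isinstance(af, float) and math.isnan(af)):
            if af < 0:
                raise InputError(f"negative allele frequency on {v.key}")
            if af >= af_threshold:
                continue
        kept.append(v)
    return kept


def filter_impact(
    variants: Iterable[VariantRecord], required: str = "HIGH"
) -> list[VariantRecord]:
    """Keep variants with the required predicted impact; a missing impact
    cannot be certified and is removed."""
    if required not in IMPACT_LEVELS:
        raise InputError(f"unknown impact class {required!r}")
    kept = []
    for v in variants:
        if v.impact is not None and v.impact not in IMPACT_LEVELS:
            raise InputError(f"unknown impact label {v.impact!r} on {v.key}")
        if v.impact == required:
            kept.append(v)
    return kept


def shared_variants(
    vr_a: Iterable[VariantRecord], vr_b: Iterable[VariantRecord]
) -> list[VariantRecord]:
    """Allele-exact intersection of two post-cascade sets (records taken
    from the first set), sorted by key."""
    keys_b = _keys(vr_b)
    return sorted((v for v in vr_a if v.key in keys_b), key=lambda v: v.key)


@dataclass
class CascadeReport:
    input_a: int
    input_b: int
    after_background_a: int
    after_background_b: int
    after_af_a: int
    after_af_b: int
    after_impact_a: int
    after_impact_b: int
    n_shared: int

    def to_dict(self) -> dict:
        return asdict(self)


def run_cascade(
    vr_a: Iterable[VariantRecord],
    vr_b: Iterable[VariantRecord],
    parental_a: Iterable[VariantRecord],
    longterm_a: Iterable[VariantRecord],
    parental_b: Iterable[VariantRecord],
    longterm_b: Iterable[VariantRecord],
    af_threshold: float = AF_THRESHOLD,
    required_impact: str = "HIGH",
    background_mode: str = "union",
) -> tuple[list[VariantRecord], CascadeReport]:
    """Full filter cascade for a pair of resistant lines."""
    vr_a, vr_b = list(vr_a), list(vr_b)
    a1 = subtract_background(vr_a, parental_a, longterm_a, background_mode)
    b1 = subtract_background(vr_b, parental_b, longterm_b, background_mode)
    a2, b2 = filter_af(a1, af_threshold), filter_af(b1, af_threshold)
    a3, b3 = filter_impact(a2, required_impact), filter_impact(b2, required_impact)
    shared = shared_variants(a3, b3)
    report = CascadeReport(
        input_a=len(vr_a),
        input_b=len(vr_b),
        after_background_a=len(a1),
        after_background_b=len(b1),
        after_af_a=len(a2),
        after_af_b=len(b2),
        after_impact_a=len(a3),
        after_impact_b=len(b3),
        n_shared=len(shared),
    )
    return shared, report


# ---------------------------------------------------------------------------
# table / VCF interchange
# ---------------------------------------------------------------------------


def records_from_table(table: pd.DataFrame) -> list[VariantRecord]:
    """Build normalized records from a variant table (columns: chromosome,
    position, ref, alt, optional gnomad_af and impact)."""
    records = []
    for row in table.itertuples(index=False):
        af = getattr(row, "gnomad_af", None)
        if af is not None and isinstance(af, float) and math.isnan(af):
            af = None
        impact = getattr(row, "impact", None)
        if impact is not None and (not isinstance(impact, str) or impact == ""):
            impact = None
        pos, ref, alt = normalize_alleles(int(row.position), str(row.ref), str(row.alt))
        records.append(
            VariantRecord(str(row.chromosome), pos, ref, alt, af, impact)
        )
    return records


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GNOMAD_AF,Number=A,Type=Float,Description="Population allele frequency">
##INFO=<ID=IMPACT,Number=A,Type=String,Description="Predicted consequence impact">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as minimal VCFv4.2 with GNOMAD_AF / IMPACT INFO keys."""
    lines = [VCF_HEADER.rstrip("\n")]
    for v in sorted(variants, key=lambda v: v.key):
        info = []
        if v.gnomad_af is not None:
            info.append(f"GNOMAD_AF={v.gnomad_af:.6g}")
        if v.impact is not None:
            info.append(f"IMPACT={v.impact}")
        lines.append(
            "\t".join(
                [
                    v.chromosome,
                    str(v.position),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    "PASS",
                    ";".join(info) or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(
    path: str | Path, af_key: str = "GNOMAD_AF", impact_key: str = "IMPACT"
) -> list[VariantRecord]:
    """Read a VCF into normalized records, splitting multi-allelic rows.

    Per-allele INFO values (Number=A) are matched to the split alleles by
    position; scalar values are shared across alleles.
    """
    records = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise InputError(f"malformed VCF line: {line[:80]!r}")
        chrom, pos, _, ref, alt_field, _, _, info_field = fields[:8]
        info = {}
        if info_field != ".":
            for item in info_field.split(";"):
                if "=" in item:
                    k, val = item.split("=", 1)
                    info[k] = val
        alts = alt_field.split(",")
        afs = info.get(af_key, "").split(",") if af_key in info else [None] * len(alts)
        impacts = (
            info.get(impact_key, "").split(",") if impact_key in info else [None] * len(alts)
        )
        if len(afs) == 1 and len(alts) > 1:
            afs = afs * len(alts)
        if len(impacts) == 1 and len(alts) > 1:
            impacts = impacts * len(alts)
        for alt, af, impact in zip(alts, afs, impacts):
            npos, nref, nalt = normalize_alleles(int(pos), ref, alt)
            af_val = None if af in (None, ".", "") else float(af)
            impact_val = None if impact in (None, ".", "") else impact
            records.append(VariantRecord(chrom, npos, nref, nalt, af_val, impact_val))
    return records
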