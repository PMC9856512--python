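"""Build the synthetic resistance cohort every later step analyses.

Plants the study-sized effect structure: 923 up- and 990 down-regulated
genes among 20,000 (with 39%/46% of them given concordant promoter
changes), paired SssI/NoE β matrices for 3 sensitive + 3 resistant
replicates, per-sample variant tables with 21 shared cascade survivors,
and a BH3-profiling readout with reduced priming in the resistant
condition.  All cohort data (matrices and truth tables) go to
scratch/cohort/; later steps write their summaries to results/.
"""

from pathlib import Path

import venetomics.io as vio
from venetomics.pipeline import DEFAULT_CONFIG, _parse_bh3_conditions
from venetomics.simulate import (
    Bh3SimConfig,
    EpiSimConfig,
    RnaSimConfig,
    VariantSimConfig,
    promoter_plan_from_truth,
    simulate_bh3,
    simulate_counts,
    simulate_epigenome,
    simulate_variants,
)
from venetomics.variants import records_from_table, write_vcf

SEED = 42
SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    sim = DEFAULT_CONFIG["simulation"]

    rna = simulate_counts(RnaSimConfig(seed=SEED, **sim["rna"]))
    vio.write_matrix(rna.counts, SCRATCH / "counts.tsv")
    rna.groups.to_csv(SCRATCH / "groups.tsv", sep="\t")
    rna.truth.save(SCRATCH / "truth_genes.json")

    plan = promoter_plan_from_truth(rna.truth)
    epi_params = dict(sim["epi"])
    n_bg = epi_params.pop("n_background_probes")
    epi = simulate_epigenome(
        EpiSimConfig(
            n_probes=len(plan) * 2 + n_bg, n_promoter_genes=len(plan),
            groups={"parental": 3, "resistant": 3}, affected_group="resistant",
            seed=SEED + 1, **epi_params,
        ),
        promoter_plan=plan,
    )
    for name in ("beta_sssi", "beta_noe", "detection", "manifest"):
        vio.write_matrix(getattr(epi, name), SCRATCH / f"{name}.tsv")

    var = simulate_variants(VariantSimConfig(seed=SEED + 2, **sim["variants"]))
    for sample, table in var.tables.items():
        write_vcf(records_from_table(table), SCRATCH / f"{sample}.vcf")
    var.truth.save(SCRATCH / "truth_variants.json")

    bh3_params = dict(sim["bh3"])
    conditions = _parse_bh3_conditions(bh3_params.pop("conditions"))
    bh3 = simulate_bh3(Bh3SimConfig(true_depolarization=conditions, seed=SEED + 3, **bh3_params))
    vio.write_table(bh3.measurements, SCRATCH / "bh3_measurements.tsv")

    planted_up = (rna.truth.genes["de_direction"] == "up").sum()
    planted_down = (rna.truth.genes["de_direction"] == "down").sum()
    print(f"cohort written under {SCRATCH}/ (seed {SEED})")
    print(f"planted DE genes: {planted_up} up, {planted_down} down of {len(rna.truth.genes)}")
    print(f"promoter plan covers {len(plan)} genes; probes simulated: {len(epi.manifest)}")
    print(f"planted shared cascade survivors: "
          f"{(var.truth.variants['planted_class'] == 'shared_pass').sum()}")


if __name__ == "__main__":
    main()
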