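"""Promoter-level integration of epigenetic and expression changes.

Promoter probes are aggregated per gene into an up/down/ambiguous/none
call, intersected with the differential-expression gene sets (reported
as Venn counts and percentages of the DE sets), and gene lists are
tested for over-representation against user-supplied GMT collections
with an upper-tail hypergeometric test, BH-adjusted jointly across all
sets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .transcriptome import bh_adjust

ENRICH_ALPHA = 0.01


def classify_promoters(probe_calls: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-gene promoter direction from member-probe directions.

    A gene is "up" when at least one of its promoter probes is up and
    none is down, "down" in the mirror case, "ambiguous" when both are
    present (an ambiguous probe alone also makes the gene ambiguous),
    and "none" otherwise.  Genes without promoter probes are omitted.
    """
    prom = manifest[manifest["promoter_region"].astype(bool) & (manifest["gene"] != "")]
    joined = prom[["gene"]].join(probe_calls[["direction"]], how="inner")
    if joined.empty:
        return pd.DataFrame(columns=["n_probes", "direction"]).rename_axis("gene")

    grouped = joined.groupby("gene")["direction"]
    n_probes = grouped.size()
    has_up = grouped.apply(lambda s: bool((s == "up").any() or (s == "ambiguous").any()))
    has_down = grouped.apply(lambda s: bool((s == "down").any() or (s == "ambiguous").any()))
    direction = np.where(
        has_up & has_down, "ambiguous", np.where(has_up, "up", np.where(has_down, "down", "none"))
    )
    return pd.DataFrame({"n_probes": n_probes, "direction": direction}).rename_axis("gene")


@dataclass
class OverlapResult:
    """Venn counts between epigenetic promoter calls and DE gene sets.

    Percentages are of the DE set: pct_up = 100 * |both up| / |DE up|,
    None when the DE set is empty.
    """

    n_epi_up: int
    n_rna_up: int
    n_both_up: int
    pct_up: float | None
    n_epi_down: int
    n_rna_down: int
    n_both_down: int
    pct_down: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_stats(promoter_calls: pd.DataFrame, de_calls: pd.DataFrame) -> OverlapResult:
    """Overlap of promoter up/down genes with DE up/down genes.

    ``promoter_calls`` is the classify_promoters output; ``de_calls`` the
    DE result table with a "label" column.  Ambiguous promoters count as
    neither direction.
    """
    epi_up = set(promoter_calls.index[promoter_calls["direction"] == "up"])
    epi_down = set(promoter_calls.index[promoter_calls["direction"] == "down"])
    rna_up = set(de_calls.index[de_calls["label"] == "up"])
    rna_down = set(de_calls.index[de_calls["label"] == "down"])

    both_up = epi_up & rna_up
    both_down = epi_down & rna_down
    return OverlapResult(
        n_epi_up=len(epi_up),
        n_rna_up=len(rna_up),
        n_both_up=len(both_up),
        pct_up=100.0 * len(both_up) / len(rna_up) if rna_up else None,
        n_epi_down=len(epi_down),
        n_rna_down=len(rna_down),
        n_both_down=len(both_down),
        pct_down=100.0 * len(both_down) / len(rna_down) if rna_down else None,
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT collection: name <tab> description <tab> genes..."""
    collections: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed GMT line: {line[:80]!r}")
        collections[parts[0]] = set(parts[2:])
    return collections


def write_gmt(collections: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)]) for name, genes in collections.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ora_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    alpha: float = ENRICH_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; the upper-tail
    p-value is the probability of an overlap at least as large under
    sampling |query| genes from the universe without replacement.  BH is
    applied jointly across all tested sets.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    query = set(query)
    if not query <= universe:
        raise InputError("query must be a subset of the universe")

    rows = []
    for name, members in collections.items():
        members = set(members) & universe
        overlap = len(members & query)
        # P(X >= overlap), X ~ Hypergeom(M=|universe|, K=|set|, N=|query|)
        p = stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query))
        rows.append((name, len(members), overlap, min(float(p), 1.0)))
    result = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap_size", "p_raw"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p_raw"])
    else:
        result["p_adj"] = pd.Series(dtype=float)
    result["significant"] = result["p_adj"] < alpha
    return result.set_index("set_name")


def overlap_pathway_intersection(
    enrichments_a: pd.DataFrame, enrichments_b: pd.DataFrame
) -> list[str]:
    """Names of sets significant in both enrichment tables, sorted."""
    sig_a = set(enrichments_a.index[enrichments_a["significant"]])
    sig_b = set(enrichments_b.index[enrichments_b["significant"]])
    return sorted(sig_a & sig_b)
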