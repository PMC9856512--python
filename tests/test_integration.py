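"""Promoter aggregation, DE overlap percentages and hypergeometric ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from venetomics.exceptions import InputError
from venetomics.integration import (
    classify_promoters,
    ora_enrichment,
    overlap_pathway_intersection,
    overlap_stats,
    read_gmt,
    write_gmt,
)


def _promoter_tables(gene_probe_directions):
    """Build probe_calls + manifest from {gene: [probe directions]}."""
    rows, calls = [], []
    i = 0
    for gene, directions in gene_probe_directions.items():
        for d in directions:
            pid = f"cg{i:04d}"
            rows.append((pid, "chr1", gene, True, False, False))
            calls.append((pid, d))
            i += 1
    manifest = pd.DataFrame(
        rows,
        columns=["probe_id", "chromosome", "gene", "promoter_region", "snp_flag", "crossreactive_flag"],
    ).set_index("probe_id")
    probe_calls = pd.DataFrame(calls, columns=["probe_id", "direction"]).set_index("probe_id")
    return probe_calls, manifest


class TestClassifyPromoters:
    @pytest.mark.parametrize(
        "directions,expected",
        [
            (["up", "none"], "up"),
            (["up", "down"], "ambiguous"),
            (["none", "none"], "none"),
            (["down"], "down"),
            (["ambiguous"], "ambiguous"),
        ],
    )
    def test_examples(self, directions, expected):
        calls, manifest = _promoter_tables({"g": directions})
        result = classify_promoters(calls, manifest)
        assert result.loc["g", "direction"] == expected

    def test_full_enumeration_of_probe_multisets(self):
        labels = ["up", "down", "ambiguous", "none"]
        for size in (1, 2, 3):
            for combo in itertools.combinations_with_replacement(labels, size):
                calls, manifest = _promoter_tables({"g": list(combo)})
                got = classify_promoters(calls, manifest).loc["g", "direction"]
                has_up = "up" in combo or "ambiguous" in combo
                has_down = "down" in combo or "ambiguous" in combo
                expected = (
                    "ambiguous" if has_up and has_down
                    else "up" if has_up
                    else "down" if has_down
                    else "none"
                )
                assert got == expected, combo

    def test_probe_order_invariance_and_sign_flip(self):
        layout = {"g1": ["up", "none"], "g2": ["down", "down"], "g3": ["none"]}
        calls, manifest = _promoter_tables(layout)
        shuffled = calls.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(
            classify_promoters(calls, manifest).sort_index(),
            classify_promoters(shuffled, manifest).sort_index(),
        )
        flipped = calls.replace({"up": "down", "down": "up"})
        fwd = classify_promoters(calls, manifest)["direction"]
        rev = classify_promoters(flipped, manifest)["direction"]
        assert (fwd.map({"up": "down", "down": "up", "ambiguous": "ambiguous", "none": "none"}) == rev).all()

    def test_genes_without_promoter_probes_omitted(self):
        calls, manifest = _promoter_tables({"g": ["up"]})
        manifest.loc[:, "promoter_region"] = False
        assert classify_promoters(calls, manifest).empty


class TestOverlapStats:
    @staticmethod
    def _de(up, down, ns=()):
        frames = [(g, "up") for g in up] + [(g, "down") for g in down] + [(g, "ns") for g in ns]
        return pd.DataFrame(frames, columns=["gene", "label"]).set_index("gene")

    @staticmethod
    def _prom(up, down):
        frames = [(g, 1, "up") for g in up] + [(g, 1, "down") for g in down]
        return pd.DataFrame(frames, columns=["gene", "n_probes", "direction"]).set_index("gene")

    def test_forty_percent_example(self):
        de = self._de(up=["a", "b", "c", "d", "e"], down=[])
        prom = self._prom(up=["a", "b"], down=[])
        result = overlap_stats(prom, de)
        assert result.pct_up == pytest.approx(40.0)
        assert result.n_both_up == 2 and result.n_rna_up == 5

    def test_disjoint_sets_zero_percent(self):
        result = overlap_stats(self._prom(["x"], ["y"]), self._de(["a"], ["b"]))
        assert result.pct_up == 0.0 and result.pct_down == 0.0

    def test_empty_de_set_reported_missing(self):
        result = overlap_stats(self._prom(["x"], []), self._de([], []))
        assert result.pct_up is None and result.pct_down is None

    def test_gene_relabeling_invariance(self):
        de = self._de(up=["a", "b", "c"], down=["d"])
        prom = self._prom(up=["a", "c"], down=["d"])
        mapping = {g: f"X_{g}" for g in "abcd"}
        de2 = de.rename(index=mapping)
        prom2 = prom.rename(index=mapping)
        assert overlap_stats(prom, de).to_dict() == overlap_stats(prom2, de2).to_dict()


class TestOra:
    def test_closed_form_full_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        collections = {"S": universe[:5]}
        result = ora_enrichment(universe[:5], universe, collections)
        assert result.loc["S", "p_raw"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_expected_overlap_not_significant(self):
        universe = [f"g{i}" for i in range(1000)]
        # query of 100 genes; set of 200 overlaps in exactly the expected 20
        query = universe[:100]
        members = universe[80:280]  # 20 genes shared with the query
        result = ora_enrichment(query, universe, {"S": members})
        assert 0.2 < result.loc["S", "p_raw"] < 0.8
        assert not result.loc["S", "significant"]

    def test_query_equal_universe_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        result = ora_enrichment(universe, universe, {"S": universe[:7]})
        assert result.loc["S", "p_raw"] == pytest.approx(1.0)

    def test_matches_brute_force_tail_enumeration(self):
        rng = np.random.default_rng(30)
        for _ in range(25):
            m = int(rng.integers(5, 26))
            universe = [f"g{i}" for i in range(m)]
            k = int(rng.integers(1, m + 1))
            n = int(rng.integers(1, m + 1))
            members = list(rng.choice(universe, size=k, replace=False))
            query = list(rng.choice(universe, size=n, replace=False))
            observed = len(set(members) & set(query))
            # brute-force hypergeometric upper tail
            tail = sum(
                math.comb(k, x) * math.comb(m - k, n - x) / math.comb(m, n)
                for x in range(observed, min(k, n) + 1)
            )
            result = ora_enrichment(query, universe, {"S": members})
            assert result.loc["S", "p_raw"] == pytest.approx(tail, rel=1e-9)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(InputError):
            ora_enrichment(["zz"], ["a", "b"], {})
        with pytest.raises(InputError):
            ora_enrichment([], [], {})


class TestPathwayIntersection:
    @staticmethod
    def _enrich(sig, nonsig):
        rows = [(s, True) for s in sig] + [(s, False) for s in nonsig]
        return pd.DataFrame(rows, columns=["set_name", "significant"]).set_index("set_name")

    def test_trivial_cases(self):
        a = self._enrich(["P1", "P2"], ["P3"])
        b = self._enrich(["P2", "P3"], ["P1"])
        assert overlap_pathway_intersection(a, b) == ["P2"]
        assert overlap_pathway_intersection(self._enrich(["P1"], []), self._enrich(["P9"], [])) == []

    def test_planted_shared_pathways_recovered(self, tmp_path):
        rng = np.random.default_rng(17)
        universe = [f"g{i:04d}" for i in range(2000)]
        query_a = list(rng.choice(universe, size=200, replace=False))
        query_b = list(rng.choice(universe, size=200, replace=False))
        shared_core = list(set(query_a) & set(query_b))
        collections = {}
        for i in range(3):  # planted: enriched in both queries
            collections[f"SHARED_{i}"] = rng.choice(shared_core, size=min(15, len(shared_core)), replace=False)
        for i in range(3):  # enriched only in query A
            only_a = [g for g in query_a if g not in query_b]
            collections[f"A_ONLY_{i}"] = rng.choice(only_a, size=15, replace=False)
        for i in range(10):  # background sets
            collections[f"NULL_{i}"] = rng.choice(universe, size=30, replace=False)
        gmt = tmp_path / "sets.gmt"
        write_gmt({k: list(v) for k, v in collections.items()}, gmt)
        loaded = read_gmt(gmt)
        enr_a = ora_enrichment(query_a, universe, loaded)
        enr_b = ora_enrichment(query_b, universe, loaded)
        shared = overlap_pathway_intersection(enr_a, enr_b)
        assert shared == ["SHARED_0", "SHARED_1", "SHARED_2"]

    def test_gmt_round_trip(self, tmp_path):
        collections = {"A": ["g1", "g2"], "B": ["g3"]}
        path = tmp_path / "c.gmt"
        write_gmt(collections, path)
        assert {k: sorted(v) for k, v in read_gmt(path).items()} == collections
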