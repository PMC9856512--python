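"""Generator-level checks: planted effects are constructed exactly, noise
behaves as configured, seeds reproduce, and truth tables match the data."""

import numpy as np
import pandas as pd
import pytest

from venetomics.exceptions import ConfigError
from venetomics.simulate import (
    Bh3SimConfig,
    EpiSimConfig,
    RnaSimConfig,
    VariantSimConfig,
    four_pl,
    simulate_bh3,
    simulate_counts,
    simulate_dose_response,
    simulate_epigenome,
    simulate_variants,
)


class TestEpigenome:
    def test_single_planted_probe_noise_free_delta_exact(self):
        cfg = EpiSimConfig(
            n_probes=10,
            n_promoter_genes=0,
            probes_per_promoter=0,
            frac_sig_acc_up=0.1,
            planted_delta=0.3,
            beta_noise_sd=0.0,
            seed=0,
        )
        data = simulate_epigenome(cfg)
        planted = data.truth.probes.query("planted_direction == 'up'")
        assert len(planted) == 1
        probe = planted.index[0]
        acc = data.beta_sssi - data.beta_noe
        delta = acc.loc[probe, ["resistant_1", "resistant_2", "resistant_3"]].mean() - acc.loc[
            probe, ["sensitive_1", "sensitive_2", "sensitive_3"]
        ].mean()
        assert delta == pytest.approx(0.30, abs=1e-12)

    def test_null_config_plants_nothing(self):
        data = simulate_epigenome(EpiSimConfig(n_probes=100, n_promoter_genes=10, seed=1))
        assert (data.truth.probes["planted_direction"] == "none").all()

    def test_mean_planted_delta_recovered_under_noise(self):
        cfg = EpiSimConfig(
            n_probes=10_000,
            frac_sig_acc_up=0.1,
            planted_delta=0.3,
            beta_noise_sd=0.02,
            seed=1,
        )
        data = simulate_epigenome(cfg)
        acc = data.beta_sssi - data.beta_noe
        res = [c for c in acc.columns if c.startswith("resistant")]
        sens = [c for c in acc.columns if c.startswith("sensitive")]
        delta = acc[res].mean(axis=1) - acc[sens].mean(axis=1)
        planted = data.truth.probes["planted_delta_acc"] > 0
        assert delta[planted].mean() == pytest.approx(0.30, abs=0.01)

    def test_flagged_probes_carry_no_planted_signal(self, small_epigenome):
        truth = small_epigenome.truth.probes
        man = small_epigenome.manifest
        flagged = (
            man["snp_flag"] | man["crossreactive_flag"] | man["chromosome"].isin(["chrX", "chrY"])
        )
        assert (truth.loc[flagged, "planted_direction"] == "none").all()

    def test_betas_in_unit_interval_and_ids_consistent(self, small_epigenome):
        for arm in (small_epigenome.beta_sssi, small_epigenome.beta_noe):
            assert ((arm.values >= 0) & (arm.values <= 1)).all()
        assert small_epigenome.manifest.index.equals(small_epigenome.beta_sssi.index)
        assert small_epigenome.truth.probes.index.equals(small_epigenome.manifest.index)

    def test_same_seed_reproduces_different_seed_differs(self):
        cfg = dict(n_probes=200, n_promoter_genes=20, frac_sig_acc_up=0.1, beta_noise_sd=0.05)
        a = simulate_epigenome(EpiSimConfig(seed=7, **cfg))
        b = simulate_epigenome(EpiSimConfig(seed=7, **cfg))
        c = simulate_epigenome(EpiSimConfig(seed=8, **cfg))
        pd.testing.assert_frame_equal(a.beta_sssi, b.beta_sssi)
        assert not a.beta_sssi.equals(c.beta_sssi)

    @pytest.mark.parametrize(
        "bad",
        [
            {"frac_snp": 1.5},
            {"planted_delta": 0.0},
            {"frac_sig_acc_up": 0.6, "frac_sig_meth_up": 0.6},
            {"detection_fail_rate": -0.1},
            {"affected_group": "missing"},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            simulate_epigenome(EpiSimConfig(n_probes=50, n_promoter_genes=5, **bad))

    def test_promoter_plan_probes_survive_flags_and_carry_direction(self):
        plan = {"geneA": "up", "geneB": "down", "geneC": "none"}
        cfg = EpiSimConfig(
            n_probes=100, n_promoter_genes=3, probes_per_promoter=2,
            frac_snp=0.5, beta_noise_sd=0.0, seed=3,
        )
        data = simulate_epigenome(cfg, promoter_plan=plan)
        man = data.manifest
        for gene, direction in plan.items():
            probes = man.index[man["gene"] == gene]
            assert len(probes) == 2
            assert not man.loc[probes, "snp_flag"].any()
            assert (data.truth.probes.loc[probes, "planted_direction"] == direction).all()


class TestCounts:
    def test_poisson_limit_group_means(self):
        cfg = RnaSimConfig(
            n_genes=200, n_up=200, n_down=0, lfc_magnitude=1.0,
            dispersion=1e-13, baseline_mean=100.0, replicates_per_group=50, seed=0,
        )
        rna = simulate_counts(cfg)
        a = rna.counts.loc[:, rna.groups == "parental"].to_numpy().mean()
        b = rna.counts.loc[:, rna.groups == "resistant"].to_numpy().mean()
        assert a == pytest.approx(100, rel=0.02)
        assert b == pytest.approx(200, rel=0.02)

    def test_planted_log_ratio_recovered(self):
        cfg = RnaSimConfig(n_genes=5000, n_up=50, n_down=50, lfc_magnitude=3.0, seed=7)
        rna = simulate_counts(cfg)
        up = rna.truth.genes.query("de_direction == 'up'").index
        a = rna.counts.loc[up, rna.groups == "parental"].to_numpy().mean(axis=1)
        b = rna.counts.loc[up, rna.groups == "resistant"].to_numpy().mean(axis=1)
        assert np.mean(np.log2(b / a)) == pytest.approx(3.0, abs=0.2)

    def test_no_planting_empty_truth_and_integer_counts(self):
        rna = simulate_counts(RnaSimConfig(n_genes=100, seed=5))
        assert (rna.truth.genes["de_direction"] == "none").all()
        mat = rna.counts.to_numpy()
        assert (mat >= 0).all() and np.issubdtype(mat.dtype, np.integer)

    def test_concordance_counts_exact(self):
        cfg = RnaSimConfig(
            n_genes=1000, n_up=100, n_down=200,
            concordance_up=0.39, concordance_down=0.46, seed=9,
        )
        truth = simulate_counts(cfg).truth.genes
        up_conc = truth.query("de_direction == 'up' and concordant_promoter")
        down_conc = truth.query("de_direction == 'down' and concordant_promoter")
        assert len(up_conc) == 39 and len(down_conc) == 92

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ConfigError):
            simulate_counts(RnaSimConfig(n_genes=10, dispersion=0.0))


class TestVariants:
    def test_planted_shared_pass_count(self):
        data = simulate_variants(VariantSimConfig(n_shared_pass=21, n_background=30, seed=1))
        assert (data.truth.variants["planted_class"] == "shared_pass").sum() == 21

    def test_all_zero_yields_empty_tables(self):
        data = simulate_variants(VariantSimConfig(seed=0))
        assert all(t.empty for t in data.tables.values())
        assert data.truth.variants.empty

    def test_emitted_tables_satisfy_set_arithmetic_oracle(self):
        # brute-force set operations on the emitted tables, independent of
        # the cascade implementation
        data = simulate_variants(VariantSimConfig(n_background=50, n_shared_pass=5, seed=3))
        keys = {
            s: set(map(tuple, t[["chromosome", "position", "ref", "alt"]].to_numpy()))
            for s, t in data.tables.items()
        }
        passing = {}
        for side in ("a", "b"):
            vr = data.tables[f"vr_{side}"]
            rare = vr["gnomad_af"].isna() | (vr["gnomad_af"] < 0.001)
            high = vr["impact"] == "HIGH"
            keyset = set(
                map(tuple, vr.loc[rare & high, ["chromosome", "position", "ref", "alt"]].to_numpy())
            )
            background = keys[f"parental_{side}"] | keys[f"longterm_{side}"]
            passing[side] = keyset - background
        assert len(passing["a"] & passing["b"]) == 5

    def test_planted_classes_membership(self):
        data = simulate_variants(
            VariantSimConfig(
                n_background=10, n_private_fail_af=5, n_private_fail_impact=5,
                n_shared_pass=3, n_private_pass_each=2, seed=4,
            )
        )
        truth = data.truth.variants
        key_cols = ["chromosome", "position", "ref", "alt"]
        vr_a = set(map(tuple, data.tables["vr_a"][key_cols].to_numpy()))
        parental_a = set(map(tuple, data.tables["parental_a"][key_cols].to_numpy()))
        bg = set(map(tuple, truth.loc[truth["planted_class"] == "background", key_cols].to_numpy()))
        shared = set(
            map(tuple, truth.loc[truth["planted_class"] == "shared_pass", key_cols].to_numpy())
        )
        assert bg == parental_a
        assert shared <= vr_a and not (shared & parental_a)


class TestBh3:
    @pytest.mark.parametrize(
        "fraction,expected", [(1.0, 100.0), (0.0, 1000.0), (0.6, 460.0)]
    )
    def test_noise_free_signal_model(self, fraction, expected):
        cfg = Bh3SimConfig(
            true_depolarization={"cond": {("BIM", 1.0): fraction}},
            dmso_level=1000.0, fccp_level=100.0, noise_sd=0.0, replicates=1, seed=0,
        )
        data = simulate_bh3(cfg)
        signal = data.measurements.query("peptide == 'BIM'")["tmre_signal"].iloc[0]
        assert signal == pytest.approx(expected)

    def test_control_inversion_rejected(self):
        with pytest.raises(ConfigError):
            simulate_bh3(Bh3SimConfig(dmso_level=100.0, fccp_level=1000.0))

    def test_fraction_outside_unit_interval_rejected(self):
        cfg = Bh3SimConfig(true_depolarization={"c": {("BIM", 1.0): 1.4}})
        with pytest.raises(ConfigError):
            simulate_bh3(cfg)


class TestDoseResponse:
    def test_midpoint_at_ic50(self):
        table = simulate_dose_response(ic50=0.5, top=100, bottom=0, doses=[0.1, 0.5, 1, 5])
        assert table.set_index("dose").loc[0.5, "response"] == pytest.approx(50.0)

    def test_steep_hill_approaches_step(self):
        resp = four_pl(np.array([0.09, 0.11]), 100.0, 0.0, 0.1, 200.0)
        assert resp[0] > 99.9 and resp[1] < 0.1

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigError):
            simulate_dose_response(ic50=-1.0)
        with pytest.raises(ConfigError):
            simulate_dose_response(ic50=1.0, doses=[0.0, 1.0, 2.0, 3.0])
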