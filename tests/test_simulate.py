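import numpy as np
import pandas as pd
import pytest

from oxbstools import annotate, simulate
from oxbstools.config import ConfigError, SimConfig
from oxbstools.io import ELEMENT_CLASSES


class TestGenerateGenome:
    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="base_5mc"):
            SimConfig(base_5mc=1.4).validate()
        with pytest.raises(ConfigError, match="group_sizes"):
            SimConfig(group_sizes=(0, 3)).validate()
        with pytest.raises(ConfigError, match="dmr_size_cpgs"):
            SimConfig(dmr_size_cpgs=(2, 10)).validate()

    def test_degenerate_empty_genome(self):
        cpgs, elements, genes = simulate.generate_genome(
            SimConfig(n_chrom=1, cpgs_per_chrom=0))
        assert cpgs.empty

    def test_count_conservation(self):
        cpgs, _, _ = simulate.generate_genome(
            SimConfig(n_chrom=2, cpgs_per_chrom=1000))
        assert len(cpgs) == 2000
        assert cpgs["chrom"].nunique() == 2

    def test_positions_strictly_increasing(self, small_dataset):
        per_chrom = small_dataset.cpg_map.groupby("chrom")["pos"]
        assert per_chrom.apply(lambda s: (np.diff(s) > 0).all()).all()

    def test_every_element_class_with_closest_gene(self, small_dataset):
        elements = small_dataset.elements
        assert set(elements["element_class"]) == set(ELEMENT_CLASSES)
        assert elements["gene_id"].notna().all()
        assert (elements["start"] < elements["end"]).all()

    def test_determinism(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=500, seed=1,
                        n_dmrs_5mc=2, n_dmrs_5hmc=2)
        a = simulate.simulate_dataset(cfg)
        b = simulate.simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.cpg_map, b.cpg_map)
        pd.testing.assert_frame_equal(a.truth.sites, b.truth.sites)
        pd.testing.assert_frame_equal(a.reports["WT1_BS"], b.reports["WT1_BS"])
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestGenerateTruth:
    def test_no_dmrs_identical_groups(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=2000, n_dmrs_5mc=0,
                        n_dmrs_5hmc=0, seed=3)
        ds = simulate.simulate_dataset(cfg)
        s = ds.truth.sites
        np.testing.assert_array_equal(s["control.p_m"], s["case.p_m"])
        np.testing.assert_array_equal(s["control.p_h"], s["case.p_h"])

    def test_injected_effect_exact_and_recorded(self, small_dataset):
        s = small_dataset.truth.sites
        for inj in small_dataset.truth.injected_dmrs.itertuples(index=False):
            sub = s[(s.chrom == inj.chrom) & (s.pos > inj.start)
                    & (s.pos <= inj.end)]
            assert len(sub) == inj.n_cpg
            col = "p_m" if inj.methylation_type == "5mC" else "p_h"
            shift = (sub[f"case.{col}"] - sub[f"control.{col}"]).to_numpy()
            np.testing.assert_allclose(shift, inj.direction * inj.effect,
                                       atol=1e-12)
            other = "p_h" if col == "p_m" else "p_m"
            np.testing.assert_array_equal(sub[f"case.{other}"],
                                          sub[f"control.{other}"])

    def test_dmrs_do_not_overlap(self, small_dataset):
        inj = small_dataset.truth.injected_dmrs
        for chrom, sub in inj.groupby("chrom"):
            sub = sub.sort_values("idx_start")
            assert (sub["idx_start"].to_numpy()[1:]
                    > sub["idx_end"].to_numpy()[:-1]).all()

    def test_triples_on_simplex(self, small_dataset):
        s = small_dataset.truth.sites
        for g in ("control", "case"):
            pm, ph = s[f"{g}.p_m"], s[f"{g}.p_h"]
            assert ((pm >= 0) & (ph >= 0) & (pm + ph <= 1)).all()

    def test_genome_mean_matches_bases_lln(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=20_000, n_dmrs_5mc=0,
                        n_dmrs_5hmc=0, seed=9)
        cpgs, _, _ = simulate.generate_genome(cfg)
        truth = simulate.generate_truth(cfg, cpgs)
        assert truth.sites["control.p_m"].mean() == pytest.approx(
            cfg.base_5mc, abs=0.005)
        assert truth.sites["control.p_h"].mean() == pytest.approx(
            cfg.base_5hmc, abs=0.005)

    def test_impossible_placement_rejected(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=120, n_dmrs_5mc=50,
                        dmr_size_cpgs=(10, 10), seed=0)
        cpgs, _, _ = simulate.generate_genome(cfg)
        with pytest.raises(ValueError, match="without overlap"):
            simulate.generate_truth(cfg, cpgs)


class TestSimulateReads:
    def test_binomial_concentration_at_high_coverage(self):
        """Coverage 10^4, single truth (p_m=0.3, p_h=0.5): BS methylated
        fraction -> 0.8, OxBS -> 0.3 within 3 binomial SDs."""
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=1, mean_coverage=1e4,
                        n_dmrs_5mc=0, n_dmrs_5hmc=0, seed=4)
        truth = simulate.SimTruth(
            sites=pd.DataFrame({"chrom": ["chr1"], "pos": [1000],
                                "control.p_m": [0.3], "control.p_h": [0.5],
                                "case.p_m": [0.3], "case.p_h": [0.5]}),
            injected_dmrs=pd.DataFrame(), expression_model={})
        _, reports = simulate.simulate_reads(truth, cfg)
        for sample_id, q in (("WT1_BS", 0.8), ("WT1_OxBS", 0.3)):
            calls = reports[sample_id]
            frac = calls["meth_count"].sum() / (
                calls["meth_count"] + calls["unmeth_count"]).sum()
            assert abs(frac - q) < 3 * np.sqrt(q * (1 - q) / 1e4)

    def test_fully_methylated_reads_all_methylated(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=1, mean_coverage=50, seed=5)
        truth = simulate.SimTruth(
            sites=pd.DataFrame({"chrom": ["chr1"], "pos": [1000],
                                "control.p_m": [1.0], "control.p_h": [0.0],
                                "case.p_m": [1.0], "case.p_h": [0.0]}),
            injected_dmrs=pd.DataFrame(), expression_model={})
        _, reports = simulate.simulate_reads(truth, cfg)
        for calls in reports.values():
            assert (calls["unmeth_count"] == 0).all()

    def test_error_terms_shift_read_probabilities(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=200, mean_coverage=1e3,
                        n_dmrs_5mc=0, n_dmrs_5hmc=0, seed=6,
                        bs_conversion_error=0.5, oxbs_oxidation_failure=1.0)
        cpgs, _, _ = simulate.generate_genome(cfg)
        truth = simulate.generate_truth(cfg, cpgs)
        _, reports = simulate.simulate_reads(truth, cfg)
        s = truth.sites
        bs = reports["WT1_BS"]
        q_bs = (s["control.p_m"] + s["control.p_h"]
                + 0.5 * (1 - s["control.p_m"] - s["control.p_h"])).mean()
        frac = bs["meth_count"].sum() / (bs["meth_count"]
                                         + bs["unmeth_count"]).sum()
        assert frac == pytest.approx(q_bs, abs=0.01)
        ox = reports["WT1_OxBS"]
        q_ox = (s["control.p_m"] + s["control.p_h"]).mean()  # full leakage
        frac_ox = ox["meth_count"].sum() / (ox["meth_count"]
                                            + ox["unmeth_count"]).sum()
        assert frac_ox == pytest.approx(q_ox, abs=0.01)


class TestSimulateExpression:
    def test_decoupled_expression_uncorrelated(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=6000, seed=8,
                        expr_coupling=0.0, n_dmrs_5mc=0, n_dmrs_5hmc=0)
        ds = simulate.simulate_dataset(cfg)
        introns = ds.elements[ds.elements.element_class == "intron"]
        means = annotate.element_mean_methylation(
            ds.truth.sites, introns, ["control.p_h"])
        merged = means.dropna().groupby("gene_id")["control.p_h"].mean()
        shared = merged.index.intersection(ds.counts.index)
        from scipy.stats import spearmanr
        rho = spearmanr(merged.loc[shared],
                        ds.counts.loc[shared, "WT1"]).statistic
        assert abs(rho) < 3 / np.sqrt(len(shared))

    def test_strong_coupling_near_monotone(self):
        cfg = SimConfig(n_chrom=1, cpgs_per_chrom=6000, seed=8,
                        expr_coupling=25.0, expr_dispersion=0.0,
                        n_dmrs_5mc=0, n_dmrs_5hmc=0,
                        libsize_factor_range=(1.0, 1.0))
        ds = simulate.simulate_dataset(cfg)
        introns = ds.elements[ds.elements.element_class == "intron"]
        means = annotate.element_mean_methylation(
            ds.truth.sites, introns, ["control.p_h"])
        merged = means.dropna().groupby("gene_id")["control.p_h"].mean()
        shared = merged.index.intersection(ds.counts.index)
        from scipy.stats import spearmanr
        rho = spearmanr(merged.loc[shared],
                        ds.counts.loc[shared, "WT1"]).statistic
        assert rho > 0.9
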