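import numpy as np
import pandas as pd
import pytest

from oxbstools import dmr


class TestPrefilter:
    def test_no_sample_reaches_two_reads_removed(self):
        cov = np.array([[0, 1, 1, 1, 0, 1]], float)
        groups = ["control"] * 3 + ["case"] * 3
        assert not dmr.prefilter(cov, groups, min_reads=2)[0]

    def test_one_covered_sample_suffices_by_default(self):
        cov = np.array([[5, 0, 0, 0, 0, 0]], float)
        groups = ["control"] * 3 + ["case"] * 3
        assert dmr.prefilter(cov, groups, min_reads=2)[0]

    def test_strict_reading_requires_both_groups(self):
        cov = np.array([[5, 0, 0, 0, 0, 0]], float)
        groups = ["control"] * 3 + ["case"] * 3
        assert not dmr.prefilter(cov, groups, min_reads=2, strict=True)[0]

    def test_min_reads_zero_identity(self):
        cov = np.zeros((4, 6))
        groups = ["control"] * 3 + ["case"] * 3
        assert dmr.prefilter(cov, groups, min_reads=0).all()


def _sites(values, positions=None, coverage=None, chrom="chr1"):
    n, s = values.shape
    if positions is None:
        positions = np.arange(1, n + 1) * 100
    cols = {"chrom": [chrom] * n, "pos": positions}
    for j in range(s):
        cols[f"s{j}.v"] = values[:, j]
        cols[f"s{j}.cov"] = (coverage[:, j] if coverage is not None
                             else np.full(n, 10.0))
    return pd.DataFrame(cols)


class TestSmooth:
    def test_constant_track_reproduced(self):
        sites = _sites(np.full((50, 2), 0.37))
        out = dmr.smooth(sites, ["s0.v", "s1.v"], ["s0.cov", "s1.cov"],
                         h_bp=500, min_cpgs=10)
        np.testing.assert_allclose(out[["s0.v", "s1.v"]], 0.37, atol=1e-12)

    def test_three_cpg_linear_center(self):
        # symmetric window, equal coverage: local linear fit passes through
        # the middle of (0.2, 0.4, 0.6)
        sites = _sites(np.array([[0.2], [0.4], [0.6]]))
        out = dmr.smooth(sites, ["s0.v"], ["s0.cov"], h_bp=1000, min_cpgs=3)
        assert out.loc[1, "s0.v"] == pytest.approx(0.4)

    def test_infinite_bandwidth_is_global_fit(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.2, 0.8, size=(40, 1))
        sites = _sites(vals)
        out = dmr.smooth(sites, ["s0.v"], ["s0.cov"], h_bp=1e9, min_cpgs=40)
        x = sites["pos"].to_numpy(float)
        beta = np.polyfit(x, vals[:, 0], 1)
        np.testing.assert_allclose(out["s0.v"], np.clip(np.polyval(beta, x),
                                                        0, 1), atol=1e-6)

    def test_missing_values_get_zero_weight(self):
        vals = np.full((30, 1), 0.5)
        vals[10, 0] = np.nan
        sites = _sites(vals)
        out = dmr.smooth(sites, ["s0.v"], ["s0.cov"], h_bp=500, min_cpgs=5)
        np.testing.assert_allclose(out["s0.v"], 0.5, atol=1e-12)


class TestTstat:
    def _smoothed(self, ctrl, case):
        n = ctrl.shape[0]
        cols = {"chrom": ["chr1"] * n, "pos": np.arange(1, n + 1) * 100}
        for j in range(ctrl.shape[1]):
            cols[f"c{j}"] = ctrl[:, j]
        for j in range(case.shape[1]):
            cols[f"k{j}"] = case[:, j]
        return pd.DataFrame(cols)

    def test_identical_group_means_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(50, 2))
        sm = self._smoothed(x, x)
        ts = dmr.tstat(sm, ["c0", "c1"], ["k0", "k1"])
        assert (ts["t"] == 0.0).all()

    def test_zero_variance_offset_capped_positive(self):
        base = np.tile(np.linspace(0.2, 0.4, 30)[:, None], (1, 2))
        ts = dmr.tstat(self._smoothed(base, base + 0.1), ["c0", "c1"],
                       ["k0", "k1"], max_cap=50)
        assert (ts["t"] == 50).all()

    def test_label_swap_negates_exactly(self):
        rng = np.random.default_rng(1)
        ctrl = rng.uniform(0.3, 0.7, size=(200, 3))
        case = rng.uniform(0.3, 0.7, size=(200, 3))
        sm = self._smoothed(ctrl, case)
        fwd = dmr.tstat(sm, ["c0", "c1", "c2"], ["k0", "k1", "k2"])
        rev = dmr.tstat(sm, ["k0", "k1", "k2"], ["c0", "c1", "c2"])
        np.testing.assert_array_equal(fwd["t"].to_numpy(),
                                      -rev["t"].to_numpy())
        np.testing.assert_array_equal(fwd["diff"].to_numpy(),
                                      -rev["diff"].to_numpy())

    def test_single_replicate_group_rejected(self):
        sm = self._smoothed(np.zeros((10, 1)), np.zeros((10, 2)))
        with pytest.raises(ValueError, match="mean_diff"):
            dmr.tstat(sm, ["c0"], ["k0", "k1"])


class TestDmrFind:
    def _tstats(self, t, diff=None, chrom=None):
        n = len(t)
        return pd.DataFrame({
            "chrom": chrom if chrom is not None else ["chr1"] * n,
            "pos": np.arange(1, n + 1) * 100,
            "t": t, "diff": diff if diff is not None else np.asarray(t) / 10})

    def test_all_zero_t_no_candidates(self):
        assert dmr.dmr_find(self._tstats(np.zeros(100))).empty

    def test_single_block_found_with_exact_size(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 0.1, size=1000)
        t[100:110] = 10.0
        cands = dmr.dmr_find(self._tstats(t), cutoff_quantiles=(0.025, 0.975))
        big = cands[cands["n_cpg"] >= 3]
        assert len(big) == 1
        row = big.iloc[0]
        assert row["n_cpg"] == 10
        assert row["start"] == 10099    # pos of first member CpG minus 1
        assert row["end"] == 11000      # pos of last member CpG (half-open)
        assert row["area_stat"] == pytest.approx(100.0)

    def test_runs_not_merged_across_gaps(self):
        t = np.zeros(100)
        t[10:13] = 5.0
        t[14:17] = 5.0  # one sub-threshold CpG between runs
        cands = dmr.dmr_find(self._tstats(t), cutoff=(-3, 3))
        assert len(cands) == 2
        assert cands["n_cpg"].tolist() == [3, 3]

    def test_chromosomes_independent(self):
        t = np.full(20, 5.0)
        chrom = ["chr1"] * 10 + ["chr2"] * 10
        cands = dmr.dmr_find(self._tstats(t, chrom=chrom), cutoff=(-3, 3))
        assert len(cands) == 2
        assert sorted(cands["chrom"]) == ["chr1", "chr2"]


class TestFilterRank:
    def _cands(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg",
                                           "mean_diff", "area_stat",
                                           "direction", "idx_start",
                                           "idx_end"])

    def test_min_three_cpgs(self):
        c = self._cands([("chr1", 0, 10, 2, 0.5, 9.0, 1, 0, 1)])
        assert dmr.filter_dmrs(c, "5mC").empty

    def test_type_specific_thresholds(self):
        c = self._cands([("chr1", 0, 10, 5, 0.08, 9.0, 1, 0, 4)])
        assert dmr.filter_dmrs(c, "5mC").empty
        assert len(dmr.filter_dmrs(c, "5hmC")) == 1

    def test_absolute_value_of_difference(self):
        c = self._cands([("chr1", 0, 10, 3, -0.10, -9.0, -1, 0, 2)])
        assert len(dmr.filter_dmrs(c, "5mC")) == 1

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            dmr.filter_dmrs(self._cands([]), "6mA")

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        c = self._cands([("chr1", i * 100, i * 100 + 50,
                          int(rng.integers(1, 8)), rng.uniform(-0.3, 0.3),
                          rng.normal(), 1, 0, 0) for i in range(50)])
        counts = [len(dmr.filter_dmrs(c, "5mC", min_cpgs=k, min_diff=d))
                  for k, d in [(1, 0.0), (3, 0.1), (5, 0.2)]]
        assert counts == sorted(counts, reverse=True)

    def test_area_stat_ranking(self):
        c = self._cands([("chr1", 0, 10, 3, 0.2, 18.0, 1, 0, 2),
                         ("chr1", 50, 60, 3, -0.2, -20.0, -1, 5, 7)])
        ranked = dmr.rank_dmrs(dmr.filter_dmrs(c, "5mC"))
        assert ranked.iloc[0]["area_stat"] == -20.0
        assert ranked["rank"].tolist() == [1, 2]


def test_label_swap_full_pipeline(study_pipeline):
    """Exchanging group labels flips every call's sign but not its geometry."""
    est = study_pipeline["est_raw"].iloc[:4000].reset_index(drop=True)
    sheet = study_pipeline["ds"].sheet
    swapped = sheet.copy()
    swapped["group"] = swapped["group"].map(
        {"control": "case", "case": "control"})
    kw = dict(h_bp=500.0, min_cpgs_smooth=21)
    fwd = dmr.call_dmrs(est, sheet, "5mC", **kw)
    rev = dmr.call_dmrs(est, swapped, "5mC", **kw)
    np.testing.assert_array_equal(fwd.tstats["t"].to_numpy(),
                                  -rev.tstats["t"].to_numpy())
    f, r = fwd.dmrs, rev.dmrs
    assert f["start"].tolist() == r["start"].tolist() or \
        set(f["start"]) == set(r["start"])
    np.testing.assert_allclose(np.sort(np.abs(f["area_stat"])),
                               np.sort(np.abs(r["area_stat"])), rtol=1e-12)
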