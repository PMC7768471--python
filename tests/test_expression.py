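"""Expression summaries, normalization and the NB quasi-likelihood test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from xenostroma import expression as ex
from xenostroma.containers import CountMatrix


@pytest.fixture
def hand_counts():
    return pd.DataFrame(
        {"s1": [10, 0, 5, 100, 35], "s2": [20, 5, 0, 50, 25], "s3": [1, 1, 1, 1, 1]},
        index=[f"g{i}" for i in range(1, 6)])


class TestCpm:
    def test_hand_matrix(self, hand_counts):
        lc = ex.cpm_log2(hand_counts)
        lib = hand_counts.sum(axis=0)
        expected = np.log2(hand_counts / lib * 1e6 + 1.0)
        pd.testing.assert_frame_equal(lc, expected)

    def test_zero_count_maps_to_zero(self, hand_counts):
        assert ex.cpm_log2(hand_counts).loc["g2", "s1"] == 0.0

    def test_single_gene_sample_is_full_million(self):
        cf = pd.DataFrame({"s1": [7]}, index=["g1"])
        assert ex.cpm(cf).iloc[0, 0] == 1e6

    def test_cpm_sums_to_million(self, hand_counts):
        assert np.allclose(ex.cpm(hand_counts).sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_rejected(self):
        cf = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            ex.cpm(cf)


class TestFilterLow:
    def _cm(self, frame):
        meta = pd.DataFrame({"model": "BM18like", "condition": "intact",
                             "replicate": range(1, frame.shape[1] + 1)},
                            index=pd.Index(frame.columns, name="sample_id"))
        return CountMatrix(frame, meta)

    def test_boundary_exactly_three_low_retained(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.integers(500, 1500, (5, 10)),
                             index=[f"g{i}" for i in range(5)],
                             columns=[f"s{i}" for i in range(10)])
        frame.iloc[0, :3] = 0   # low in exactly 3 samples -> retained
        frame.iloc[1, :4] = 0   # low in 4 samples -> removed
        kept = ex.filter_low(self._cm(frame)).counts.index
        assert "g0" in kept and "g1" not in kept

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.poisson(3, (200, 8)),
                             index=[f"g{i}" for i in range(200)],
                             columns=[f"s{i}" for i in range(8)])
        frame += 1  # avoid all-zero samples
        kept = set(ex.filter_low(self._cm(frame)).counts.index)
        lc = np.log2(frame / frame.sum(axis=0) * 1e6 + 1)
        brute = {g for g in frame.index if (lc.loc[g] < 1).sum() <= 3}
        assert kept == brute


class TestTpm:
    def test_equal_counts_equal_lengths(self):
        cf = pd.DataFrame({"s1": [10, 10, 10, 10]}, index=list("abcd"))
        t = ex.tpm(cf, {g: 100 for g in "abcd"})
        assert np.allclose(t["s1"], 250_000)

    def test_halving_length_doubles_share(self):
        cf = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        t1 = ex.tpm(cf, {"a": 100, "b": 100})
        t2 = ex.tpm(cf, {"a": 50, "b": 100})
        assert np.isclose(t2.loc["a", "s1"] / t2.loc["b", "s1"],
                          2 * t1.loc["a", "s1"] / t1.loc["b", "s1"])

    def test_formula_oracle(self):
        rng = np.random.default_rng(2)
        cf = pd.DataFrame(rng.integers(1, 100, (6, 2)),
                          index=list("abcdef"), columns=["s1", "s2"])
        lengths = pd.Series(rng.integers(200, 2000, 6), index=list("abcdef"))
        rate = cf.div(lengths, axis=0)
        expected = rate / rate.sum(axis=0) * 1e6
        pd.testing.assert_frame_equal(ex.tpm(cf, lengths), expected)
        assert np.allclose(ex.tpm(cf, lengths).sum(axis=0), 1e6)

    def test_missing_length_rejected(self):
        cf = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ex.tpm(cf, {"a": 100})


class TestZfpkm:
    def test_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(3)
        log2_fpkm = rng.normal(5.0, 2.0, 5000)
        frame = pd.DataFrame({"s1": 2.0 ** log2_fpkm})
        z = ex.zfpkm(frame)
        # recover mu and sigma: z = (x - mu)/sigma on the log2 scale
        slope, intercept = np.polyfit(log2_fpkm, z["s1"], 1)
        assert abs(1 / slope - 2.0) < 0.2
        assert abs(-intercept / slope - 5.0) < 0.2

    def test_mode_gene_scores_zero(self):
        rng = np.random.default_rng(4)
        vals = np.r_[rng.normal(4, 1, 999), 4.0]
        z = ex.zfpkm(pd.DataFrame({"s1": 2.0 ** vals}))
        assert abs(z["s1"].iloc[-1]) < 0.15

    def test_expressed_calls_strict_threshold(self):
        z = pd.DataFrame({"s1": [-3.0, -2.9], "s2": [0.0, 0.0]}, index=["g1", "g2"])
        assert ex.expressed_calls(z, threshold=-3.0) == ["g2"]

    def test_too_few_nonzero_rejected(self):
        frame = pd.DataFrame({"s1": [1.0] * 5 + [0.0] * 20})
        with pytest.raises(ValueError):
            ex.zfpkm(frame)


class TestTopVariablePca:
    def test_constant_gene_never_selected(self):
        frame = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 9.0], "s3": [1.0, 2.0]},
                             index=["flat", "var"])
        assert ex.top_variable(frame, 1) == ["var"]

    def test_ranking_matches_brute_sort(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(0, 1, (50, 6)),
                             index=[f"g{i:02d}" for i in range(50)])
        got = ex.top_variable(frame, 20)
        var = frame.var(axis=1, ddof=1)
        brute = sorted(frame.index, key=lambda g: (-var[g], g))[:20]
        assert got == brute

    def test_pca_separates_planted_groups(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(6)
        base = rng.normal(5, 1, (100, 1))
        group = np.r_[np.zeros(4), np.ones(4)]
        expr = base + rng.normal(0, 0.3, (100, 8))
        expr[:30, group == 1] += 2.0
        frame = pd.DataFrame(expr, columns=[f"s{i}" for i in range(8)])
        coords = ex.pca(frame.loc[ex.top_variable(frame, 50)], 2)
        assert silhouette_score(coords.values, group) > 0.5

    def test_too_many_components_rejected(self):
        frame = pd.DataFrame(np.eye(4), columns=list("abcd"))
        with pytest.raises(ValueError):
            ex.pca(frame, n_components=4)


def tmm_oracle(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> pd.Series:
    """Plainly-coded weighted trimmed mean of M-values (test oracle)."""
    lib = counts.sum(axis=0).astype(float)
    rate = counts.div(lib, axis=1)
    q75 = rate.apply(lambda col: np.quantile(col[col > 0], 0.75))
    ref = (q75 - q75.mean()).abs().idxmin()
    raw = {}
    for s in counts.columns:
        if s == ref:
            raw[s] = 1.0
            continue
        ok = (counts[s] > 0) & (counts[ref] > 0)
        y, r = counts[s][ok].astype(float), counts[ref][ok].astype(float)
        m = np.log2((y / lib[s]) / (r / lib[ref]))
        a = 0.5 * np.log2((y / lib[s]) * (r / lib[ref]))
        w = (lib[s] - y) / (lib[s] * y) + (lib[ref] - r) / (lib[ref] * r)
        if np.abs(m).max() < 1e-6:
            raw[s] = 1.0
            continue
        n = len(m)
        lo_l, lo_s = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        keep = ((rankdata(m) >= lo_l) & (rankdata(m) <= n + 1 - lo_l)
                & (rankdata(a) >= lo_s) & (rankdata(a) <= n + 1 - lo_s))
        raw[s] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
    f = pd.Series(raw)
    return f / np.exp(np.log(f).mean())


class TestTmm:
    def test_identical_columns_unit_factors(self):
        cf = pd.DataFrame({"s1": [5, 10, 2], "s2": [5, 10, 2], "s3": [5, 10, 2]})
        assert np.allclose(ex.tmm_factors(cf).factors, 1.0)

    def test_pure_depth_difference_unit_factors(self):
        rng = np.random.default_rng(7)
        base = rng.integers(10, 1000, 300)
        cf = pd.DataFrame({"s1": base, "s2": 2 * base})
        assert np.allclose(ex.tmm_factors(cf).factors, 1.0)

    def test_matches_oracle_on_random_nb(self):
        rng = np.random.default_rng(8)
        mu = rng.lognormal(4, 1, 200)
        cf = pd.DataFrame({f"s{j}": rng.negative_binomial(10, 10 / (10 + mu))
                           for j in range(4)})
        got = ex.tmm_factors(cf).factors
        want = tmm_oracle(cf)
        assert np.max(np.abs(got - want[got.index])) < 1e-10

    def test_unit_geometric_mean_and_gene_order_invariance(self):
        rng = np.random.default_rng(9)
        cf = pd.DataFrame(rng.poisson(50, (150, 5)) + 1,
                          index=[f"g{i}" for i in range(150)])
        f1 = ex.tmm_factors(cf).factors
        assert abs(np.log(f1).mean()) < 1e-12
        shuffled = cf.sample(frac=1.0, random_state=0)
        f2 = ex.tmm_factors(shuffled).factors
        assert np.allclose(f1, f2[f1.index])


class TestNbQlTest:
    def test_null_type_one_error(self, null_de):
        """Type-I error at nominal 0.05 stays in [0.03, 0.07] under the null."""
        frac = (null_de.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_null_pvalues_uniform(self, null_de):
        from scipy.stats import kstest
        assert kstest(null_de.table["p"], "uniform").pvalue > 0.01

    def test_power_on_planted_effect(self, null_count_matrix):
        frame, groups = null_count_matrix
        boosted = frame.copy()
        planted = frame.index[:50]
        boosted.loc[planted, groups[groups == "A"].index] *= 8
        de = ex.nb_ql_test(boosted, ex.tmm_factors(boosted), groups, ("B", "A"))
        sig = set(ex.significant(de))
        assert sum(g in sig for g in planted) >= 0.95 * len(planted)

    def test_contrast_reversal_flips_sign(self, null_count_matrix):
        frame, groups = null_count_matrix
        sub = frame.iloc[:100]
        f = ex.tmm_factors(sub)
        ab = ex.nb_ql_test(sub, f, groups, ("A", "B")).table
        ba = ex.nb_ql_test(sub, f, groups, ("B", "A")).table
        assert np.allclose(ab["log2FC"], -ba["log2FC"], atol=1e-8)
        assert np.allclose(ab["p"], ba["p"], atol=1e-10)

    def test_all_zero_gene_excluded(self, null_count_matrix):
        frame, groups = null_count_matrix
        sub = frame.iloc[:50].copy()
        sub.loc["dead"] = 0
        de = ex.nb_ql_test(sub, ex.tmm_factors(sub), groups, ("B", "A"))
        assert "dead" in de.excluded
        assert "dead" not in de.table.index


class TestSignificant:
    def _mk(self, fdr, lfc):
        table = pd.DataFrame({"log2FC": lfc, "FDR": fdr,
                              "logCPM": 5.0, "F": 1.0, "p": fdr, "dispersion": 0.1},
                             index=[f"g{i}" for i in range(len(fdr))])
        return ex.DEResult(table, ("B", "A"), [])

    def test_boundaries_are_strict(self):
        de = self._mk(fdr=[0.05, 0.049, 0.049], lfc=[2.0, 1.0, -1.01])
        assert ex.significant(de) == ["g2"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        de = self._mk(fdr=rng.uniform(0, 0.2, 200), lfc=rng.normal(0, 1.5, 200))
        brute = [g for g in de.table.index
                 if de.table.loc[g, "FDR"] < 0.05 and abs(de.table.loc[g, "log2FC"]) > 1]
        assert ex.significant(de) == brute


class TestZscore:
    def test_two_sample_forced_values(self):
        frame = pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["g"])
        z = ex.zscore_matrix(frame)
        assert np.allclose(z.values, [[-np.sqrt(0.5), np.sqrt(0.5)]])

    def test_constant_gene_zero_row(self):
        frame = pd.DataFrame({"s1": [2.0, 1.0], "s2": [2.0, 5.0]}, index=["flat", "v"])
        z = ex.zscore_matrix(frame)
        assert (z.loc["flat"] == 0).all()

    def test_rows_standardized(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(rng.normal(0, 1, (30, 6)))
        z = ex.zscore_matrix(frame)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)
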