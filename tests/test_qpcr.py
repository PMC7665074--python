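"""ΔCt schemes and reference-gene stability estimators vs. oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rnaseqbench import (
    average_duplicates,
    consensus_rank,
    delta_ct_endogenous,
    delta_ct_global_median,
    delta_ct_most_stable,
    stability_bestkeeper,
    stability_comparative_dct,
    stability_genorm,
    stability_normfinder,
)
from rnaseqbench.qpcr import StabilityResult


def long_ct(wide: pd.DataFrame) -> pd.DataFrame:
    rows = [(g, s, 1, wide.loc[g, s])
            for g in wide.index for s in wide.columns]
    return pd.DataFrame(rows, columns=["gene", "sample", "duplicate", "ct"])


def wide_of(ct) -> pd.DataFrame:
    return average_duplicates(ct).pivot(index="gene", columns="sample",
                                        values="ct")


class TestAverageDuplicates:
    @pytest.mark.parametrize("cts,expected", [
        ((30.0, 32.0), 31.0),
        ((28.5,), 28.5),
        ((30.0, 30.0, 30.0), 30.0),
    ])
    def test_arithmetic_mean_of_duplicates(self, cts, expected):
        ct = pd.DataFrame(
            [("g", "s", d + 1, v) for d, v in enumerate(cts)],
            columns=["gene", "sample", "duplicate", "ct"])
        out = average_duplicates(ct)
        assert out.loc[0, "ct"] == pytest.approx(expected)

    def test_idempotent(self, toy_ct):
        once = average_duplicates(toy_ct)
        twice = average_duplicates(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDeltaCtSchemes:
    def test_endogenous_direct_substitution(self):
        wide = pd.DataFrame({"s1": [20.0, 22.0, 25.0]},
                            index=["c1", "c2", "target"])
        delta = delta_ct_endogenous(long_ct(wide), ["c1", "c2"])
        assert delta.wide().loc["target", "s1"] == pytest.approx(-4.0)

    def test_sole_control_is_its_own_zero(self):
        wide = pd.DataFrame({"s1": [23.0, 29.0]}, index=["c", "t"])
        delta = delta_ct_endogenous(long_ct(wide), ["c"])
        assert delta.wide().loc["c", "s1"] == 0.0

    def test_endogenous_toy_matches_hand_computation(self):
        wide = pd.DataFrame({"s1": [20.0, 24.0, 30.0],
                             "s2": [21.0, 23.0, 28.0]},
                            index=["c", "g1", "g2"])
        delta = delta_ct_endogenous(long_ct(wide), ["c"]).wide()
        expected = pd.DataFrame({"s1": [0.0, -4.0, -10.0],
                                 "s2": [0.0, -2.0, -7.0]},
                                index=["c", "g1", "g2"])
        pd.testing.assert_frame_equal(
            delta.loc[expected.index], expected, check_names=False)

    def test_global_median_forced_by_definition(self):
        wide = pd.DataFrame({"s1": [30.0, 32.0, 34.0]},
                            index=["g1", "g2", "g3"])
        delta = delta_ct_global_median(long_ct(wide)).wide()
        assert list(delta["s1"]) == pytest.approx([2.0, 0.0, -2.0])

    def test_global_median_ceiling_is_strict(self):
        wide = pd.DataFrame({"s1": [30.0, 35.0, 40.0]},
                            index=["g1", "g2", "g3"])
        delta = delta_ct_global_median(long_ct(wide)).wide()
        assert list(delta["s1"]) == pytest.approx([0.0, -5.0, -10.0])

    def test_empty_sample_under_ceiling_names_the_sample(self):
        wide = pd.DataFrame({"bad": [36.0, 38.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            delta_ct_global_median(long_ct(wide))

    def test_most_stable_scheme_zero_for_reference(self, toy_ct):
        delta = delta_ct_most_stable(toy_ct, "gB").wide()
        assert (delta.loc["gB"] == 0).all()

    def test_most_stable_equals_endogenous_with_single_control(self, toy_ct):
        a = delta_ct_most_stable(toy_ct, "gC").wide()
        b = delta_ct_endogenous(toy_ct, ["gC"]).wide()
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("scheme", ["endogenous", "global_median",
                                        "most_stable"])
    def test_per_sample_shift_equivariance(self, toy_ct, scheme):
        # adding a per-sample constant shifts the reference identically,
        # so between-gene ΔCt differences are unchanged
        shifted = toy_ct.copy()
        offsets = {s: i * 1.7 for i, s in
                   enumerate(sorted(shifted["sample"].unique()))}
        shifted["ct"] = shifted["ct"] + shifted["sample"].map(offsets)
        fns = {
            "endogenous": lambda ct: delta_ct_endogenous(ct, ["gA"]),
            "global_median": lambda ct: delta_ct_global_median(ct, 100.0),
            "most_stable": lambda ct: delta_ct_most_stable(ct, "gB"),
        }
        base = fns[scheme](toy_ct).wide()
        after = fns[scheme](shifted).wide()
        diff_base = base.loc["gA"] - base.loc["gD"]
        diff_after = after.loc["gA"] - after.loc["gD"]
        pd.testing.assert_series_equal(diff_base, diff_after)


def brute_force_pairwise_sd(wide: pd.DataFrame) -> dict:
    """Independent oracle: SD of Ct differences for every gene pair."""
    out = {}
    for j, k in itertools.permutations(wide.index, 2):
        diffs = [wide.loc[j, s] - wide.loc[k, s] for s in wide.columns]
        out[(j, k)] = float(np.std(diffs, ddof=1))
    return out


class TestGenorm:
    def test_parallel_genes_have_zero_pairwise_variation(self):
        base = pd.DataFrame({f"s{i}": [20.0 + i, 23.0 + i, 27.0 + i]
                             for i in range(4)},
                            index=["g1", "g2", "g3"])
        res = stability_genorm(long_ct(base))
        assert res.values.max() == pytest.approx(0.0)

    def test_sample_shift_invariance(self, toy_ct):
        res_a = stability_genorm(toy_ct)
        shifted = toy_ct.copy()
        offsets = {s: i * 2.5 for i, s in
                   enumerate(sorted(shifted["sample"].unique()))}
        shifted["ct"] = shifted["ct"] + shifted["sample"].map(offsets)
        res_b = stability_genorm(shifted)
        pd.testing.assert_series_equal(res_a.values, res_b.values)

    def test_round_one_m_matches_brute_force(self, toy_ct):
        wide = wide_of(toy_ct)
        oracle = brute_force_pairwise_sd(wide)
        comparative = stability_comparative_dct(toy_ct)
        for j in wide.index:
            m_j = np.mean([oracle[(j, k)] for k in wide.index if k != j])
            assert comparative.values[j] == pytest.approx(m_j)

    def test_iterative_exclusion_against_step_by_step_oracle(self, toy_ct):
        wide = wide_of(toy_ct)
        res = stability_genorm(toy_ct)
        # replay the pruning by hand with the brute-force pair SDs
        remaining = sorted(wide.index)
        expected = {}
        while len(remaining) > 2:
            oracle = brute_force_pairwise_sd(wide.loc[remaining])
            m = {j: np.mean([oracle[(j, k)] for k in remaining if k != j])
                 for j in remaining}
            worst = min([g for g in remaining
                         if m[g] == max(m.values())])
            expected[worst] = m[worst]
            remaining.remove(worst)
        oracle = brute_force_pairwise_sd(wide.loc[remaining])
        for g in remaining:
            expected[g] = np.mean([oracle[(g, k)]
                                   for k in remaining if k != g])
        for g in wide.index:
            assert res.values[g] == pytest.approx(expected[g])

    def test_needs_three_genes(self):
        wide = pd.DataFrame({"s1": [20.0, 21.0], "s2": [22.0, 24.0]},
                            index=["g1", "g2"])
        with pytest.raises(ValueError):
            stability_genorm(long_ct(wide))


class TestComparativeDct:
    def test_two_genes_share_the_single_pairwise_sd(self):
        wide = pd.DataFrame({"s1": [20.0, 25.0], "s2": [21.0, 27.0],
                             "s3": [19.0, 24.0]}, index=["g1", "g2"])
        res = stability_comparative_dct(long_ct(wide))
        sd = np.std([-5.0, -6.0, -5.0], ddof=1)
        assert res.values["g1"] == pytest.approx(sd)
        assert res.values["g2"] == pytest.approx(sd)

    def test_matches_brute_force(self, toy_ct):
        wide = wide_of(toy_ct)
        oracle = brute_force_pairwise_sd(wide)
        res = stability_comparative_dct(toy_ct)
        for j in wide.index:
            expected = np.mean([oracle[(j, k)]
                                for k in wide.index if k != j])
            assert res.values[j] == pytest.approx(expected)


class TestBestKeeper:
    def test_constant_gene_gets_best_rank(self, toy_ct):
        ct = pd.concat([toy_ct, pd.DataFrame(
            [("flat", s, 1, 25.0) for s in toy_ct["sample"].unique()],
            columns=["gene", "sample", "duplicate", "ct"])],
            ignore_index=True)
        res = stability_bestkeeper(ct)
        assert res.values["flat"] == 0.0
        assert res.ranks["flat"] == res.ranks.min()

    def test_sd_matches_hand_computation(self):
        wide = pd.DataFrame({"s1": [20.0, 30.0, 24.0],
                             "s2": [22.0, 31.0, 26.0],
                             "s3": [21.0, 35.0, 22.0],
                             "s4": [23.0, 30.0, 28.0]},
                            index=["g1", "g2", "g3"])
        res = stability_bestkeeper(long_ct(wide))
        for g in wide.index:
            assert res.values[g] == pytest.approx(
                np.std(wide.loc[g], ddof=1))

    def test_gene_identical_to_index_correlates_perfectly(self):
        # two mirrored genes make the index; a third follows the index
        s = np.array([20.0, 22.0, 21.0, 24.0])
        wide = pd.DataFrame({f"x{i}": [s[i] + 1, s[i] - 1, s[i]]
                             for i in range(4)},
                            index=["g1", "g2", "g3"])
        res = stability_bestkeeper(long_ct(wide))
        assert res.extras["index_correlation"]["g3"] == pytest.approx(1.0)

    def test_constant_index_marks_correlation_undefined(self):
        wide = pd.DataFrame({"s1": [20.0, 30.0], "s2": [22.0, 28.0]},
                            index=["g1", "g2"])  # index constant at 25
        res = stability_bestkeeper(long_ct(wide))
        assert np.isnan(res.extras["index_correlation"]).all()
        assert res.ranks.notna().all()  # ranking falls back to SD


def brute_force_normfinder(wide: pd.DataFrame, groups: dict) -> dict:
    """Loop-based reimplementation of the documented stability estimator."""
    centred = {}
    for s in wide.columns:
        col_mean = np.mean([wide.loc[g, s] for g in wide.index])
        for g in wide.index:
            centred[(g, s)] = wide.loc[g, s] - col_mean
    labels = sorted(set(groups.values()))
    out = {}
    for g in wide.index:
        means, ses = [], []
        for lab in labels:
            cols = [s for s in wide.columns if groups[s] == lab]
            vals = [centred[(g, s)] for s in cols]
            means.append(np.mean(vals))
            ses.append(np.sqrt(np.var(vals, ddof=1) / len(vals)))
        grand = np.mean(means)
        bias = np.mean([abs(m - grand) for m in means])
        out[g] = bias + np.mean(ses)
    return out


class TestNormFinder:
    def groups(self, ct):
        samples = sorted(ct["sample"].unique())
        half = len(samples) // 2
        return {s: ("A" if i < half else "B")
                for i, s in enumerate(samples)}

    def test_degenerate_optimum_scores_zero(self):
        wide = pd.DataFrame(
            {f"s{i}": [20.0 + i, 24.0 + i, 29.0 + i] for i in range(6)},
            index=["g1", "g2", "g3"])
        ct = long_ct(wide)
        res = stability_normfinder(ct, self.groups(ct))
        assert np.allclose(res.values, 0.0)

    def test_matches_brute_force_oracle(self, toy_ct):
        groups = self.groups(toy_ct)
        # drop one sample to get 2+2 grouping with 5 samples -> use 4
        keep = sorted(toy_ct["sample"].unique())[:4]
        ct = toy_ct[toy_ct["sample"].isin(keep)]
        groups = {s: g for s, g in self.groups(ct).items() if s in keep}
        res = stability_normfinder(ct, groups)
        oracle = brute_force_normfinder(wide_of(ct), groups)
        for g in res.values.index:
            assert res.values[g] == pytest.approx(oracle[g])

    def test_permuting_samples_within_groups_changes_nothing(self, toy_ct):
        keep = sorted(toy_ct["sample"].unique())[:4]
        ct = toy_ct[toy_ct["sample"].isin(keep)].copy()
        groups = {s: ("A" if i < 2 else "B") for i, s in enumerate(keep)}
        res_a = stability_normfinder(ct, groups)
        swap = {keep[0]: keep[1], keep[1]: keep[0],
                keep[2]: keep[3], keep[3]: keep[2]}
        ct2 = ct.copy()
        ct2["sample"] = ct2["sample"].map(swap)
        res_b = stability_normfinder(ct2, groups)
        pd.testing.assert_series_equal(res_a.values, res_b.values)

    def test_small_group_rejected(self, toy_ct):
        groups = {s: ("A" if i == 0 else "B")
                  for i, s in enumerate(sorted(toy_ct["sample"].unique()))}
        with pytest.raises(ValueError, match="fewer than 2"):
            stability_normfinder(toy_ct, groups)


def fake_result(method: str, ranks: dict) -> StabilityResult:
    series = pd.Series(ranks, dtype=float)
    return StabilityResult(method=method, values=series, ranks=series)


class TestConsensus:
    def test_unanimous_winner(self):
        ranks = {"g1": 1, "g2": 2, "g3": 3}
        results = [fake_result(m, ranks) for m in
                   ("genorm", "normfinder", "bestkeeper", "comparative_dct")]
        cons = consensus_rank(results)
        assert cons.most_stable == "g1"
        assert cons.geo_mean["g1"] == pytest.approx(1.0)

    def test_geometric_mean_of_1_2_4_8(self):
        methods = ("genorm", "normfinder", "bestkeeper", "comparative_dct")
        per_method = {"genorm": 1, "normfinder": 2, "bestkeeper": 4,
                      "comparative_dct": 8}
        results = [fake_result(m, {"g1": per_method[m], "g2": 5})
                   for m in methods]
        cons = consensus_rank(results)
        assert cons.geo_mean["g1"] == pytest.approx(64 ** 0.25)

    def test_identical_rank_vectors_tie_broken_by_gene_id(self):
        ranks = {"zz": 1.5, "aa": 1.5, "mm": 3.0}
        results = [fake_result(m, ranks) for m in
                   ("genorm", "normfinder", "bestkeeper", "comparative_dct")]
        cons = consensus_rank(results)
        assert cons.order[:2] == ["aa", "zz"]
        assert cons.most_stable == "aa"

    def test_gene_set_mismatch_rejected(self):
        a = fake_result("genorm", {"g1": 1, "g2": 2})
        b = fake_result("bestkeeper", {"g1": 1, "g3": 2})
        with pytest.raises(ValueError):
            consensus_rank([a, b])


def test_every_ranking_is_a_valid_permutation(toy_ct):
    groups = {s: ("A" if i < 2 else "B")
              for i, s in enumerate(sorted(toy_ct["sample"].unique()))}
    # need >= 2 per group: 5 samples -> 2 + 3
    results = [stability_genorm(toy_ct),
               stability_comparative_dct(toy_ct),
               stability_bestkeeper(toy_ct),
               stability_normfinder(toy_ct, groups)]
    n = toy_ct["gene"].nunique()
    for res in results:
        assert sorted(res.ranks) == pytest.approx(sorted(
            pd.Series(res.values).rank(method="average")))
        assert res.ranks.sum() == pytest.approx(n * (n + 1) / 2)
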