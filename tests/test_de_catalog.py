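import math

import numpy as np
import pandas as pd
import pytest

from mirnatime.de_catalog import (StageGrouping, classify_groups, enrich_terms,
                                  pca_ordination, pooled_group_test,
                                  top_abundant, venn_overlap)
from mirnatime.de_test import PAIRWISE_RULE


def make_results(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "stage", "direction", "significant"])


class TestClassify:
    def test_single_stage_membership(self):
        res = make_results([("m1", "35E", "up", True), ("m1", "49E", "up", False)])
        cat = classify_groups(res)
        assert cat.sets["G1_up"] == {"m1"}
        assert not cat.sets["G1_down"] and not cat.sets["G2_up"]

    def test_matches_bruteforce_set_builder(self, rng):
        grouping = StageGrouping()
        stages = list(grouping.g1) + list(grouping.g2)
        rows = []
        for i in range(40):
            for s in stages:
                rows.append((f"m{i}", s, rng.choice(["up", "down"]),
                             bool(rng.uniform() < 0.3)))
        res = make_results(rows)
        cat = classify_groups(res)
        # independent oracle: exhaustive scan of the flag table
        expected = {"G1_up": set(), "G1_down": set(), "G2_up": set(), "G2_down": set()}
        for mid, stage, direction, sig in rows:
            if sig:
                g = "G1" if stage in grouping.g1 else "G2"
                expected[f"{g}_{direction}"].add(mid)
        assert cat.sets == expected

    def test_stage_counts_partition(self, rng):
        rows = [(f"m{i}", s, rng.choice(["up", "down"]), bool(rng.uniform() < 0.5))
                for i in range(30) for s in StageGrouping().g1]
        cat = classify_groups(make_results(rows))
        per_stage = cat.stage_table[~cat.stage_table["stage"].isin(["G1", "G2"])]
        assert (per_stage["n_up"] + per_stage["n_down"] == per_stage["n_total"]).all()

    def test_dual_direction_retained_with_warning(self):
        res = make_results([("m1", "35E", "up", True), ("m1", "49E", "down", True)])
        with pytest.warns(UserWarning):
            cat = classify_groups(res)
        assert "m1" in cat.sets["G1_up"] and "m1" in cat.sets["G1_down"]
        assert cat.dual_direction["G1"] == {"m1"}

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="99X"):
            classify_groups(make_results([("m1", "99X", "up", True)]))

    def test_group_sets_monotone_in_stages(self):
        res = make_results([("m1", "49E", "up", True), ("m2", "35E", "up", True)])
        # 49E is not in the one-stage grouping; restrict the table to its stages
        small = classify_groups(res[res["stage"] == "35E"],
                                StageGrouping(g1=("35E",), g2=("2P",)))
        full = classify_groups(res)
        assert small.sets["G1_up"] <= full.sets["G1_up"]


class TestVenn:
    def test_disjoint_and_identical(self):
        res = make_results([("a", "35E", "up", True), ("b", "2P", "down", True)])
        cat = classify_groups(res)
        assert venn_overlap(cat, "G1_up", "G2_down") == (1, 0, 1)
        assert venn_overlap(cat, "G1_up", "G1_up") == (0, 1, 0)

    def test_random_sets_against_intersection(self, rng):
        res = make_results([
            (f"m{i}", rng.choice(["35E", "2P"]), rng.choice(["up", "down"]), True)
            for i in range(60)])
        cat = classify_groups(res)
        a, b = cat.sets["G1_up"], cat.sets["G2_up"]
        only_a, shared, only_b = venn_overlap(cat, "G1_up", "G2_up")
        assert (only_a, shared, only_b) == (len(a - b), len(a & b), len(b - a))
        assert only_a + shared == len(a)

    def test_unknown_set_name(self):
        cat = classify_groups(make_results([("a", "35E", "up", True)]))
        with pytest.raises(KeyError):
            venn_overlap(cat, "G1_up", "nope")


class TestTopAbundant:
    def test_k_larger_than_set(self):
        tpm = pd.DataFrame({"L": [5.0, 1.0]}, index=["a", "b"])
        out = top_abundant(tpm, {"a", "b"}, ["L"], k=10)
        assert list(out["mirna_id"]) == ["a", "b"]

    def test_single_member(self):
        tpm = pd.DataFrame({"L": [5.0, 9.0]}, index=["a", "b"])
        out = top_abundant(tpm, {"a"}, ["L"], k=3)
        assert list(out["mirna_id"]) == ["a"]

    def test_matches_naive_sort_oracle(self, rng):
        ids = [f"m{i:02d}" for i in range(40)]
        tpm = pd.DataFrame(rng.uniform(0, 100, size=(40, 3)), index=ids,
                           columns=["A", "B", "C"])
        tpm.iloc[5] = tpm.iloc[7]  # force a tie
        sel = set(ids[:25])
        for stat in ("mean", "max"):
            out = top_abundant(tpm, sel, ["A", "B", "C"], k=10, rank_stat=stat)
            vals = {m: (tpm.loc[m].mean() if stat == "mean" else tpm.loc[m].max())
                    for m in sel}
            oracle = sorted(vals, key=lambda m: (-vals[m], m))[:10]
            assert list(out["mirna_id"]) == oracle


class TestOrdination:
    def test_duplicated_samples_identical_scores(self, rng):
        mat = pd.DataFrame(rng.uniform(1, 100, size=(10, 4)),
                           index=[f"m{i}" for i in range(10)],
                           columns=["s1", "s2", "s3", "s4"])
        mat["s4"] = mat["s1"]
        res = pca_ordination(mat)
        np.testing.assert_allclose(res.scores.loc["s1"], res.scores.loc["s4"],
                                   atol=1e-9)

    def test_full_reconstruction(self, rng):
        mat = pd.DataFrame(rng.uniform(1, 50, size=(6, 5)))
        res = pca_ordination(mat, log2_pseudocount=None)
        x = mat.to_numpy().T
        xc = x - x.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, xc, atol=1e-8)

    def test_variance_fractions_valid(self, rng):
        res = pca_ordination(pd.DataFrame(rng.uniform(1, 50, size=(8, 6))))
        assert (res.variance_fractions >= 0).all()
        assert res.variance_fractions.sum() <= 1 + 1e-9

    def test_scores_match_eigendecomposition_oracle(self):
        mat = pd.DataFrame([[1.0, 2.0, 6.0], [4.0, 3.0, 1.0], [2.0, 8.0, 5.0]],
                           index=["f1", "f2", "f3"], columns=["s1", "s2", "s3"])
        res = pca_ordination(mat, log2_pseudocount=None)
        x = mat.to_numpy().T
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        scores_ref = xc @ evecs[:, order]
        for j in range(2):  # rank is n_samples - 1
            got = res.scores.to_numpy()[:, j]
            ref = scores_ref[:, j]
            assert (np.allclose(got, ref, atol=1e-8)
                    or np.allclose(got, -ref, atol=1e-8))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pca_ordination(pd.DataFrame({"only": [1.0, 2.0]}))


class TestEnrichment:
    def test_exact_hypergeometric_value(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        selection = {"g0", "g1", "g2", "g3", "g10", "g11"}  # overlap 4
        out = enrich_terms(selection, universe, {"T": term})
        expected = (math.comb(5, 4) * math.comb(15, 2) + math.comb(5, 5)
                    * math.comb(15, 1)) / math.comb(20, 6)
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(540 / 38760)

    def test_selection_equals_universe(self):
        universe = {f"g{i}" for i in range(10)}
        ann = {"A": {"g0", "g1"}, "B": {"g5"}}
        out = enrich_terms(universe, universe, ann)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_zero_overlap_term(self):
        out = enrich_terms({"g0"}, {"g0", "g1", "g2"}, {"T": {"g1", "g2"}})
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        universe = {f"g{i}" for i in range(30)}
        term = {f"g{i}" for i in range(10)}
        ps = []
        for k in range(1, 6):
            sel = {f"g{i}" for i in range(k)} | {f"g{20 + i}" for i in range(5 - k)}
            ps.append(enrich_terms(sel, universe, {"T": term}).loc[0, "p"])
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_selection_outside_universe(self):
        with pytest.raises(ValueError):
            enrich_terms({"zz"}, {"g0"}, {"T": {"g0"}})


def test_pooled_group_mode_detects_persistent_effect(small_counts):
    counts = small_counts.counts.copy()
    counts.loc["mir-000", ["LR_35E", "LR_49E"]] *= 8  # persistent G1 effect in LR
    from mirnatime.containers import CountMatrix
    res = pooled_group_test(CountMatrix(counts),
                            StageGrouping(g1=("35E",), g2=("49E",)),
                            ("LR", "LT"), PAIRWISE_RULE)
    g1 = res[(res["group"] == "G1") & (res["mirna_id"] == "mir-000")].iloc[0]
    assert g1["significant"] and g1["log2fc"] > 1
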