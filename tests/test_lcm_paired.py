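import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tnbctype.io_formats import ExpressionMatrix
from tnbctype.lcm_paired import (PairedCompartment, compartment_separation,
                                 differential_expression,
                                 overrepresentation_test,
                                 paired_subtype_concordance, read_gmt,
                                 wilcoxon_signed_rank_exact)
from tnbctype.synthetic_data import generate_paired_lcm

# the ten published tumor/stroma call pairs
TABLE3_PAIRS = [
    ("BL1", "MSL"), ("BL1", "MSL"), ("BL1", "MSL"), ("BL1", "MSL"),
    ("BL2", "BL2"), ("M", "BL2"), ("M", "M"), ("MSL", "MSL"),
    ("M", "MSL"), ("LAR", "LAR"),
]


def _pairs(call_pairs):
    return [PairedCompartment(f"P{i}", f"T{i}", f"S{i}", tumor_call=t,
                              stroma_call=s)
            for i, (t, s) in enumerate(call_pairs)]


class TestDifferentialExpression:
    def test_identical_groups_yield_no_hits(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 6)),
                          index=[f"G{i}" for i in range(50)],
                          columns=[f"S{i}" for i in range(6)])
        m = ExpressionMatrix(df)
        out = differential_expression(m, m.sample_ids[:3], m.sample_ids[:3],
                                      paired=True)
        assert int(out["passes"].sum()) == 0

    def test_spiked_genes_recovered_and_nulls_controlled(self):
        sim = generate_paired_lcm(n_pairs=10, n_spiked=50, compartment_fc=2.0,
                                  stroma_msl_boost=0.0, seed=5)
        m = sim["expression"]
        tumor = [p.tumor_profile for p in sim["pairs"]]
        stroma = [p.stroma_profile for p in sim["pairs"]]
        out = differential_expression(m, tumor, stroma, paired=True)
        spiked = set(sim["spiked_genes"])
        hits = set(out.loc[out["passes"], "gene_id"])
        assert len(hits & spiked) >= 45
        assert len(hits - spiked) <= 1

    def test_fold_change_gate_blocks_small_effects(self):
        # a strongly significant gene below the 2-fold gate must not pass
        rng = np.random.default_rng(1)
        df = pd.DataFrame(5.0 + 0.01 * rng.normal(size=(2, 12)),
                          index=["NULL", "SHIFT"],
                          columns=[f"S{i}" for i in range(12)])
        df.loc["SHIFT", df.columns[:6]] += 0.9
        m = ExpressionMatrix(df)
        out = differential_expression(m, m.sample_ids[:6], m.sample_ids[6:],
                                      paired=False).set_index("gene_id")
        assert out.loc["SHIFT", "p_value"] < 1e-6
        assert abs(out.loc["SHIFT", "log2fc"]) < 1.0
        assert not out.loc["SHIFT", "passes"]

    def test_welch_matches_scipy_on_regular_genes(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 11)),
                          index=[f"G{i}" for i in range(20)],
                          columns=[f"S{i}" for i in range(11)])
        m = ExpressionMatrix(df)
        a, b = m.sample_ids[:5], m.sample_ids[5:]
        out = differential_expression(m, a, b, paired=False)
        ref = stats.ttest_ind(df[a], df[b], axis=1, equal_var=False)
        assert np.allclose(out["p_value"], ref.pvalue, atol=1e-10)

    def test_bh_q_values_monotone_in_sorted_p(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 8)),
                          index=[f"G{i}" for i in range(200)],
                          columns=[f"S{i}" for i in range(8)])
        df.iloc[:20, :4] += 2.0
        m = ExpressionMatrix(df)
        out = differential_expression(m, m.sample_ids[:4], m.sample_ids[4:])
        s = out.sort_values("p_value")
        assert np.all(np.diff(s["q_value"].values) >= -1e-12)
        assert np.all(s["q_value"].values >= s["p_value"].values - 1e-12)

    def test_type_i_error_near_nominal_under_global_null(self):
        # 200 null repetitions; per-gene rejection at alpha=0.05 on raw p
        rng = np.random.default_rng(42)
        rates = []
        for _ in range(200):
            df = pd.DataFrame(rng.normal(size=(40, 12)),
                              index=[f"G{i}" for i in range(40)],
                              columns=[f"S{i}" for i in range(12)])
            m = ExpressionMatrix(df)
            out = differential_expression(m, m.sample_ids[:6],
                                          m.sample_ids[6:], paired=True)
            rates.append((out["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_pca_separates_compartments(self):
        # a compartment effect dominating between-patient variation must
        # show up as a positive silhouette on the first two PCs
        sim = generate_paired_lcm(n_pairs=8, compartment_fc=4.0,
                                  stroma_msl_boost=3.0, seed=6)
        res = compartment_separation(
            sim["expression"],
            [p.tumor_profile for p in sim["pairs"]],
            [p.stroma_profile for p in sim["pairs"]])
        assert res["silhouette"] > 0


class TestOverrepresentation:
    def test_disjoint_set_has_p_one(self):
        universe = {f"G{i}" for i in range(30)}
        out = overrepresentation_test({"G1", "G2"}, {"S": {"G20", "G21"}},
                                      universe).set_index("set_name")
        assert out.loc["S", "overlap"] == 0
        assert out.loc["S", "p_value"] == pytest.approx(1.0)

    def test_full_overlap_matches_combinatorial_oracle(self):
        # P(all 5 drawn genes land in a 5-gene set of a 20-gene universe)
        universe = {f"G{i}" for i in range(20)}
        target = {f"G{i}" for i in range(5)}
        out = overrepresentation_test(target, {"S": target}, universe)
        oracle = 1 / math.comb(20, 5)
        assert out["p_value"].iloc[0] == pytest.approx(oracle, rel=1e-9)

    def test_whole_universe_set_has_p_one(self):
        universe = {f"G{i}" for i in range(15)}
        out = overrepresentation_test({"G0", "G1"}, {"ALL": universe}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_tail_matches_enumeration_sum(self):
        universe = {f"G{i}" for i in range(12)}
        gene_set = {f"G{i}" for i in range(4)}
        de = {f"G{i}" for i in range(0, 6)}  # overlap 4
        out = overrepresentation_test(de, {"S": gene_set}, universe)
        k = len(gene_set & de)
        oracle = sum(math.comb(4, j) * math.comb(8, 6 - j) for j in
                     range(k, 5)) / math.comb(12, 6)
        assert out["p_value"].iloc[0] == pytest.approx(oracle, rel=1e-12)

    def test_de_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            overrepresentation_test({"X"}, {}, {"G1"})

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET_A\tdesc\tG1\tG2\nSET_B\tdesc\tg3\n")
        sets = read_gmt(path)
        assert sets == {"SET_A": {"G1", "G2"}, "SET_B": {"G3"}}


class TestConcordance:
    def test_published_call_pairs(self):
        out = paired_subtype_concordance(_pairs(TABLE3_PAIRS))
        assert out["n_pairs"] == 10
        assert out["n_discordant"] == 6
        assert out["n_concordant"] == 4
        assert out["n_discordant_stroma_msl"] == 5

    def test_all_concordant(self):
        out = paired_subtype_concordance(_pairs([("BL1", "BL1")] * 5))
        assert out["n_discordant"] == 0 and out["n_concordant"] == 5

    def test_random_pairs_match_hand_enumeration(self):
        rng = np.random.default_rng(7)
        subtypes = ["BL1", "BL2", "M", "MSL", "LAR", "IM"]
        calls = [(rng.choice(subtypes), rng.choice(subtypes)) for _ in range(7)]
        out = paired_subtype_concordance(_pairs(calls))
        disc = [c for c in calls if c[0] != c[1]]
        assert out["n_discordant"] == len(disc)
        assert out["n_discordant_stroma_msl"] == sum(
            1 for c in disc if c[1] == "MSL")


class TestSignedRank:
    def test_ten_one_sided_pairs_give_two_over_1024(self):
        x = np.arange(1.0, 11.0)
        y = x + np.linspace(0.5, 5.0, 10)  # every y above its x
        out = wilcoxon_signed_rank_exact(x, y)
        assert out["p_value"] == pytest.approx(2 / 1024)
        assert out["exact"]

    def test_symmetric_two_pairs_give_p_one(self):
        out = wilcoxon_signed_rank_exact([1.0, 1.0], [0.0, 2.0])
        assert out["p_value"] == pytest.approx(1.0)

    def test_matches_full_sign_vector_enumeration(self):
        d = np.array([1.3, -0.4, 2.2, 0.9, -3.1])
        x = np.zeros(5)
        out = wilcoxon_signed_rank_exact(x + d, x)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        sums = [np.sum(ranks[list(signs)])
                for r in range(6)
                for signs in itertools.combinations(range(5), r)]
        p_ge = np.mean([s >= w_obs for s in sums])
        p_le = np.mean([s <= w_obs for s in sums])
        oracle = min(1.0, 2 * min(p_ge, p_le))
        assert out["p_value"] == pytest.approx(oracle, rel=1e-12)

    def test_matches_scipy_exact_mode(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        y = x + rng.normal(0.4, 1.0, size=12)
        ours = wilcoxon_signed_rank_exact(x, y)
        ref = stats.wilcoxon(x, y, mode="exact")
        assert ours["p_value"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_zero_differences_flagged(self):
        with pytest.warns(UserWarning, match="zero"):
            out = wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])
        assert out["p_value"] == 1.0 and out["all_zero"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_swap_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = x + rng.normal(0, 1, size=8)
        p_xy = wilcoxon_signed_rank_exact(x, y)["p_value"]
        p_yx = wilcoxon_signed_rank_exact(y, x)["p_value"]
        assert p_xy == pytest.approx(p_yx)
        # cubing differences preserves their rank order and signs
        d = x - y
        p_cubed = wilcoxon_signed_rank_exact(d ** 3, np.zeros(8))["p_value"]
        assert p_xy == pytest.approx(p_cubed)

    def test_stroma_msl_dominance_on_boosted_pairs(self):
        from tnbctype.centroid_subtyping import subtype_samples
        sim = generate_paired_lcm(n_pairs=10, stroma_msl_boost=1.0, seed=5)
        res = {r.sample_id: r for r in
               subtype_samples(sim["expression"], sim["centroids"])}
        tumor_msl = [res[p.tumor_profile].msl_score for p in sim["pairs"]]
        stroma_msl = [res[p.stroma_profile].msl_score for p in sim["pairs"]]
        assert sum(s > t for s, t in zip(stroma_msl, tumor_msl)) >= 9
        out = wilcoxon_signed_rank_exact(tumor_msl, stroma_msl)
        assert out["p_value"] < 0.01
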