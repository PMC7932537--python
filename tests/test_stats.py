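"""Entropy, RP, K-L divergence, selectome thresholding and comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selectome import (
    HexamerSet,
    cluster_naive,
    cluster_probabilities,
    cluster_selection,
    compare_selectomes,
    extract_selectome,
    fold_specificity,
    kl_divergence,
    relative_probability,
    selection_completeness,
    selectome_threshold,
    shannon_entropy,
)
from selectome.stats import ProbabilityTable, RPTable, SelectomeResult


def ptable(probs: dict, mode="selection", total=None):
    s = pd.Series(probs, dtype=float)
    total = total if total is not None else 1000
    return ProbabilityTable(
        probs=s, mode=mode, total_hexamers=total,
        counts=(s * total).round().astype(int),
    )


def rp_from(p_sel: dict, p_naive: dict, total_sel=1000, total_naive=10000):
    return relative_probability(
        ptable(p_sel, "selection", total_sel), ptable(p_naive, "naive", total_naive)
    )


class TestClusterProbabilities:
    def test_sizes_normalize(self):
        hs = HexamerSet(counts={"PANQAG": 1, "LPANQA": 1, "KELANQ": 1}, n_reads_total=3)
        table = cluster_selection(hs)
        p = cluster_probabilities(table)
        assert math.isclose(p.probs.sum(), 1.0)
        # PANQ holds 2 of 3 hexamers, KELA 1 of 3
        assert math.isclose(p.probs["PANQ"], 2 / 3)
        assert math.isclose(p.probs["KELA"], 1 / 3)

    def test_single_cluster_probability_one(self):
        hs = HexamerSet(counts={"AAAAAA": 1}, n_reads_total=1)
        p = cluster_probabilities(cluster_naive(hs))
        assert p.probs.tolist() == [1.0]


class TestShannonEntropy:
    def test_uniform_tetramer_space(self):
        p = np.full(160_000, 1 / 160_000)
        assert shannon_entropy(p) == pytest.approx(17.288, abs=5e-4)

    def test_point_mass_zero(self):
        assert shannon_entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_uniform_four(self):
        assert shannon_entropy(np.full(4, 0.25)) == 2.0

    def test_log20_convention(self):
        assert shannon_entropy(np.full(20, 0.05), base=20) == pytest.approx(1.0)


class TestRelativeProbability:
    def test_non_specific_protease_rp_one(self):
        rp = rp_from({"AAAA": 0.5, "CCCC": 0.5}, {"AAAA": 0.5, "CCCC": 0.5})
        assert rp.df["rp"].tolist() == [1.0, 1.0]

    def test_maximally_specific_rp(self):
        # single substrate against a uniform naive library of 160,000
        sel = ProbabilityTable(pd.Series({"AAAA": 1.0}), "selection", 100)
        idx = [f"t{i}" for i in range(159_999)] + ["AAAA"]
        naive = ProbabilityTable(
            pd.Series(1 / 160_000, index=idx), "naive", 160_000
        )
        rp = relative_probability(sel, naive)
        assert rp.df.at["AAAA", "rp"] == pytest.approx(160_000)

    def test_simple_ratio(self):
        rp = rp_from({"AAAA": 0.5, "CCCC": 0.5}, {"AAAA": 0.25, "CCCC": 0.75})
        assert rp.df.at["AAAA", "rp"] == pytest.approx(2.0)

    def test_absent_from_selection_rp_zero(self):
        rp = rp_from({"AAAA": 1.0}, {"AAAA": 0.5, "CCCC": 0.5})
        assert rp.df.at["CCCC", "rp"] == 0.0
        assert rp.df.at["CCCC", "kl_contrib"] == 0.0

    def test_naive_zero_pseudocounted_and_flagged(self):
        rp = rp_from({"AAAA": 0.9, "DDDD": 0.1}, {"AAAA": 1.0}, total_naive=500)
        assert bool(rp.df.at["DDDD", "pseudocounted"])
        assert rp.df.at["DDDD", "rp"] == pytest.approx(0.1 / (1 / 500))
        assert rp.n_pseudocounted == 1

    def test_empty_naive_rejected(self):
        with pytest.raises(ValueError):
            relative_probability(
                ptable({"AAAA": 1.0}),
                ProbabilityTable(pd.Series(dtype=float), "naive", 0),
            )


class TestKLDivergence:
    def test_point_mass_vs_uniform(self):
        sel = ProbabilityTable(pd.Series({"t0": 1.0}), "selection", 10)
        naive = ProbabilityTable(
            pd.Series(1 / 160_000, index=[f"t{i}" for i in range(160_000)]),
            "naive", 160_000,
        )
        d, _ = kl_divergence(sel, naive)
        assert d == pytest.approx(17.288, abs=5e-4)

    def test_equal_distributions_zero(self):
        p = ptable({"AAAA": 0.3, "CCCC": 0.7})
        d, contrib = kl_divergence(p, p)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert (contrib == 0).all()

    def test_two_term_example(self):
        # 0.5*log2(2) + 0.5*log2(2/3) = 0.20752 bits
        d, _ = kl_divergence(
            ptable({"a": 0.5, "b": 0.5}), ptable({"a": 0.25, "b": 0.75}, "naive")
        )
        assert d == pytest.approx(0.20752, abs=1e-5)

    def test_unpseudocounted_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(ptable({"a": 1.0}), ptable({"b": 1.0}, "naive"))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.01, 10), st.floats(0.01, 10)), min_size=2, max_size=12))
    def test_gibbs_inequality(self, raw):
        ps = np.array([a for a, _ in raw]); ps /= ps.sum()
        pn = np.array([b for _, b in raw]); pn /= pn.sum()
        idx = [f"t{i}" for i in range(len(raw))]
        d, _ = kl_divergence(
            ProbabilityTable(pd.Series(ps, index=idx), "selection", 100),
            ProbabilityTable(pd.Series(pn, index=idx), "naive", 100),
        )
        assert d >= -1e-12


def toy_rp_table(rps, contribs, p_sel=None):
    n = len(rps)
    df = pd.DataFrame(
        {
            "n_sel": [1] * n,
            "n_naive": [1] * n,
            "p_sel": p_sel if p_sel is not None else [1 / n] * n,
            "p_naive": [1 / n] * n,
            "rp": rps,
            "kl_contrib": contribs,
            "pseudocounted": [False] * n,
        },
        index=[f"t{i}" for i in range(n)],
    )
    df["rank"] = df["rp"].rank(ascending=False, method="first").astype(int)
    return RPTable(df=df, total_sel=n, total_naive=n)


class TestSelectomeThreshold:
    def test_running_sum_crossing(self):
        rp = toy_rp_table([0.5, 2.0, 5.0, 9.0], [-0.4, 0.1, 0.3, 1.0])
        assert selectome_threshold(rp) == 5.0

    def test_no_overrepresented_clusters(self):
        rp = toy_rp_table([0.2, 0.9, 1.0], [-0.5, -0.01, 0.0])
        assert selectome_threshold(rp) is None

    def test_two_cluster_crossing_from_distributions(self):
        rp = rp_from({"a": 0.5, "b": 0.5}, {"a": 0.9, "b": 0.1})
        # contributions: -0.424 at RP 0.556, +1.161 at RP 5
        assert selectome_threshold(rp) == pytest.approx(5.0)

    def test_all_positive_mass_thresholds_at_one(self):
        rp = toy_rp_table([3.0, 8.0], [0.2, 0.9])
        assert selectome_threshold(rp) == 1.0

    def test_cumulative_consistency(self):
        """Below the threshold the cumulative contribution is <= 0 and
        within one cluster's contribution of zero."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = rng.integers(3, 30)
            ps = rng.dirichlet(np.ones(k))
            pn = rng.dirichlet(np.ones(k))
            idx = [f"t{i}" for i in range(k)]
            rp = relative_probability(
                ProbabilityTable(pd.Series(ps, index=idx), "selection", 1000),
                ProbabilityTable(pd.Series(pn, index=idx), "naive", 1000),
            )
            thr = selectome_threshold(rp)
            if thr is None:
                continue
            below = rp.df[(rp.df["rp"] < thr) & (rp.df["p_sel"] > 0)]
            at = rp.df[rp.df["rp"] == thr]
            total_below = below["kl_contrib"].sum()
            assert total_below <= 1e-12
            assert total_below + at["kl_contrib"].sum() >= -1e-12


class TestExtractSelectome:
    def test_none_threshold_gives_empty_selectome(self):
        rp = toy_rp_table([0.5, 0.8], [-0.3, -0.1])
        res = extract_selectome(rp, None)
        assert res.selectome == set()

    def test_strict_inequality_at_threshold(self):
        rp = toy_rp_table([0.5, 2.0, 5.0, 9.0], [-0.4, 0.1, 0.3, 1.0])
        res = extract_selectome(rp, 5.0)
        assert res.selectome == {"t3"}
        assert res.n_hexamers_in == 1 and res.n_hexamers_out == 3

    def test_entropies_and_divergence_reported(self):
        rp = rp_from({"a": 0.5, "b": 0.5}, {"a": 0.9, "b": 0.1})
        res = extract_selectome(rp, selectome_threshold(rp))
        assert res.h_selection == pytest.approx(1.0)
        assert res.d_kl == pytest.approx(-0.424 + 1.161, abs=1e-3)


class TestFoldSpecificity:
    @pytest.mark.parametrize(
        "h_obs,h_ref,base,expected",
        [
            (13.93, 17.288, 2, 10.25),
            (13.67, 17.288, 2, 12.28),
            (7.386, 8.0, 20, 6.29),
            (7.078, 8.0, 20, 15.83),
        ],
    )
    def test_reference_ratios(self, h_obs, h_ref, base, expected):
        assert fold_specificity(h_obs, h_ref, base=base) == pytest.approx(
            expected, rel=5e-3
        )

    def test_identity(self):
        assert fold_specificity(3.3, 3.3) == 1.0

    def test_negative_entropy_rejected(self):
        with pytest.raises(ValueError):
            fold_specificity(-1.0, 2.0)
        with pytest.raises(ValueError):
            fold_specificity(3.0, 2.0)


class TestCompareSelectomes:
    def _res(self, members):
        return SelectomeResult(
            rp_threshold=1.0, selectome=set(members), h_selection=0, h_naive=0,
            d_kl=0, n_clusters_total=len(members), n_clusters_selectome=len(members),
            n_hexamers_in=0, n_hexamers_out=0,
        )

    def test_disjoint(self):
        cmp = compare_selectomes(self._res({"AAAA"}), self._res({"CCCC"}))
        assert cmp.shared == set()

    def test_identical(self):
        cmp = compare_selectomes(self._res({"AAAA", "CCCC"}), self._res({"AAAA", "CCCC"}))
        assert cmp.unique_a == set() and cmp.unique_b == set()

    def test_shared_fraction(self):
        a = {f"a{i}" for i in range(4019)} | {f"s{i}" for i in range(3902)}
        b = {f"b{i}" for i in range(2189)} | {f"s{i}" for i in range(3902)}
        cmp = compare_selectomes(self._res(a), self._res(b))
        assert cmp.combined_size == 10_110
        assert cmp.fractions()["shared"] == pytest.approx(0.386, abs=1e-3)


class TestSelectionCompleteness:
    def test_reference_conditions(self):
        assert selection_completeness(3289, 200e-9, 7200) == pytest.approx(0.991, abs=1e-3)

    def test_zero_rate(self):
        assert selection_completeness(0, 200e-9, 7200) == 0.0

    def test_closed_form(self):
        assert selection_completeness(1000, 200e-9, 3600) == pytest.approx(
            1 - math.exp(-0.72)
        )


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.floats(0.01, 5), st.floats(0.01, 5)), min_size=2, max_size=10))
def test_normalization_duality(raw):
    """Sum over clusters of P_NL(t) * RP(t) equals 1 when no pseudocounts
    are involved (both distributions share support)."""
    ps = np.array([a for a, _ in raw]); ps /= ps.sum()
    pn = np.array([b for _, b in raw]); pn /= pn.sum()
    idx = [f"t{i}" for i in range(len(raw))]
    rp = relative_probability(
        ProbabilityTable(pd.Series(ps, index=idx), "selection", 100),
        ProbabilityTable(pd.Series(pn, index=idx), "naive", 100),
    )
    assert not rp.df["pseudocounted"].any()
    assert (rp.df["p_naive"] * rp.df["rp"]).sum() == pytest.approx(1.0)
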