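import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import syntropy as sy
from syntropy.network import InteromicNetwork


def _net(x: pd.DataFrame, y: pd.DataFrame) -> InteromicNetwork:
    return sy.spearman_all_pairs(x, y)


def _frame(cols: dict, n: int) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


class TestSpearmanAllPairs:
    def test_identical_vectors_give_rho_one(self):
        v = [0.1, 0.5, 0.3, 0.9, 0.2, 0.7, 0.4, 0.6, 0.8, 1.0]
        net = _net(_frame({"o": v}, 10), _frame({"m": v}, 10))
        assert net.edges.loc[0, "rho"] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=12)
        y = rng.normal(size=12)
        raw = _net(_frame({"o": v}, 12), _frame({"m": y}, 12))
        trans = _net(_frame({"o": v}, 12), _frame({"m": np.exp(3 * y)}, 12))
        assert raw.edges.loc[0, "rho"] == pytest.approx(trans.edges.loc[0, "rho"])
        assert raw.edges.loc[0, "p"] == pytest.approx(trans.edges.loc[0, "p"])

    def test_tied_toy_matches_midrank_pearson_oracle(self):
        # 6 samples with one tie in y; oracle = Pearson on midranks, written out
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 2.0, 3.0, 1.0, 5.0, 4.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        net = _net(_frame({"o": x}, 6), _frame({"m": y}, 6))
        assert net.edges.loc[0, "rho"] == pytest.approx(oracle, abs=1e-12)
        # exact permutation p agrees with scipy's spearmanr direction
        assert 0 < net.edges.loc[0, "p"] <= 1

    def test_small_sample_p_is_exact_permutation_tail(self):
        # n=5, no ties: compare against full enumeration via scipy distribution
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        net = _net(_frame({"o": x}, 5), _frame({"m": y}, 5))
        import itertools

        rhos = [np.corrcoef(x, perm)[0, 1] for perm in itertools.permutations(y)]
        obs = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        expected = np.mean([abs(r) >= abs(obs) - 1e-12 for r in rhos])
        assert net.edges.loc[0, "p"] == pytest.approx(expected)

    def test_too_few_shared_samples_is_an_error(self):
        with pytest.raises(ValueError, match="4"):
            _net(_frame({"o": [1, 2, 3]}, 3), _frame({"m": [1, 2, 3]}, 3))

    def test_zero_variance_pairs_are_excluded_and_counted(self):
        net = _net(_frame({"o": [1, 2, 3, 4, 5]}, 5),
                   _frame({"flat": [2, 2, 2, 2, 2], "ok": [5, 3, 1, 2, 4]}, 5))
        assert net.n_excluded == 1
        assert set(net.edges["analyte_id"]) == {"ok"}
        assert np.isnan(net.rho_matrix.loc["o", "flat"])


class TestQvalues:
    def test_all_ones_stay_one(self):
        assert np.allclose(sy.qvalues(np.ones(8)), 1.0)

    def test_bh_equivalence_when_pi0_forced_to_one(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.02, 0.03, 0.04, 0.2, 0.5, 0.6, 0.7, 0.9, 1.0])
        q = sy.qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sy.qvalues([0.5, 0.0])
        with pytest.raises(ValueError):
            sy.qvalues([0.5, 1.2])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=40))
    def test_order_preserving_and_permutation_invariant(self, p):
        p = np.asarray(p)
        q = sy.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q2 = sy.qvalues(p[perm])
        assert np.allclose(np.sort(q), np.sort(q2))
        assert np.all(q <= 1.0 + 1e-12)


class TestSignificantEdges:
    def _net_with_q(self, qs):
        edges = pd.DataFrame({"otu_id": [f"o{i}" for i in range(len(qs))],
                              "analyte_id": [f"m{i}" for i in range(len(qs))],
                              "rho": 0.5, "p": 0.01, "q": qs})
        return InteromicNetwork(edges, pd.DataFrame(), n_samples=10)

    def test_threshold_is_strict(self):
        net = self._net_with_q([0.19, 0.20, 0.21])
        kept = sy.significant_edges(net, 0.2)
        assert list(kept.edges["q"]) == [0.19]

    def test_empty_input_gives_empty_output(self):
        net = self._net_with_q([])
        assert len(sy.significant_edges(net, 0.2)) == 0

    def test_default_threshold_is_point_two(self):
        import inspect

        assert inspect.signature(sy.significant_edges).parameters["q_max"].default == 0.2


class TestGenusBinning:
    def _sig_net(self, rows):
        edges = pd.DataFrame(rows, columns=["otu_id", "analyte_id"])
        edges["rho"] = 0.5
        edges["p"] = 0.01
        edges["q"] = 0.05
        return InteromicNetwork(edges, pd.DataFrame(), n_samples=10)

    def test_duplicate_metabolite_collapses_to_single_interaction(self):
        tax = pd.Series({f"o{i}": "k__;p__F;c__;o__;f__;g__Blautia;s__" for i in range(3)})
        net = self._sig_net([(f"o{i}", "met1") for i in range(3)])
        out = sy.bin_by_genus(net, tax)
        assert out.loc["Blautia", "n_unique_metabolites"] == 1

    def test_distinct_metabolites_counted_and_unresolved_excluded(self):
        tax = pd.Series({"o1": "k__;p__F;c__;o__;f__;g__Roseburia;s__",
                         "o2": "k__;p__F;c__;o__;f__;g__;s__"})
        net = self._sig_net([("o1", "m1"), ("o1", "m2"), ("o1", "m3"), ("o2", "m1")])
        out = sy.bin_by_genus(net, tax)
        assert out.loc["Roseburia", "n_unique_metabolites"] == 3
        assert len(out) == 1  # the g__-only OTU contributes no genus row

    def test_counts_equal_brute_force_set_unions(self):
        rng = np.random.default_rng(1)
        genera = ["Blautia", "Roseburia", "Bacteroides"]
        tax = pd.Series({f"o{i}": f"k__;p__F;c__;o__;f__;g__{genera[i % 3]};s__"
                         for i in range(9)})
        rows = [(f"o{rng.integers(9)}", f"m{rng.integers(6)}") for _ in range(30)]
        net = self._sig_net(sorted(set(rows)))
        out = sy.bin_by_genus(net, tax)
        brute: dict = {}
        for o, m in set(rows):
            g = genera[int(o[1:]) % 3]
            brute.setdefault(g, set()).add(m)
        for g, mets in brute.items():
            assert out.loc[g, "n_unique_metabolites"] == len(mets)


class TestNetworkSummary:
    def test_empty_network(self):
        net = InteromicNetwork(pd.DataFrame(columns=["otu_id", "analyte_id", "rho", "p", "q"]),
                               pd.DataFrame(), n_samples=10)
        tax = pd.Series({"o1": "k__;p__Firmicutes;c__;o__;f__;g__;s__"})
        summ = sy.summarize_network(net, ["o1"], tax)
        assert summ.total_edges == 0
        assert summ.per_phylum_ratio["Firmicutes"] == 0.0
        assert summ.mean_edges_per_otu == 0.0

    def test_phylum_ratio_counts_otus_with_any_edge(self):
        tax = pd.Series({f"o{i}": "k__;p__Firmicutes;c__;o__;f__;g__;s__" for i in range(10)})
        edges = pd.DataFrame({"otu_id": ["o0", "o0", "o1", "o2"],
                              "analyte_id": ["m1", "m2", "m1", "m3"],
                              "rho": 0.4, "p": 0.01, "q": 0.1})
        net = InteromicNetwork(edges, pd.DataFrame(), n_samples=10)
        summ = sy.summarize_network(net, list(tax.index), tax)
        assert summ.per_phylum_ratio["Firmicutes"] == pytest.approx(0.30)
        assert summ.mean_edges_per_analyte == pytest.approx(
            summ.total_edges / summ.unique_analyte_nodes)
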