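import numpy as np
import pandas as pd
import pytest
from scipy import stats

import syntropy as sy
from syntropy.network import InteromicNetwork


class TestSingleCountConvention:
    def test_three_otus_give_identity_matrix(self):
        table = sy.single_count_profile_convention(["a", "b", "c"])
        assert np.array_equal(table.counts.to_numpy(), np.eye(3, dtype=int))

    def test_row_sums_all_one(self):
        table = sy.single_count_profile_convention([f"o{i}" for i in range(5)])
        assert (table.counts.sum(axis=1) == 1).all()

    def test_round_trips_through_table_io(self, tmp_path):
        table = sy.single_count_profile_convention(["x", "y"])
        path = tmp_path / "single.tsv"
        sy.write_otu_table(table, path)
        assert sy.read_otu_table(path) == table


def _assignment(groups: dict) -> sy.ClusterAssignment:
    labels = {}
    for c, members in groups.items():
        for m in members:
            labels[m] = c
    s = pd.Series(labels)
    return sy.ClusterAssignment(s, k=len(groups))


class TestClusterPathwayTests:
    def test_identical_abundances_give_zero_h(self):
        pp = sy.PathwayProfile(pd.DataFrame({"PWY1": [0.5] * 9},
                                            index=[f"o{i}" for i in range(9)]))
        ca = _assignment({1: [f"o{i}" for i in range(3)],
                          2: [f"o{i}" for i in range(3, 6)],
                          3: [f"o{i}" for i in range(6, 9)]})
        out = sy.cluster_pathway_tests(pp, ca)
        assert out.loc["PWY1", "H"] == 0.0
        assert not out.loc["PWY1", "significant"]

    def test_three_group_toy_matches_rank_sum_formula(self):
        vals = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        pp = sy.PathwayProfile(pd.DataFrame({"PWY1": vals},
                                            index=[f"o{i}" for i in range(9)]))
        ca = _assignment({1: [f"o{i}" for i in range(3)],
                          2: [f"o{i}" for i in range(3, 6)],
                          3: [f"o{i}" for i in range(6, 9)]})
        out = sy.cluster_pathway_tests(pp, ca)
        # brute force: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2, no ties
        ranks = stats.rankdata(vals)
        N = 9
        rbar = ranks.mean()
        h = 12 / (N * (N + 1)) * sum(
            3 * (ranks[i:i + 3].mean() - rbar) ** 2 for i in (0, 3, 6))
        assert out.loc["PWY1", "H"] == pytest.approx(h, abs=1e-12)
        # direction flags: lowest-rank cluster depleted, highest enriched
        assert out.loc["PWY1", "cluster_1"] == -1
        assert out.loc["PWY1", "cluster_3"] == 1

    def test_bonferroni_runs_over_pathways(self):
        rng = np.random.default_rng(0)
        pp = sy.PathwayProfile(pd.DataFrame(
            rng.uniform(size=(12, 4)), index=[f"o{i}" for i in range(12)],
            columns=[f"PWY{i}" for i in range(4)]))
        ca = _assignment({1: [f"o{i}" for i in range(6)],
                          2: [f"o{i}" for i in range(6, 12)]})
        out = sy.cluster_pathway_tests(pp, ca)
        assert np.allclose(out["p_bonferroni"], np.minimum(1.0, out["p"] * 4))

    def test_small_cluster_excluded(self):
        pp = sy.PathwayProfile(pd.DataFrame({"PWY1": np.arange(7.0)},
                                            index=[f"o{i}" for i in range(7)]))
        ca = _assignment({1: [f"o{i}" for i in range(3)],
                          2: [f"o{i}" for i in range(3, 6)],
                          3: ["o6"]})
        out = sy.cluster_pathway_tests(pp, ca)  # cluster 3 dropped, test proceeds
        assert "cluster_3" not in out.columns


class TestMetaboliteMetagenomeConcordance:
    def _nets(self, rho: pd.DataFrame, support: dict):
        rows = []
        for analyte, n in support.items():
            for otu in rho.index[:n]:
                rows.append({"otu_id": otu, "analyte_id": analyte,
                             "rho": rho.loc[otu, analyte], "p": 1e-4, "q": 0.01})
        edges = pd.DataFrame(rows, columns=["otu_id", "analyte_id", "rho", "p", "q"])
        net = InteromicNetwork(edges, rho, n_samples=20)
        return net, net

    def test_proportional_vectors_give_r_one_and_positive_category(self):
        otus = [f"o{i}" for i in range(8)]
        rng = np.random.default_rng(1)
        rho = pd.DataFrame({"met1": rng.uniform(-1, 1, 8)}, index=otus)
        pp = sy.PathwayProfile(pd.DataFrame({"PWY1": 0.4 * rho["met1"] + 0.5}, index=otus))
        sig, full = self._nets(rho, {"met1": 5})
        out = sy.metabolite_metagenome_concordance(
            sig, full, pp, {"met1": [("cmpd", "PWY1")]})
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert out.loc[0, "category"] == "positive"

    def test_minimum_support_boundary_is_five(self):
        otus = [f"o{i}" for i in range(8)]
        rho = pd.DataFrame({"met4": np.linspace(-1, 1, 8),
                            "met5": np.linspace(1, -1, 8)}, index=otus)
        pp = sy.PathwayProfile(pd.DataFrame({"PWY1": np.arange(8.0)}, index=otus))
        sig, full = self._nets(rho, {"met4": 4, "met5": 5})
        id_map = {"met4": [("c", "PWY1")], "met5": [("c", "PWY1")]}
        out = sy.metabolite_metagenome_concordance(sig, full, pp, id_map)
        assert set(out["metabolite_id"]) == {"met5"}

    def test_r_matches_brute_force_covariance_formula(self):
        otus = [f"o{i}" for i in range(6)]
        a = np.array([0.2, -0.1, 0.6, 0.4, -0.5, 0.3])
        b = np.array([1.0, 0.4, 2.0, 1.1, 0.2, 1.5])
        rho = pd.DataFrame({"met1": a}, index=otus)
        pp = sy.PathwayProfile(pd.DataFrame({"PWY1": b}, index=otus))
        sig, full = self._nets(rho, {"met1": 5})
        out = sy.metabolite_metagenome_concordance(sig, full, pp, {"met1": [("c", "PWY1")]})
        expected = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert out.loc[0, "pearson_r"] == pytest.approx(expected, abs=1e-12)

    def test_missing_pathway_skipped_and_categories_partition(self):
        otus = [f"o{i}" for i in range(10)]
        rng = np.random.default_rng(2)
        rho = pd.DataFrame(rng.uniform(-1, 1, size=(10, 3)),
                           index=otus, columns=["m1", "m2", "m3"])
        pp = sy.PathwayProfile(pd.DataFrame(rng.uniform(size=(10, 2)), index=otus,
                                            columns=["PWY1", "PWY2"]))
        sig, full = self._nets(rho, {"m1": 5, "m2": 6, "m3": 7})
        id_map = {"m1": [("c1", "PWY1")], "m2": [("c2", "MISSING")],
                  "m3": [("c3", "PWY1"), ("c3", "PWY2")]}
        out = sy.metabolite_metagenome_concordance(sig, full, pp, id_map)
        assert "MISSING" not in set(out["pathway_id"])
        counts = out["category"].value_counts()
        assert counts.sum() == len(out)

    def test_planted_pathway_links_recovered_positive(self, small_bundle):
        """On synthetic data where the pathway profile is a monotone function
        of the planted link effects, planted pairs come out 'positive'."""
        b1, _, truth = small_bundle
        an = np.log(b1.metabolites.intensities + 1.0)
        net = sy.add_qvalues(sy.spearman_all_pairs(b1.otus, an))
        sig = sy.significant_edges(net, 0.2)
        fmap = truth.feature_map["cecum"]
        id_map = {fmap[ident]: [("planted", pw)]
                  for ident, pw in truth.pathway_link.itertuples(index=False)}
        out = sy.metabolite_metagenome_concordance(
            sig, net, b1.pathways, id_map, min_otus=1)
        assert len(out) > 0
        assert (out["pearson_r"] > 0).mean() > 0.7
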