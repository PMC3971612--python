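import numpy as np
import pandas as pd
import pytest

import syntropy as sy


def _compositional_counts(n=60, d=20, depth=20_000, corr_pair=None, rho=0.8, seed=0):
    """Log-normal basis + multinomial counts, optionally one correlated pair."""
    rng = np.random.default_rng(seed)
    C = np.eye(d)
    if corr_pair is not None:
        i, j = corr_pair
        C[i, j] = C[j, i] = rho
    mu = rng.normal(0, 1.0, size=d)
    z = mu + rng.standard_normal((n, d)) @ np.linalg.cholesky(C).T
    frac = np.exp(z - z.max(axis=1, keepdims=True))
    frac /= frac.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in frac])
    return pd.DataFrame(counts, index=[f"s{i}" for i in range(n)],
                        columns=[f"o{i}" for i in range(d)])


class TestSparcc:
    def test_diagonal_is_exactly_one(self):
        res = sy.sparcc(_compositional_counts(n=30, d=8), seed=0)
        assert np.allclose(np.diag(res.correlation), 1.0)
        c = res.correlation.to_numpy()
        assert np.allclose(c, c.T)
        assert (np.abs(c) <= 1.0).all()

    def test_underdetermined_inputs_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            sy.sparcc(_compositional_counts(n=30, d=8).iloc[:, :3])
        with pytest.raises(ValueError):
            sy.sparcc(_compositional_counts(n=6, d=8))

    def test_seeded_determinism_and_sample_permutation_invariance(self):
        counts = _compositional_counts(n=40, d=10, seed=1)
        r1 = sy.sparcc(counts, seed=5)
        r2 = sy.sparcc(counts, seed=5)
        assert np.allclose(r1.correlation, r2.correlation)
        # permuting sample rows changes only the Dirichlet draws, so the
        # estimate agrees up to that Monte-Carlo noise
        perm = np.random.default_rng(0).permutation(len(counts))
        r3 = sy.sparcc(counts.iloc[perm], seed=5)
        diff = (r1.correlation - r3.correlation).to_numpy()
        assert np.abs(diff).max() < 0.2
        assert np.abs(diff).mean() < 0.05

    def test_independent_basis_yields_small_correlations(self):
        counts = _compositional_counts(n=100, d=50, seed=2)
        res = sy.sparcc(counts, seed=0)
        c = res.correlation.to_numpy()
        off = c[~np.eye(50, dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_planted_basis_correlation_recovered(self):
        counts = _compositional_counts(n=100, d=20, corr_pair=(0, 1), rho=0.8, seed=3)
        res = sy.sparcc(counts, seed=0)
        assert res.correlation.iloc[0, 1] > 0.5
        assert res.basis_variance.min() > 0


class TestGroupStructureTest:
    def test_planted_co_exclusion_structure_is_significant(self):
        """Two anti-correlated guilds sharing a metabolite (the co-exclusion
        pattern) show significantly stronger positive and negative structure
        than random same-size OTU groups."""
        cfg = sy.SynthConfig(seed=4, n_subjects=46, n_otus=120, n_metabolites=30,
                             n_modules=0, n_planted_links=0, n_guilds=2,
                             guild_size=5, guild_corr=0.7, guild_cross_corr=-0.6,
                             read_depth_mean=20_000, shared_metabolite_fraction=0.8)
        b1, _, truth = sy.generate_paired_dataset(cfg)
        group = list(truth.guild_assignment.index)
        res = sy.group_structure_test(b1.otus.counts, group, n_perm=99, seed=0,
                                      group_id="co_exclusion")
        assert res.p_mean_pos <= 0.05
        assert res.p_mean_neg <= 0.05
        assert res.mean_pos >= 0 >= res.mean_neg

    def test_pvalues_never_zero_and_floor_respected(self):
        counts = _compositional_counts(n=30, d=15, seed=5)
        res = sy.group_structure_test(counts, [f"o{i}" for i in range(5)],
                                      n_perm=19, seed=1)
        for p in (res.p_mean_pos, res.p_mean_neg, res.p_above, res.p_below):
            assert 1 / 20 <= p <= 1.0

    def test_ordered_pair_counts_are_even(self):
        counts = _compositional_counts(n=30, d=15, seed=6)
        res = sy.group_structure_test(counts, [f"o{i}" for i in range(6)],
                                      n_perm=9, seed=2)
        assert res.n_above % 2 == 0
        assert res.n_below % 2 == 0

    def test_small_group_rejected(self):
        counts = _compositional_counts(n=30, d=10)
        with pytest.raises(ValueError):
            sy.group_structure_test(counts, ["o0", "o1", "o2"], n_perm=9)


class TestAssociationType:
    @pytest.mark.parametrize("rhos,expected", [
        ([0.3, 0.5, 0.1], "all positive"),
        ([-0.3, -0.5], "all negative"),
        ([0.4, 0.5, -0.2], "mostly positive"),
        ([-0.4, -0.5, 0.2], "mostly negative"),
        ([0.4, -0.2], "50% negative, 50% positive"),
    ])
    def test_labelling_rules(self, rhos, expected):
        assert sy.association_type(rhos) == expected

    def test_thirty_seventy_split_gets_percentages(self):
        rhos = [0.4] * 7 + [-0.3] * 19  # ~27% positive, 73% negative: mostly
        assert sy.association_type(rhos) == "mostly negative"
        rhos = [0.4] * 10 + [-0.3] * 16  # 38% / 62%: percentage label
        assert sy.association_type(rhos) == "62% negative, 38% positive"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sy.association_type([])


class TestTaxonomyCladogram:
    def test_shared_lineage_shortens_induced_subtree(self):
        tax = pd.Series({
            "a": "k__Bacteria;p__F;c__C;o__O;f__Fam;g__G;s__",
            "b": "k__Bacteria;p__F;c__C;o__O;f__Fam;g__G;s__",
            "c": "k__Bacteria;p__B;c__C2;o__O2;f__Fam2;g__G2;s__",
        })
        newick = sy.taxonomy_cladogram(tax)
        # same full lineage: MRCA is the genus node, two unit tip edges
        assert sy.total_branch_length(newick, ["a", "b"]) == pytest.approx(2.0)
        # different phylum: each tip sits 6 unit edges below the kingdom MRCA
        assert sy.total_branch_length(newick, ["a", "c"]) == pytest.approx(12.0)

    def test_unresolved_ranks_attach_near_root(self):
        tax = pd.Series({"a": "k__Bacteria;p__F;c__;o__;f__;g__;s__",
                         "b": "k__Bacteria;p__B;c__;o__;f__;g__;s__"})
        newick = sy.taxonomy_cladogram(tax)
        assert sy.total_branch_length(newick, ["a", "b"]) == pytest.approx(4.0)


class TestTotalBranchLength:
    def test_hand_computed_induced_subtree(self):
        assert sy.total_branch_length("(A:1,(B:2,C:3):4);", ["B", "C"]) == pytest.approx(5.0)

    def test_single_tip_is_zero(self):
        assert sy.total_branch_length("(A:1,(B:2,C:3):4);", ["B"]) == 0.0

    def test_all_tips_equals_total_tree_length(self):
        newick = "((A:1,B:2):0.5,(C:3,D:4):1.5);"
        assert sy.total_branch_length(newick, list("ABCD")) == pytest.approx(12.0)

    def test_missing_tip_named_in_error(self):
        with pytest.raises(ValueError, match="ZZZ"):
            sy.total_branch_length("(A:1,B:2);", ["A", "ZZZ"])
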