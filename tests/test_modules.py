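import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import syntropy as sy
from syntropy.modules import DEFAULT_POWERS, UNCLUSTERED, scale_free_fit, soft_adjacency


def _planted_blocks(sizes, n_samples=60, within=0.9, seed=0, n_noise=0):
    """Block-correlated metabolite matrix plus its true labels."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for b, size in enumerate(sizes):
        factor = rng.standard_normal(n_samples)
        for _ in range(size):
            cols.append(np.sqrt(within) * factor + np.sqrt(1 - within) * rng.standard_normal(n_samples))
            labels.append(f"block{b}")
    for _ in range(n_noise):
        cols.append(rng.standard_normal(n_samples))
        labels.append("noise")
    x = pd.DataFrame(np.column_stack(cols),
                     columns=[f"met{i}" for i in range(len(cols))])
    return x, pd.Series(labels, index=x.columns)


class TestSoftThreshold:
    def test_power_one_adjacency_equals_absolute_pearson(self):
        x, _ = _planted_blocks([2], n_samples=30)
        a = soft_adjacency(x, power=1)
        expected = abs(np.corrcoef(x.to_numpy(), rowvar=False)[0, 1])
        assert a.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_candidate_grid_admits_the_canonical_choices(self):
        assert 22 in DEFAULT_POWERS and 32 in DEFAULT_POWERS

    def test_fit_index_matches_brute_force_regression(self):
        # oracle: bin k, regress log10 freq on log10 mean-k directly
        rng = np.random.default_rng(3)
        k = rng.gamma(2.0, 2.0, size=200)
        n_bins = 10
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        lk, lp = [], []
        for b in range(n_bins):
            m = idx == b
            if m.sum():
                lk.append(np.log10(k[m].mean()))
                lp.append(np.log10(m.mean()))
        slope, inter = np.polyfit(lk, lp, 1)
        pred = slope * np.asarray(lk) + inter
        r2 = 1 - np.sum((np.asarray(lp) - pred) ** 2) / np.sum((np.asarray(lp) - np.mean(lp)) ** 2)
        expected = -r2 if slope > 0 else r2
        assert scale_free_fit(k) == pytest.approx(expected, abs=1e-12)

    def test_requires_ten_metabolites(self):
        x, _ = _planted_blocks([5])
        with pytest.raises(ValueError):
            sy.pick_soft_threshold(x)

    def test_returns_smallest_power_meeting_target(self):
        x, _ = _planted_blocks([10, 10], n_samples=80, within=0.85, seed=1)
        power, fit = sy.pick_soft_threshold(x)
        reached = fit[fit["fit_r2"] >= 0.8]
        if len(reached):
            assert power == reached["power"].iloc[0]
        else:
            assert power == fit.loc[fit["fit_r2"].idxmax(), "power"]


class TestTomDissimilarity:
    def test_empty_adjacency_gives_unit_dissimilarity(self):
        d = sy.tom_dissimilarity(np.zeros((4, 4)))
        off = d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(d), 0.0)

    def test_perfect_clique_gives_zero_dissimilarity(self):
        a = np.ones((3, 3)) - np.eye(3)
        d = sy.tom_dissimilarity(a)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_matches_elementwise_formula_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, size=(5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        d = sy.tom_dissimilarity(a)
        k = a.sum(axis=1)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                L = sum(a[i, u] * a[u, j] for u in range(5))
                tom = (L + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert d[i, j] == pytest.approx(1 - tom, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            sy.tom_dissimilarity(a)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        x, truth = _planted_blocks([12, 13], n_samples=80, within=0.9, seed=2)
        ms = sy.build_modules(x, power=6, min_size=10)
        assert len(ms.module_labels) == 2
        assert adjusted_rand_score(truth, ms.assignment) == pytest.approx(1.0)

    def test_fewer_metabolites_than_min_size_all_unclustered(self):
        x, _ = _planted_blocks([9], n_samples=40)
        ms = sy.build_modules(x, power=6, min_size=10)
        assert (ms.assignment == UNCLUSTERED).all()

    def test_default_min_size_is_ten(self):
        import inspect

        assert inspect.signature(sy.detect_modules).parameters["min_size"].default == 10

    def test_partition_invariant_to_column_permutation(self):
        x, _ = _planted_blocks([12, 14], n_samples=60, within=0.85, seed=4, n_noise=5)
        ms1 = sy.build_modules(x, power=6)
        perm = np.random.default_rng(0).permutation(x.shape[1])
        ms2 = sy.build_modules(x.iloc[:, perm], power=6)
        aligned = ms2.assignment.reindex(ms1.assignment.index)
        assert adjusted_rand_score(ms1.assignment, aligned) == pytest.approx(1.0)
        assert list(ms1.assignment.sort_index()) == list(aligned.sort_index())


class TestEigenmetabolite:
    def test_identical_members_reproduce_the_profile(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(20)
        x = pd.DataFrame({"a": v, "b": v, "c": v})
        profile, ve = sy.eigenmetabolite(x)
        assert ve == pytest.approx(1.0)
        assert abs(np.corrcoef(profile, v)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(profile, v)[0, 1] > 0  # orientation rule
        assert np.linalg.norm(profile) == pytest.approx(1.0)

    def test_sign_flip_of_members_respects_orientation_contract(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.standard_normal((15, 4)))
        p1, _ = sy.eigenmetabolite(x)
        p2, _ = sy.eigenmetabolite(-x)
        assert np.allclose(np.abs(p1), np.abs(p2), atol=1e-10)
        # both orientations have positive mean member correlation
        for prof, mat in ((p1, x), (p2, -x)):
            corrs = [np.corrcoef(prof, mat[c])[0, 1] for c in mat]
            assert np.mean(corrs) > 0

    def test_matches_full_svd_oracle(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.standard_normal((4, 3)))
        profile, ve = sy.eigenmetabolite(x)
        z = (x - x.mean()) / x.std(ddof=0)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        assert ve == pytest.approx(s[0] ** 2 / (s ** 2).sum(), abs=1e-10)
        assert np.allclose(np.abs(profile), np.abs(u[:, 0]), atol=1e-10)

    def test_degenerate_modules_rejected(self):
        with pytest.raises(ValueError):
            sy.eigenmetabolite(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="constant"):
            sy.eigenmetabolite(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestValidationAndCombine:
    def test_separated_blocks_validate_cleanly(self):
        x, _ = _planted_blocks([12, 13], n_samples=80, within=0.9, seed=5)
        ms = sy.build_modules(x, power=6)
        val = sy.validate_modules(ms, x)
        assert val.mean_silhouette > 0
        assert val.kmeans_agreement == pytest.approx(1.0)
        assert val.plain_hclust_agreement == pytest.approx(1.0)
        assert 0 < val.cophenetic_corr <= 1

    def test_zero_modules_passes_input_through(self):
        x, _ = _planted_blocks([9], n_samples=30)
        ms = sy.build_modules(x, power=6, min_size=10)
        combined = sy.combine_with_unclustered(ms, x)
        assert combined.shape == x.shape
        assert list(combined.columns) == list(x.columns)

    def test_column_count_is_modules_plus_unclustered(self):
        x, _ = _planted_blocks([12, 13], n_samples=60, within=0.9, seed=6, n_noise=7)
        ms = sy.build_modules(x, power=6)
        combined = sy.combine_with_unclustered(ms, x)
        n_unclustered = int((ms.assignment == UNCLUSTERED).sum())
        assert combined.shape[1] == len(ms.module_labels) + n_unclustered

    def test_variance_explained_in_unit_interval(self):
        x, _ = _planted_blocks([12], n_samples=40, within=0.8, seed=8)
        ms = sy.build_modules(x, power=6)
        for ve in ms.variance_explained.values():
            assert 0 < ve <= 1
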