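"""Metabolite-driven microbial clustering.

OTUs are described by their full (unthresholded) Spearman correlation profile
against analytes that carry at least a minimum number of significant OTU
edges, then grouped by complete-linkage hierarchical clustering on Euclidean
distances. The cluster number is chosen by prediction strength (repeated
2-fold splits scored with k-means), and cluster composition can be compared
across paired regions with one-sided Fisher exact tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from . import io as _io
from ._utils import get_rng, logger
from .network import InteromicNetwork


@dataclass
class ClusterAssignment:
    labels: pd.Series  # otu_id -> cluster index 1..k
    k: int
    linkage: np.ndarray | None = None
    cut_height: float = np.nan

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def correlation_profile_matrix(net_full: InteromicNetwork, net_significant: InteromicNetwork,
                               min_significant_otus: int = 2) -> pd.DataFrame:
    """OTU x analyte matrix of raw rho, columns filtered by edge support.

    Keeps analytes with >= ``min_significant_otus`` significant OTU edges;
    cells are the unthresholded correlations. Undefined cells (zero-variance
    pairs) are imputed as 0 with a logged count, since Euclidean clustering
    needs complete rows.
    """
    support = net_significant.edges.groupby("analyte_id")["otu_id"].nunique()
    keep = support[support >= min_significant_otus].index
    if len(keep) == 0:
        raise ValueError("no analytes pass the significant-edge filter")
    mat = net_full.rho_matrix.loc[:, [c for c in net_full.rho_matrix.columns if c in set(keep)]]
    n_missing = int(mat.isna().to_numpy().sum())
    if n_missing:
        logger.info("correlation_profile_matrix: imputing %d undefined rho cell(s) as 0", n_missing)
    return mat.fillna(0.0)


def cluster_otus(profiles: pd.DataFrame, k: int) -> ClusterAssignment:
    """Complete-linkage / Euclidean clustering of OTU correlation profiles,
    cut to exactly ``k`` groups.

    The cut undoes the last ``k``-1 merges in merge order, which equals the
    minimal-height cut whenever some height yields ``k`` groups and otherwise
    splits the largest cluster at its topmost internal merge (logged).
    """
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of OTUs ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    z = hierarchy.linkage(pdist(profiles.to_numpy(float), metric="euclidean"), method="complete")
    flat = hierarchy.cut_tree(z, n_clusters=k).ravel()
    heights = z[:, 2]
    cut_height = float(heights[n - k - 1]) if k < n else 0.0
    by_height = len(np.unique(hierarchy.fcluster(z, t=cut_height, criterion="distance"))) == k if k < n else True
    if not by_height:
        logger.info("cluster_otus: no single cut height yields k=%d; splitting at merge order", k)
    # stable numbering: clusters ordered by first occurrence along the index
    remap = {}
    labels = []
    for c in flat:
        if c not in remap:
            remap[c] = len(remap) + 1
        labels.append(remap[c])
    return ClusterAssignment(pd.Series(labels, index=profiles.index, name="cluster"),
                             k=k, linkage=z, cut_height=cut_height)


def prediction_strength(profiles: pd.DataFrame, k_range, n_splits: int = 50,
                        threshold: float = 0.8, seed=None) -> tuple[int, pd.DataFrame]:
    """Prediction strength over candidate cluster counts.

    For each k and each random 2-fold split, both halves are clustered with
    k-means; test points are classified by the nearest training centroid and
    ps(k) is the worst-cluster proportion of co-clustered test pairs that the
    training centroids also co-assign, averaged over splits. Returns the
    largest k with ps(k) >= threshold (k=1 scores 1 by definition).
    """
    x = profiles.to_numpy(float)
    n = x.shape[0]
    rng = get_rng(seed)
    rows = []
    for k in sorted(set(int(k) for k in k_range)):
        if k == 1:
            rows.append({"k": 1, "prediction_strength": 1.0})
            continue
        if 2 * k > n:
            raise ValueError(f"need at least 2*k={2*k} OTUs for k={k}, got {n}")
        vals = []
        for s in range(n_splits):
            perm = rng.permutation(n)
            test, train = perm[: n // 2], perm[n // 2:]
            km_tr = KMeans(n_clusters=k, n_init=4,
                           random_state=int(rng.integers(2**31 - 1))).fit(x[train])
            km_te = KMeans(n_clusters=k, n_init=4,
                           random_state=int(rng.integers(2**31 - 1))).fit(x[test])
            co_train = km_tr.predict(x[test])
            cluster_scores = []
            for c in range(k):
                idx = np.nonzero(km_te.labels_ == c)[0]
                m = len(idx)
                if m < 2:
                    continue  # degenerate test cluster: no pairs to score
                same = (co_train[idx][:, None] == co_train[idx][None, :])
                cluster_scores.append((same.sum() - m) / (m * (m - 1)))
            if cluster_scores:
                vals.append(min(cluster_scores))
        rows.append({"k": k, "prediction_strength": float(np.mean(vals)) if vals else np.nan})
    curve = pd.DataFrame(rows)
    ok = curve[curve["prediction_strength"] >= threshold]
    k_star = int(ok["k"].max()) if len(ok) else 1
    return k_star, curve


def cluster_composition(ca: ClusterAssignment, taxonomy: pd.Series) -> pd.DataFrame:
    """Per-cluster phylum fractions (rows sum to 1)."""
    rows = {}
    for c in sorted(ca.labels.unique()):
        members = ca.members(c)
        phyla = pd.Series([_io.phylum_of(taxonomy.get(o, "")) or "unclassified" for o in members])
        rows[c] = phyla.value_counts(normalize=True)
    return pd.DataFrame(rows).T.fillna(0.0).rename_axis("cluster")


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]]:
    the exact hypergeometric tail P(X >= a)."""
    N = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, N, a + b, a + c))


def cross_region_overlap(ca1: ClusterAssignment, ca2: ClusterAssignment,
                         shared_otus, alpha: float = 0.05) -> pd.DataFrame:
    """Cluster-overlap table between two regions over shared OTUs.

    For every (cluster1, cluster2) pair a 2x2 membership table over the shared
    OTUs is scored with a one-sided (greater) Fisher exact test; the
    significance flag applies Bonferroni correction over all k1*k2 cells.
    """
    shared = [o for o in shared_otus if o in ca1.labels.index and o in ca2.labels.index]
    if not shared:
        raise ValueError("shared OTU universe is empty")
    l1 = ca1.labels.loc[shared]
    l2 = ca2.labels.loc[shared]
    n = len(shared)
    rows = []
    cells = ca1.k * ca2.k
    for c1 in range(1, ca1.k + 1):
        for c2 in range(1, ca2.k + 1):
            in1 = l1 == c1
            in2 = l2 == c2
            a = int((in1 & in2).sum())
            b = int((in1 & ~in2).sum())
            c = int((~in1 & in2).sum())
            d = n - a - b - c
            p = fisher_greater(a, b, c, d)
            rows.append({"cluster_region1": c1, "cluster_region2": c2,
                         "overlap": a, "p": p,
                         "p_bonferroni": min(1.0, p * cells),
                         "significant": p * cells < alpha})
    return pd.DataFrame(rows)


def plot_profile_heatmap(profiles: pd.DataFrame, ca: ClusterAssignment | None = None, path=None):
    """Minimal heat map of OTU correlation profiles, rows ordered by the
    cluster dendrogram and columns by average-linkage over metabolites."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = profiles
    if ca is not None and ca.linkage is not None:
        order = hierarchy.leaves_list(ca.linkage)
        mat = mat.iloc[order]
    col_z = hierarchy.linkage(pdist(mat.to_numpy().T), method="average")
    mat = mat.iloc[:, hierarchy.leaves_list(col_z)]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    ax.set_xlabel("analytes")
    ax.set_ylabel("OTUs")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return None
    return fig
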