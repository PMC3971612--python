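"""Metabolite co-occurrence modules with eigenmetabolite summaries.

The construction follows the weighted-correlation-network recipe: a
soft-thresholded |Pearson|^beta adjacency, topological-overlap dissimilarity,
average-linkage hierarchical clustering, branch cutting with a minimum module
size, and a first-singular-vector ("eigenmetabolite") summary per module.
Modules are validated by silhouette width, cophenetic correlation, and
agreement with two independent clusterings (plain 1-Pearson hierarchical and
k-means on correlation profiles).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from ._utils import logger

UNCLUSTERED = "unclustered"
DEFAULT_POWERS = tuple(range(1, 11)) + tuple(range(12, 42, 2))


@dataclass
class ModuleSet:
    """Metabolite -> module assignment with per-module eigenmetabolites.

    ``assignment`` maps every metabolite to a module label or ``unclustered``;
    ``eigenmetabolites`` is samples x modules (unit-norm columns);
    ``variance_explained`` is the fraction of the standardized module
    submatrix's variance carried by the first singular direction.
    """

    assignment: pd.Series
    eigenmetabolites: pd.DataFrame
    power: int | None
    min_module_size: int
    variance_explained: dict = field(default_factory=dict)
    linkage: np.ndarray | None = None
    dissimilarity: np.ndarray | None = None

    @property
    def module_labels(self) -> list[str]:
        return [l for l in pd.unique(self.assignment) if l != UNCLUSTERED]

    def members(self, label: str) -> list:
        return list(self.assignment.index[self.assignment == label])


# ---------------------------------------------------------------------------
# adjacency and soft threshold
# ---------------------------------------------------------------------------

def soft_adjacency(x: pd.DataFrame, power: int) -> pd.DataFrame:
    """Unsigned adjacency |Pearson(x_i, x_j)|^power with zero diagonal."""
    corr = np.corrcoef(x.to_numpy(float), rowvar=False)
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=x.columns, columns=x.columns)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) on log10 k over binned connectivities (signed by slope).

    This is the scale-free topology fit index: frequencies of binned whole-
    network connectivity regressed on bin-mean connectivity in log-log space.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size < 4 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    logk, logp = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            logk.append(np.log10(mean_k))
            logp.append(np.log10(freq))
    if len(logk) < 3:
        return 0.0
    logk = np.asarray(logk)
    logp = np.asarray(logp)
    slope, intercept = np.polyfit(logk, logp, 1)
    resid = logp - (slope * logk + intercept)
    ss_tot = ((logp - logp.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - (resid ** 2).sum() / ss_tot
    return float(-r2 if slope > 0 else r2)


def pick_soft_threshold(x: pd.DataFrame, candidate_powers=DEFAULT_POWERS,
                        target_r2: float = 0.8) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``target_r2`` (else argmax).

    Constant metabolite columns are excluded with a warning before the
    correlation is formed.
    """
    if x.shape[1] < 10:
        raise ValueError("need >= 10 metabolites to pick a soft threshold")
    const = x.std(axis=0, ddof=0) == 0
    if const.any():
        logger.warning("pick_soft_threshold: excluding %d constant column(s)", int(const.sum()))
        x = x.loc[:, ~const]
    rows = []
    corr_abs = np.abs(np.corrcoef(x.to_numpy(float), rowvar=False))
    np.fill_diagonal(corr_abs, 0.0)
    for beta in candidate_powers:
        a = corr_abs ** beta
        k = a.sum(axis=1)
        rows.append({"power": int(beta), "fit_r2": scale_free_fit(k),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    fit = pd.DataFrame(rows)
    ok = fit[fit["fit_r2"] >= target_r2]
    power = int(ok["power"].iloc[0]) if len(ok) else int(fit.loc[fit["fit_r2"].idxmax(), "power"])
    return power, fit


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def tom_dissimilarity(a) -> np.ndarray:
    """1 - TOM for an adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj and k_i = sum_u a_iu; the diagonal of the result
    is zero and all entries lie in [0, 1].
    """
    a = np.asarray(a, dtype=float) if not isinstance(a, pd.DataFrame) else a.to_numpy(float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - tom
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def detect_modules(d, ids=None, min_size: int = 10, cut_quantile: float = 0.99) -> ModuleSet:
    """Branches of the average-linkage tree over a dissimilarity matrix.

    The tree is cut at ``cut_quantile`` of its maximum merge height; branches
    smaller than ``min_size`` become ``unclustered``. Labels ("M1", "M2", ...)
    are ordered by decreasing size (ties by smallest member id), so the
    partition and labels are invariant to input-column permutation.
    """
    dm = d.to_numpy(float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if ids is None:
        ids = d.columns if isinstance(d, pd.DataFrame) else pd.RangeIndex(dm.shape[0])
    ids = pd.Index(ids)
    n = dm.shape[0]
    if n != len(ids):
        raise ValueError("ids length must match dissimilarity size")
    if n < 2:
        assignment = pd.Series([UNCLUSTERED] * n, index=ids)
        return ModuleSet(assignment, pd.DataFrame(), None, min_size)
    z = hierarchy.linkage(squareform(dm, checks=False), method="average")
    height = cut_quantile * z[:, 2].max()
    flat = hierarchy.fcluster(z, t=height, criterion="distance")
    labels = pd.Series(flat, index=ids)
    groups = [g for _, g in labels.groupby(labels) if len(g) >= min_size]
    groups.sort(key=lambda g: (-len(g), str(sorted(map(str, g.index))[0])))
    assignment = pd.Series(UNCLUSTERED, index=ids, dtype=object)
    for i, g in enumerate(groups, start=1):
        assignment.loc[g.index] = f"M{i}"
    return ModuleSet(assignment, pd.DataFrame(), None, min_size, linkage=z, dissimilarity=dm)


def eigenmetabolite(x: pd.DataFrame) -> tuple[pd.Series, float]:
    """First left singular vector of the standardized module submatrix.

    The profile has unit norm and is sign-oriented so that its mean
    correlation with the member metabolites is positive. Also returns the
    fraction of variance explained by the first singular direction.
    """
    if x.shape[1] < 2:
        raise ValueError("module must have >= 2 members")
    v = x.to_numpy(float)
    sd = v.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all-constant module")
    sd = np.where(sd == 0, 1.0, sd)
    z = (v - v.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    profile = u[:, 0]
    orient = np.sign(vt[0].mean())
    if orient == 0:
        orient = 1.0 if profile[np.argmax(np.abs(profile))] >= 0 else -1.0
    profile = profile * orient
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return pd.Series(profile, index=x.index, name="eigenmetabolite"), var_explained


def build_modules(x: pd.DataFrame, power: int | str = "auto", min_size: int = 10,
                  candidate_powers=DEFAULT_POWERS, cut_quantile: float = 0.99,
                  min_kme: float = 0.5) -> ModuleSet:
    """Full module construction: adjacency -> TOM -> tree cut -> membership
    pruning -> eigenmetabolites.

    After branch detection, members whose module membership (|correlation
    with the module eigenmetabolite|, kME) falls below ``min_kme`` are pruned
    to ``unclustered`` and the eigenmetabolite recomputed — branches should
    keep only metabolites that genuinely track the module profile, and 0.5 is
    the conventional core-membership cutoff. Modules shrinking below
    ``min_size`` dissolve entirely.
    """
    const = x.std(axis=0, ddof=0) == 0
    kept = x.loc[:, ~const]
    if const.any():
        logger.warning("build_modules: %d constant metabolite(s) left unclustered", int(const.sum()))
    if power == "auto":
        power, _ = pick_soft_threshold(kept, candidate_powers)
    power = int(power)
    a = soft_adjacency(kept, power)
    d = tom_dissimilarity(a)
    ms = detect_modules(pd.DataFrame(d, index=kept.columns, columns=kept.columns),
                        min_size=min_size, cut_quantile=cut_quantile)
    assignment = ms.assignment.reindex(x.columns, fill_value=UNCLUSTERED).copy()
    eig = {}
    var = {}
    for label in ms.module_labels:
        members = ms.members(label)
        profile, ve = eigenmetabolite(kept[members])
        kme = np.abs([np.corrcoef(kept[m], profile)[0, 1] for m in members])
        weak = [m for m, k in zip(members, kme) if not k >= min_kme]
        if weak:
            logger.info("build_modules: pruning %d weak member(s) (|kME| < %g) from %s",
                        len(weak), min_kme, label)
            assignment.loc[weak] = UNCLUSTERED
            members = [m for m in members if m not in set(weak)]
            if len(members) < min_size:
                assignment.loc[members] = UNCLUSTERED
                continue
            profile, ve = eigenmetabolite(kept[members])
        eig[label] = profile
        var[label] = ve
    # relabel by surviving size so labels stay dense and deterministic
    survivors = sorted(eig, key=lambda l: (-(assignment == l).sum(),
                                           str(min(map(str, assignment.index[assignment == l])))))
    rename = {old: f"M{i}" for i, old in enumerate(survivors, start=1)}
    assignment = assignment.map(lambda l: rename.get(l, UNCLUSTERED))
    eigdf = pd.DataFrame({rename[l]: eig[l] for l in survivors}, index=x.index) \
        if survivors else pd.DataFrame(index=x.index)
    var = {rename[l]: var[l] for l in survivors}
    return ModuleSet(assignment, eigdf, power, min_size, var, ms.linkage, ms.dissimilarity)


# ---------------------------------------------------------------------------
# validation and downstream assembly
# ---------------------------------------------------------------------------

@dataclass
class ModuleValidation:
    mean_silhouette: float
    cophenetic_corr: float
    kmeans_agreement: float
    plain_hclust_agreement: float


def validate_modules(ms: ModuleSet, x: pd.DataFrame) -> ModuleValidation:
    """Internal validation of a module assignment.

    Silhouette uses 1 - Pearson distances over clustered metabolites;
    cophenetic correlation compares the module tree's merge heights with the
    dissimilarity it was built from; the two agreement scores are adjusted
    Rand indices against average-linkage on 1 - Pearson and against k-means
    with k = module count.
    """
    labels = ms.assignment
    clustered = labels[labels != UNCLUSTERED]
    k = len(ms.module_labels)
    if k < 2:
        return ModuleValidation(np.nan, _cophenetic(ms), np.nan, np.nan)
    sub = x[clustered.index]
    corr = np.corrcoef(sub.to_numpy(float), rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    sil = float(silhouette_score(dist, clustered.to_numpy(), metric="precomputed"))

    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    plain = hierarchy.cut_tree(z, n_clusters=k).ravel()
    plain_ari = float(adjusted_rand_score(clustered.to_numpy(), plain))

    km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(corr)
    km_ari = float(adjusted_rand_score(clustered.to_numpy(), km.labels_))
    return ModuleValidation(sil, _cophenetic(ms), km_ari, plain_ari)


def _cophenetic(ms: ModuleSet) -> float:
    if ms.linkage is None or ms.dissimilarity is None:
        return np.nan
    c, _ = hierarchy.cophenet(ms.linkage, squareform(ms.dissimilarity, checks=False))
    return float(c)


def combine_with_unclustered(ms: ModuleSet, x: pd.DataFrame) -> pd.DataFrame:
    """Analyte matrix: one eigenmetabolite column per module plus raw
    intensity columns for every unclustered metabolite. This is the analyte
    input to the inter-omic network stage."""
    uncl = ms.assignment.index[ms.assignment == UNCLUSTERED]
    pieces = []
    if len(ms.eigenmetabolites.columns):
        pieces.append(ms.eigenmetabolites.loc[x.index])
    pieces.append(x[list(uncl)])
    return pd.concat(pieces, axis=1)
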