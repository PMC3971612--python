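"""Imputed-function analysis: pathway differentiation across microbial
clusters and metabolite-metagenome concordance.

The pathway table is the consumption side of 16S metagenome imputation: per
OTU, the relative genomic proportion of each KEGG pathway. Two questions are
asked of it: (i) do the metabolite-driven microbial clusters differ in pathway
content (Kruskal-Wallis with Bonferroni control), and (ii) is a metabolite's
OTU-correlation profile concordant with the genomic abundance of the pathway
that produces it (Pearson across OTUs, Bonferroni over tested records)?
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import io as _io
from ._utils import logger
from .clusters import ClusterAssignment
from .network import InteromicNetwork


@dataclass
class ConcordanceRecord:
    metabolite_id: str
    putative_compound: str
    pathway_id: str
    n_otus: int
    pearson_r: float
    p: float
    p_bonferroni: float
    category: str  # positive | negative | not_significant


def single_count_profile_convention(otu_ids) -> _io.OtuTable:
    """The OTU x OTU identity count table used to obtain per-OTU metagenomes
    from external imputation tools: each OTU is represented by a single count
    in its own column."""
    otu_ids = list(otu_ids)
    if not otu_ids:
        raise ValueError("need at least one OTU id")
    counts = pd.DataFrame(np.eye(len(otu_ids), dtype=np.int64),
                          index=pd.Index(otu_ids, name="sample_id"),
                          columns=pd.Index(otu_ids, name="otu_id"))
    tax = pd.Series([""] * len(otu_ids), index=counts.columns, dtype=object)
    return _io.OtuTable(counts, tax)


def cluster_pathway_tests(pp: _io.PathwayProfile, ca: ClusterAssignment,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis test of each pathway's OTU-level abundance across clusters.

    H is tie-corrected; Bonferroni correction runs over pathways. Per-cluster
    direction flags compare the cluster's mean rank with the overall mean
    rank (+1 enriched, -1 depleted). Clusters with fewer than 2 OTUs are
    excluded with a warning.
    """
    groups = {}
    for c in sorted(ca.labels.unique()):
        members = [o for o in ca.members(c) if o in pp.abundance.index]
        if len(members) < 2:
            logger.warning("cluster_pathway_tests: cluster %s has <2 OTUs with pathway rows; excluded", c)
            continue
        groups[c] = members
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters with >= 2 OTUs each")
    n_pathways = pp.abundance.shape[1]
    rows = []
    for pathway in pp.abundance.columns:
        samples = [pp.abundance.loc[m, pathway].to_numpy(float) for m in groups.values()]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        ranks = stats.rankdata(pooled)
        offsets = np.cumsum([0] + [len(s) for s in samples])
        overall = ranks.mean()
        flags = {f"cluster_{c}": int(np.sign(ranks[offsets[i]:offsets[i + 1]].mean() - overall))
                 for i, c in enumerate(groups)}
        p_bonf = min(1.0, p * n_pathways)
        rows.append({"pathway_id": pathway, "H": float(h), "p": float(p),
                     "p_bonferroni": p_bonf, "significant": p_bonf < alpha, **flags})
    return pd.DataFrame(rows).set_index("pathway_id")


def metabolite_metagenome_concordance(
        net_significant: InteromicNetwork, net_full: InteromicNetwork,
        pp: _io.PathwayProfile, id_map: dict, min_otus: int = 5,
        alpha: float = 0.05) -> pd.DataFrame:
    """Concordance of metabolite correlation profiles with pathway genomics.

    For each metabolite with >= ``min_otus`` significant OTU edges and at
    least one putative (compound, pathway) candidate: vector A holds the
    metabolite's Spearman rho against every OTU in the detected universe
    (undefined cells dropped pairwise), vector B the candidate pathway's
    imputed abundance per OTU. Records carry Pearson(A, B), its two-sided p,
    Bonferroni correction over all tested records, and a three-way category.
    """
    support = net_significant.edges.groupby("analyte_id")["otu_id"].nunique()
    eligible = [m for m in support[support >= min_otus].index if id_map.get(m)]
    records = []
    for met in eligible:
        a_full = net_full.rho_matrix[met] if met in net_full.rho_matrix.columns else None
        if a_full is None:
            continue
        for compound, pathway in id_map[met]:
            if pathway not in pp.abundance.columns:
                logger.warning("concordance: pathway %s absent from profile; record skipped", pathway)
                continue
            b_full = pp.abundance[pathway]
            shared = a_full.dropna().index.intersection(b_full.index)
            if len(shared) < 3:
                continue
            a = a_full.loc[shared].to_numpy(float)
            b = b_full.loc[shared].to_numpy(float)
            if np.allclose(a, a[0]) or np.allclose(b, b[0]):
                continue
            r, p = stats.pearsonr(a, b)
            records.append({"metabolite_id": met, "putative_compound": compound,
                            "pathway_id": pathway, "n_otus": len(shared),
                            "pearson_r": float(r), "p": float(p)})
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=["metabolite_id", "putative_compound", "pathway_id",
                                     "n_otus", "pearson_r", "p", "p_bonferroni", "category"])
    m = len(df)
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * m)
    logger.info("concordance: Bonferroni correction over %d tested records", m)
    df["category"] = np.where(df["p_bonferroni"] >= alpha, "not_significant",
                              np.where(df["pearson_r"] > 0, "positive", "negative"))
    return df.sort_values("pearson_r", ascending=False).reset_index(drop=True)
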