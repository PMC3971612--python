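"""OTU-metabolite Spearman correlation networks with Storey q-value control.

Every (OTU, analyte) pair gets a rank correlation rho and a two-sided p-value
(t approximation for n >= 10, exact permutation enumeration below that);
q-values implement Storey's pi0-adaptive FDR estimate. Edges surviving the
q threshold are summarised network-wide and binned by genus with duplicate
metabolite correlations collapsed, so that a genus correlating with one
metabolite through many OTUs still counts as a single interaction.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as _io
from ._utils import logger

EXACT_P_MAX_N = 9  # exact permutation p-values below this many samples


@dataclass
class InteromicNetwork:
    """Edge list plus the full rho matrix it was derived from.

    ``edges`` has columns (otu_id, analyte_id, rho, p[, q]); ``rho_matrix``
    is OTU x analyte with NaN where either vector had zero variance.
    """

    edges: pd.DataFrame
    rho_matrix: pd.DataFrame
    n_samples: int
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class NetworkSummary:
    total_edges: int
    unique_otu_nodes: int
    unique_analyte_nodes: int
    per_phylum_ratio: dict
    mean_edges_per_otu: float
    mean_edges_per_analyte: float


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (permuting one margin)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    hits = total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        r = float(rx @ np.asarray(perm)) / denom
        total += 1
        if abs(r) >= target:
            hits += 1
    return hits / total


def spearman_all_pairs(otus, analytes: pd.DataFrame, p_method: str = "permutation",
                       n_null_permutations: int = 50, seed: int = 0) -> InteromicNetwork:
    """Spearman rho and two-sided p for every (OTU, analyte) pair.

    ``otus`` may be an OtuTable (relative abundances are used) or a plain
    samples x OTUs DataFrame. Tables are merged on their shared sample index;
    fewer than 4 shared samples is an error. Pairs where either vector is
    constant have undefined rho and are excluded (count logged).

    p-values: below 10 samples the exact permutation enumeration is used.
    Otherwise ``p_method`` selects between a pooled permutation-calibrated
    empirical null (default: sample rows of the analyte table are permuted
    ``n_null_permutations`` times and all pairs' |rho| pooled into one null
    reference, which keeps the far tail honest for the multiple-testing step)
    and the classical ``"t"`` approximation, whose far tail is measurably
    anti-conservative at cohort-scale n and is kept only for comparability.
    """
    if isinstance(otus, _io.OtuTable):
        x = otus.relative_abundance()
    else:
        x = otus
    shared = x.index.intersection(analytes.index)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    x = x.loc[shared]
    y = analytes.loc[shared]
    n = len(shared)

    rx = _midranks(x.to_numpy(float))
    ry = _midranks(y.to_numpy(float))
    sx = rx.std(axis=0)
    sy = ry.std(axis=0)
    zx = (rx - rx.mean(axis=0)) / np.where(sx == 0, np.nan, sx)
    zy = (ry - ry.mean(axis=0)) / np.where(sy == 0, np.nan, sy)
    rho = (zx.T @ zy) / n  # OTU x analyte

    if n < 10:
        p = np.full_like(rho, np.nan)
        xv = x.to_numpy(float)
        yv = y.to_numpy(float)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                if np.isfinite(rho[i, j]):
                    p[i, j] = _exact_spearman_p(xv[:, i], yv[:, j], rho[i, j])
    elif p_method == "t":
        r = np.clip(rho, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.minimum(p, 1.0)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        zx0 = zx[:, sx != 0]  # constant columns stay out of the null pool
        zy0 = zy[:, sy != 0]
        pool = np.empty(n_null_permutations * zx0.shape[1] * zy0.shape[1])
        width = zx0.shape[1] * zy0.shape[1]
        for b in range(n_null_permutations):
            perm = rng.permutation(n)
            pool[b * width:(b + 1) * width] = np.abs((zx0.T @ zy0[perm]) / n).ravel()
        pool.sort()
        idx = np.searchsorted(pool, np.abs(rho).ravel())
        p = ((1.0 + pool.size - idx) / (pool.size + 1.0)).reshape(rho.shape)
    else:
        raise ValueError(f"unknown p_method: {p_method}")

    rho_df = pd.DataFrame(rho, index=x.columns, columns=y.columns)
    oi, ai = np.nonzero(np.isfinite(rho))
    n_excluded = rho.size - len(oi)
    if n_excluded:
        logger.info("spearman_all_pairs: %d pair(s) excluded for zero variance", n_excluded)
    edges = pd.DataFrame({
        "otu_id": rho_df.index.to_numpy()[oi],
        "analyte_id": rho_df.columns.to_numpy()[ai],
        "rho": rho[oi, ai],
        "p": np.maximum(p[oi, ai], np.finfo(float).tiny),
    })
    return InteromicNetwork(edges, rho_df, n_samples=n, n_excluded=n_excluded)


def qvalues(p, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated on a lambda grid (0.05..0.95) and extrapolated to
    lambda -> 1 with a least-squares cubic smoother; q(p_(i)) is the usual
    step-up minimum of pi0 * m * p_(j) / j over j >= i. When the smoother
    yields pi0 outside (0, 1], pi0 falls back to 1, and forcing ``pi0=1``
    reduces the procedure to plain Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    if pi0 is None:
        pi0 = estimate_pi0(p, lambdas)
    elif not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def estimate_pi0(p: np.ndarray, lambdas) -> float:
    """Proportion of true nulls, via cubic extrapolation of pi0(lambda) to 1."""
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    try:
        coeffs = np.polynomial.polynomial.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polynomial.polynomial.polyval(1.0, coeffs))
    except Exception:  # degenerate grid
        pi0 = 1.0
    if not 0.0 < pi0 <= 1.0:
        pi0 = 1.0
    return pi0


def add_qvalues(net: InteromicNetwork, lambdas=None) -> InteromicNetwork:
    edges = net.edges.copy()
    edges["q"] = qvalues(edges["p"].to_numpy(), lambdas=lambdas) if len(edges) else []
    return InteromicNetwork(edges, net.rho_matrix, net.n_samples, net.n_excluded)


def significant_edges(net: InteromicNetwork, q_max: float = 0.2) -> InteromicNetwork:
    """Strict threshold: keep edges with q < ``q_max``."""
    if "q" not in net.edges.columns:
        raise ValueError("q-values not computed; call add_qvalues first")
    edges = net.edges[net.edges["q"] < q_max].reset_index(drop=True)
    return InteromicNetwork(edges, net.rho_matrix, net.n_samples, net.n_excluded)


def bin_by_genus(net: InteromicNetwork, taxonomy: pd.Series,
                 relative_abundance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Collapse a significant network to genus-level interaction counts.

    OTUs are grouped by the genus rank; per genus, each distinct analyte
    counts once no matter how many member OTUs correlate with it. OTUs
    without genus-level resolution are excluded. The optional relative
    abundance table adds the genus's mean relative abundance across samples.
    """
    genus = net.edges["otu_id"].map(lambda o: _io.genus_of(taxonomy.get(o, "")))
    edges = net.edges.assign(genus=genus).dropna(subset=["genus"])
    counts = edges.groupby("genus")["analyte_id"].nunique().rename("n_unique_metabolites")
    out = counts.to_frame()
    if relative_abundance is not None:
        genus_of_otu = pd.Series(
            {o: _io.genus_of(taxonomy.get(o, "")) for o in relative_abundance.columns})
        mean_ab = {}
        for g in out.index:
            members = genus_of_otu[genus_of_otu == g].index
            mean_ab[g] = float(relative_abundance[members].sum(axis=1).mean()) if len(members) else np.nan
        out["mean_relative_abundance"] = pd.Series(mean_ab)
    return out.sort_values("n_unique_metabolites", ascending=False)


def summarize_network(net: InteromicNetwork, detected_otus, taxonomy: pd.Series) -> NetworkSummary:
    """Network-wide counts plus per-phylum edge-bearing ratios.

    The per-phylum ratio is (#OTUs of that phylum with >= 1 significant edge)
    / (#detected OTUs of that phylum), over the detected-OTU universe.
    """
    edges = net.edges
    otus_with_edges = set(edges["otu_id"])
    phyla: dict[str, list[int]] = {}
    for o in detected_otus:
        ph = _io.phylum_of(taxonomy.get(o, ""))
        if ph is None:
            continue
        hit, tot = phyla.get(ph, (0, 0))
        phyla[ph] = (hit + int(o in otus_with_edges), tot + 1)
    ratio = {ph: (h / t if t else 0.0) for ph, (h, t) in phyla.items()}
    n_otu = edges["otu_id"].nunique()
    n_analyte = edges["analyte_id"].nunique()
    return NetworkSummary(
        total_edges=len(edges),
        unique_otu_nodes=int(n_otu),
        unique_analyte_nodes=int(n_analyte),
        per_phylum_ratio=ratio,
        mean_edges_per_otu=len(edges) / n_otu if n_otu else 0.0,
        mean_edges_per_analyte=len(edges) / n_analyte if n_analyte else 0.0,
    )


def write_edges(net: InteromicNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, lineterminator="\n")
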