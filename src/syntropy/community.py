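"""Compositional (SparCC-style) correlation and the permutation test of
metabolite-associated microbial community structure.

Sequencing counts are compositional: per-sample totals are arbitrary, so
naive correlations between relative abundances are biased. The SparCC
estimator works from log-ratio variances T_ij = Var log(f_i/f_j), solves for
basis (absolute-abundance) log variances under a sparsity assumption, and
iteratively excludes the strongest correlated pairs from the solve to guard
that assumption. Uncertainty in the fractions themselves is integrated out by
averaging over Dirichlet posterior draws of the per-sample compositions.

The community-structure question: do OTUs sharing a correlated metabolite
co-occur (or co-exclude) more than randomly chosen OTUs? Answered by
permutation - same-size random OTU sets from the same filtered table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io
from ._utils import get_rng, logger

_VAR_MIN = 1e-4  # floor for basis variances, per the reference conventions


@dataclass
class SparccResult:
    correlation: pd.DataFrame  # OTU x OTU, unit diagonal, clipped to [-1, 1]
    basis_variance: pd.Series
    n_iterations: int
    n_excluded_pairs: int


@dataclass
class CommunityStructureResult:
    group_id: str
    n_otus: int
    total_branch_length: float
    association_type: str
    mean_pos: float
    mean_neg: float
    n_above: int
    n_below: int
    p_mean_pos: float
    p_mean_neg: float
    p_above: float
    p_below: float
    n_permutations: int = 0

    def to_row(self) -> dict:
        return dict(self.__dict__)


def _basis_correlations_batched(T: np.ndarray, n_exclusion_iters: int,
                                exclusion_threshold: float):
    """Solve basis variances for a stack of variation matrices with iterative
    strongest-pair exclusion, vectorized over the stack.

    Exclusion zeroes the pair's contribution to the row sums and decrements
    the system matrix, following the reference strategy; rho is always
    computed from the original T. Returns (rho, omega, n_excluded) with
    leading batch dimension.
    """
    B, D, _ = T.shape
    M = np.full((B, D, D), 1.0)
    diag = np.arange(D)
    M[:, diag, diag] = float(D - 1)  # (D-2) I + all-ones
    T_work = T.copy()
    excluded = np.zeros((B, D, D), dtype=bool)
    n_excl = np.zeros(B, dtype=int)
    active = np.ones(B, dtype=bool)
    eye = np.eye(D, dtype=bool)
    rho = omega = None
    for it in range(n_exclusion_iters + 1):
        t_row = T_work.sum(axis=2)
        try:
            omega = np.linalg.solve(M, t_row[..., None])[..., 0]
        except np.linalg.LinAlgError:
            omega = np.stack([np.linalg.lstsq(M[b], t_row[b], rcond=None)[0]
                              for b in range(B)])
        np.maximum(omega, _VAR_MIN, out=omega)
        denom = 2.0 * np.sqrt(omega[:, :, None] * omega[:, None, :])
        rho = (omega[:, :, None] + omega[:, None, :] - T) / denom
        np.clip(rho, -1.0, 1.0, out=rho)
        rho[:, eye] = 1.0
        if it == n_exclusion_iters:
            break
        ar = np.abs(rho)
        ar[:, eye] = 0.0
        ar[excluded] = 0.0
        flat = ar.reshape(B, -1)
        idx = flat.argmax(axis=1)
        strongest = flat[np.arange(B), idx]
        active = active & (strongest > exclusion_threshold)
        if not active.any():
            break
        b = np.nonzero(active)[0]
        i, j = idx[b] // D, idx[b] % D
        excluded[b, i, j] = excluded[b, j, i] = True
        n_excl[b] += 1
        T_work[b, i, j] = T_work[b, j, i] = 0.0
        M[b, i, i] -= 1.0
        M[b, j, j] -= 1.0
        M[b, i, j] -= 1.0
        M[b, j, i] -= 1.0
    return rho, omega, n_excl


def _variation_matrices(log_f: np.ndarray) -> np.ndarray:
    """T_ij = Var over samples of log(f_i/f_j) for a (batch, sample, OTU) stack."""
    n = log_f.shape[1]
    centered = log_f - log_f.mean(axis=1, keepdims=True)
    v = np.einsum("bni,bnj->bij", centered, centered) / (n - 1)
    dv = np.einsum("bii->bi", v)
    return dv[:, :, None] + dv[:, None, :] - 2.0 * v


def sparcc(counts, n_dirichlet: int = 20, n_exclusion_iters: int = 10,
           exclusion_threshold: float = 0.1, seed=None) -> SparccResult:
    """SparCC correlation estimate for a sample x OTU count table.

    Per Dirichlet draw (posterior fractions under a uniform prior, which also
    handles zeros), the log-ratio variation matrix is formed and basis
    variances solved with iterative strongest-pair exclusion; the reported
    correlation is the median over draws, clipped to [-1, 1].
    """
    frame = counts.counts if isinstance(counts, _io.OtuTable) else counts
    otu_ids = frame.columns
    x = frame.to_numpy(float)
    n, D = x.shape
    if D < 4:
        raise ValueError("basis decomposition underdetermined: need >= 4 OTUs")
    if n < 8:
        raise ValueError("need >= 8 samples for a stable SparCC estimate")
    rng = get_rng(seed)
    # Dirichlet(counts + 1) posterior fractions for every draw at once
    g = rng.standard_gamma(np.broadcast_to(x + 1.0, (n_dirichlet, n, D)))
    f = g / g.sum(axis=2, keepdims=True)
    T = _variation_matrices(np.log(f))
    rhos, omegas, excl = _basis_correlations_batched(T, n_exclusion_iters,
                                                     exclusion_threshold)
    corr = np.clip(np.median(rhos, axis=0), -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return SparccResult(
        correlation=pd.DataFrame(corr, index=otu_ids, columns=otu_ids),
        basis_variance=pd.Series(np.median(omegas, axis=0), index=otu_ids),
        n_iterations=n_exclusion_iters,
        n_excluded_pairs=int(np.median(excl)),
    )


def _structure_stats(corr: np.ndarray, hi: float, lo: float, ordered_pairs: bool) -> tuple:
    """(mean_pos, mean_neg, n_above, n_below) over off-diagonal entries."""
    D = corr.shape[0]
    mask = ~np.eye(D, dtype=bool)
    vals = corr[mask]  # ordered pairs: each unordered pair appears twice
    pos = vals[vals > 0]
    neg = vals[vals < 0]
    mean_pos = float(pos.mean()) if pos.size else 0.0
    mean_neg = float(neg.mean()) if neg.size else 0.0
    n_above = int((vals > hi).sum())
    n_below = int((vals < lo).sum())
    if not ordered_pairs:
        n_above //= 2
        n_below //= 2
    return mean_pos, mean_neg, n_above, n_below


def group_structure_test(counts, group, n_perm: int = 1000, thresholds=(0.2, -0.2),
                         seed=None, group_id: str = "", tree=None,
                         association_rhos=None, ordered_pairs: bool = True,
                         n_dirichlet: int = 20) -> CommunityStructureResult:
    """Permutation test of a metabolite-associated OTU group's SparCC structure.

    The group's count submatrix is scored by SparCC (mean positive and mean
    negative off-diagonal correlation, counts above/below the supplementary
    thresholds); the null re-scores ``n_perm`` equally sized OTU sets drawn
    without replacement from the same table. "Stronger" means a larger
    positive mean / count and a more negative mean / larger below-count;
    p-values use the add-one permutation correction and can never be 0.
    """
    frame = counts.counts if isinstance(counts, _io.OtuTable) else counts
    group = [o for o in group]
    missing = [o for o in group if o not in frame.columns]
    if missing:
        raise ValueError(f"group OTUs absent from table: {missing[:5]}")
    if len(group) < 4:
        raise ValueError("group must contain >= 4 OTUs")
    rng = get_rng(seed)
    hi, lo = max(thresholds), min(thresholds)

    def stats_for(cols, child_seed):
        res = sparcc(frame[cols], seed=child_seed, n_dirichlet=n_dirichlet)
        return _structure_stats(res.correlation.to_numpy(), hi, lo, ordered_pairs)

    obs = stats_for(group, rng)
    all_otus = np.asarray(frame.columns)
    size = len(group)
    hits = np.zeros(4, dtype=int)
    for _ in range(n_perm):
        sel = rng.choice(all_otus, size=size, replace=False)
        mp, mn, na, nb = stats_for(list(sel), rng)
        hits[0] += mp >= obs[0]
        hits[1] += mn <= obs[1]
        hits[2] += na >= obs[2]
        hits[3] += nb >= obs[3]
    p = (1 + hits) / (1 + n_perm)

    tbl = total_branch_length(tree, group) if tree is not None else np.nan
    assoc = association_type(association_rhos) if association_rhos is not None else ""
    return CommunityStructureResult(
        group_id=group_id, n_otus=size, total_branch_length=tbl,
        association_type=assoc, mean_pos=obs[0], mean_neg=obs[1],
        n_above=obs[2], n_below=obs[3],
        p_mean_pos=float(p[0]), p_mean_neg=float(p[1]),
        p_above=float(p[2]), p_below=float(p[3]), n_permutations=n_perm,
    )


def association_type(rhos) -> str:
    """Label the sign mix of a metabolite's OTU correlations.

    100% one sign -> "all positive"/"all negative"; at least two thirds one
    sign -> "mostly ..."; otherwise the literal percentage split (so an even
    split is reported as percentages, never "mostly").
    """
    rhos = np.asarray(list(rhos), dtype=float)
    if rhos.size == 0:
        raise ValueError("empty correlation list")
    n_pos = int((rhos > 0).sum())
    n_neg = rhos.size - n_pos
    n = rhos.size
    if n_neg == 0:
        return "all positive"
    if n_pos == 0:
        return "all negative"
    if 3 * n_pos > 2 * n or 3 * n_pos == 2 * n:
        return "mostly positive"
    if 3 * n_neg > 2 * n or 3 * n_neg == 2 * n:
        return "mostly negative"
    pct_neg = round(100 * n_neg / n)
    return f"{pct_neg}% negative, {100 - pct_neg}% positive"


def taxonomy_cladogram(taxonomy) -> str:
    """Unit-branch-length cladogram over OTUs built from their taxonomy strings.

    A surrogate for a real phylogeny when only taxonomy is available: OTUs
    sharing deeper ranks sit closer, every edge has length 1. Unresolved
    (empty or bare-prefix) ranks are skipped, so an unclassified OTU attaches
    near the root.
    """
    root: dict = {}
    for otu, tax in taxonomy.items():
        ranks = [r for r in _io.split_ranks(tax) if r and not r.endswith("__")]
        node = root
        for r in ranks:
            node = node.setdefault(r, {})
        node[("tip", str(otu))] = None

    def render(node: dict) -> str:
        parts = []
        for key, child in sorted(node.items(), key=lambda kv: str(kv[0])):
            if isinstance(key, tuple):
                parts.append(f"{key[1]}:1")
            else:
                parts.append(f"{render(child)}:1")
        return "(" + ",".join(parts) + ")"

    return render(root) + ";"


def total_branch_length(tree, tips) -> float:
    """Sum of branch lengths of the subtree induced by ``tips``.

    The subtree is rooted at the tips' most recent common ancestor; the stem
    above it is excluded. A single tip has zero induced length. Accepts an
    ``skbio.TreeNode`` or a newick string.
    """
    from skbio import TreeNode

    if isinstance(tree, str):
        import io as _stdio

        tree = TreeNode.read(_stdio.StringIO(tree), format="newick")
    tips = list(dict.fromkeys(tips))
    names = {t.name for t in tree.tips()}
    for t in tips:
        if t not in names:
            raise ValueError(f"tip not found in tree: {t}")
    if len(tips) == 1:
        return 0.0
    sub = tree.shear(tips)
    return float(sum(n.length or 0.0 for n in sub.traverse(include_self=False)))
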