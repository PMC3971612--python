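"""Paired-region synthetic data with known planted structure.

The generator emulates the study design the analysis pipeline expects:
two colonic regions sampled from the same subjects, a compositional 16S OTU
table (log-normal basis abundances with guild-block correlation, multinomial
reads at ~30,000 depth), a UPLC-MS style metabolite table with module
structure and planted OTU-metabolite links of both signs, a per-OTU KEGG
pathway profile concordant with the links, a pure-birth phylogeny, and
GreenGenes-style taxonomy strings. Every planted element is returned as
ground truth so downstream recovery is testable.

Planted links couple a metabolite to the *rank* of an OTU's relative
abundance (a Gaussian-score transform plus independent noise), so Spearman -
not Pearson - is the natural detector; the noise weight is chosen so the
population Spearman correlation equals ``link_effect``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MetaboliteTable, OtuTable, PathwayProfile, write_metabolite_table, \
    write_otu_table, write_pathway_profile, write_tree

REGIONS = ("cecum", "sigmoid")
_PHYLA = (
    ("Bacteroidetes", 0.36),
    ("Firmicutes", 0.40),
    ("Proteobacteria", 0.12),
    ("Actinobacteria", 0.06),
    ("Tenericutes", 0.03),
    ("Verrucomicrobia", 0.03),
)


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the violated invariant."""


@dataclass
class SynthConfig:
    """Study conditions for one paired-region synthetic dataset.

    Defaults mirror the emulated study: 46 subjects per region, read depth
    ~30,000, metabolite modules of 10-25 members with within-module
    correlation 0.8, and planted OTU-metabolite links targeting
    |Spearman| = 0.6.
    """

    seed: int = 0
    n_subjects: int = 46
    n_otus: int = 300
    n_metabolites: int = 200
    n_modules: int = 3
    module_size_range: tuple = (10, 25)
    module_sizes: tuple | None = None  # explicit sizes override the range
    n_planted_links: int = 30
    link_effect: float = 0.6
    frac_negative_links: float = 0.3
    n_guilds: int = 2
    guild_size: int = 10
    guild_corr: float = 0.7
    guild_cross_corr: float = 0.0  # correlation between guilds 1 and 2 (co-exclusion)
    read_depth_mean: int = 30_000
    n_pathways: int = 40
    shared_metabolite_fraction: float = 0.7
    mass_jitter_sd: float = 0.001
    rt_jitter_sd: float = 0.01
    module_corr: float = 0.8
    links_per_metabolite: int = 1
    link_otus_from_guilds: bool = False  # tie each linked metabolite to one guild's OTUs

    def validate(self) -> None:
        sizes = self.resolved_module_sizes()
        if sum(sizes) > self.n_metabolites:
            raise ConfigurationError("module sizes exceed n_metabolites")
        if self.module_sizes is None and self.n_modules > 0 and \
                self.n_modules * max(self.module_size_range) > self.n_metabolites:
            raise ConfigurationError("n_modules x max module size exceeds n_metabolites")
        if self.n_planted_links > self.n_otus * self.n_metabolites:
            raise ConfigurationError("n_planted_links exceeds n_otus x n_metabolites")
        if self.read_depth_mean <= 0:
            raise ConfigurationError("read_depth_mean must be positive")
        if not 0.0 < self.link_effect <= 1.0:
            raise ConfigurationError("link_effect must be in (0, 1]")
        if not 0.0 <= self.frac_negative_links <= 1.0:
            raise ConfigurationError("frac_negative_links must be in [0, 1]")
        if not -1.0 < self.guild_corr < 1.0:
            raise ConfigurationError("guild_corr must be in (-1, 1)")
        if not -1.0 < self.guild_cross_corr < 1.0:
            raise ConfigurationError("guild_cross_corr must be in (-1, 1)")
        if self.n_guilds * self.guild_size > self.n_otus:
            raise ConfigurationError("guild membership exceeds n_otus")
        if self.link_otus_from_guilds:
            if self.n_planted_links and (self.n_guilds < 1 or
                                         self.guild_size < self.links_per_metabolite):
                raise ConfigurationError(
                    "link_otus_from_guilds needs a guild with >= links_per_metabolite members")
        elif self.n_guilds * self.guild_size + self.n_planted_links > self.n_otus:
            raise ConfigurationError("guild members plus planted-link OTUs exceed n_otus")
        if not 0.0 <= self.shared_metabolite_fraction <= 1.0:
            raise ConfigurationError("shared_metabolite_fraction must be in [0, 1]")
        if not 0.0 < self.module_corr < 1.0:
            raise ConfigurationError("module_corr must be in (0, 1)")
        needed = sum(sizes) + self.n_link_metabolites()
        if needed > self.n_shared():
            raise ConfigurationError(
                "planted modules and links must fit within the shared metabolite pool "
                f"(need {needed}, shared pool {self.n_shared()})")

    def resolved_module_sizes(self) -> tuple:
        if self.module_sizes is not None:
            return tuple(int(s) for s in self.module_sizes)
        lo, hi = self.module_size_range
        # deterministic mid-range sizes; randomized sizes add nothing testable
        return tuple(int(lo + (hi - lo) * (i + 1) / (self.n_modules + 1))
                     for i in range(self.n_modules))

    def n_shared(self) -> int:
        return int(round(self.shared_metabolite_fraction * self.n_metabolites))

    def n_link_metabolites(self) -> int:
        if self.n_planted_links == 0:
            return 0
        return math.ceil(self.n_planted_links / self.links_per_metabolite)


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by metabolite *identity* ids.

    ``feature_map[region]`` translates identities into that region's feature
    ids; ``module_factors[region]`` holds the per-sample latent factor behind
    each module.
    """

    link_list: pd.DataFrame  # otu_id, metabolite_identity, sign, fid per region
    module_assignment: pd.Series  # identity -> module label
    guild_assignment: pd.Series  # otu_id -> guild label (members only)
    basis_correlation: pd.DataFrame
    pathway_link: pd.DataFrame  # metabolite_identity, pathway_id
    shared_metabolite_pairs: pd.DataFrame  # feature ids in each region
    feature_map: dict = field(default_factory=dict)
    module_factors: dict = field(default_factory=dict)

    def links_for_region(self, region: str) -> pd.DataFrame:
        df = self.link_list.copy()
        df["feature_id"] = df["metabolite_identity"].map(self.feature_map[region])
        return df

    def module_assignment_for(self, region: str) -> pd.Series:
        fmap = self.feature_map[region]
        keep = self.module_assignment.index.intersection(fmap.index)
        s = self.module_assignment.loc[keep]
        return pd.Series(s.to_numpy(), index=[fmap[i] for i in keep])

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.link_list.to_csv(out / "truth_links.tsv", sep="\t", index=False, lineterminator="\n")
        self.module_assignment.rename_axis("metabolite_identity").rename("module").to_csv(
            out / "truth_modules.tsv", sep="\t", lineterminator="\n")
        self.guild_assignment.rename_axis("otu_id").rename("guild").to_csv(
            out / "truth_guilds.tsv", sep="\t", lineterminator="\n")
        self.pathway_link.to_csv(out / "truth_pathway_links.tsv", sep="\t", index=False,
                                 lineterminator="\n")
        self.shared_metabolite_pairs.to_csv(out / "truth_shared_metabolites.tsv", sep="\t",
                                            index=False, lineterminator="\n")


@dataclass
class DatasetBundle:
    """One region's complete observation: counts, intensities, pathways, tree."""

    region: str
    otus: OtuTable
    metabolites: MetaboliteTable
    pathways: PathwayProfile
    tree_newick: str

    def write(self, outdir) -> dict:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "otu_table": out / f"{self.region}_otu_table.tsv",
            "metabolites": out / f"{self.region}_metabolites.tsv",
            "pathways": out / f"{self.region}_pathways.tsv",
            "tree": out / f"{self.region}_tree.nwk",
        }
        write_otu_table(self.otus, paths["otu_table"])
        write_metabolite_table(self.metabolites, paths["metabolites"])
        write_pathway_profile(self.pathways, paths["pathways"])
        write_tree(self.tree_newick, paths["tree"])
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def spearman_to_pearson_weight(target_spearman: float) -> float:
    """Squared latent Pearson correlation giving a target Spearman under a
    bivariate-Gaussian-score coupling: rho = 2 sin(pi * s / 6)."""
    rho = 2.0 * math.sin(math.pi * target_spearman / 6.0)
    return min(rho ** 2, 1.0)


def gaussian_scores(x: np.ndarray) -> np.ndarray:
    """Midrank-based normal scores of a vector (ties share a score)."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.5) / len(x))


def _yule_newick(names, rng) -> str:
    """Pure-birth (Yule) tree over the given tips, strictly positive lengths."""
    nodes = [(str(n), 0.0) for n in names]
    if len(nodes) == 1:
        return f"({nodes[0][0]}:1.0);"
    t = 0.0
    while len(nodes) > 1:
        t += rng.exponential(1.0 / len(nodes))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = (f"({na}:{t - ha:.6f},{nb}:{t - hb:.6f})", t)
        nodes[j] = merged
        nodes.pop(i)
    return nodes[0][0] + ";"


def _taxonomy(n_otus: int, rng) -> pd.Series:
    phyla = [p for p, _ in _PHYLA]
    probs = np.array([w for _, w in _PHYLA])
    probs = probs / probs.sum()
    assignments = rng.choice(len(phyla), size=n_otus, p=probs)
    strings = []
    for i, pi in enumerate(assignments):
        ph = phyla[pi]
        genus = f"g__{ph[:4]}Genus{rng.integers(1, 1 + max(3, n_otus // 12))}" \
            if rng.random() < 0.6 else "g__"
        strings.append(
            f"k__Bacteria;p__{ph};c__{ph}ia;o__{ph}ales;f__{ph}aceae;{genus};s__")
    return pd.Series(strings, name="taxonomy")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _plan_structure(cfg: SynthConfig, rng) -> dict:
    otu_ids = [f"otu{i:04d}" for i in range(cfg.n_otus)]
    mu = rng.normal(0.0, 1.5, size=cfg.n_otus)

    # guilds and link OTUs come from the abundant half so they are detectable
    order = np.argsort(-mu)
    abundant = list(order[: max(cfg.n_otus // 2, cfg.n_guilds * cfg.guild_size + cfg.n_planted_links)])
    guild_members: dict[int, int] = {}
    pos = 0
    for g in range(cfg.n_guilds):
        for _ in range(cfg.guild_size):
            guild_members[abundant[pos]] = g
            pos += 1
    link_pool = [i for i in abundant[pos:]]
    rng.shuffle(link_pool)
    if not cfg.link_otus_from_guilds:
        link_otus = link_pool[: cfg.n_planted_links]
        if len(link_otus) < cfg.n_planted_links:
            raise ConfigurationError("not enough non-guild OTUs for the requested links")

    C = np.eye(cfg.n_otus)
    for i in guild_members:
        for j in guild_members:
            if i == j:
                continue
            if guild_members[i] == guild_members[j]:
                C[i, j] = cfg.guild_corr
            elif cfg.guild_cross_corr and {guild_members[i], guild_members[j]} == {0, 1}:
                C[i, j] = cfg.guild_cross_corr
    if guild_members:
        eig_min = np.linalg.eigvalsh(C).min()
        if eig_min <= 1e-9:
            raise ConfigurationError(
                f"guild correlation structure is not positive definite (min eigenvalue {eig_min:.3g})")

    # metabolite identities: shared pool first, then per-region unique pools
    n_shared = cfg.n_shared()
    n_unique = cfg.n_metabolites - n_shared
    n_ident = n_shared + 2 * n_unique
    identities = [f"met{i:04d}" for i in range(n_ident)]
    shared_ids = identities[:n_shared]
    unique1 = identities[n_shared: n_shared + n_unique]
    unique2 = identities[n_shared + n_unique:]

    pool = list(shared_ids)
    rng.shuffle(pool)
    sizes = cfg.resolved_module_sizes()
    module_assignment = {}
    cursor = 0
    for mi, size in enumerate(sizes, start=1):
        for ident in pool[cursor: cursor + size]:
            module_assignment[ident] = f"module_{mi}"
        cursor += size
    link_met_ids = pool[cursor: cursor + cfg.n_link_metabolites()]

    signs = np.ones(cfg.n_planted_links)
    n_neg = int(round(cfg.frac_negative_links * cfg.n_planted_links))
    signs[:n_neg] = -1.0
    rng.shuffle(signs)
    links = []
    if cfg.link_otus_from_guilds and cfg.n_planted_links:
        # each linked metabolite is tied to OTUs of a single guild, cycling
        # over guilds: the "metabolite-associated microbial community" pattern
        by_guild: dict[int, list[int]] = {}
        for oi, g in guild_members.items():
            by_guild.setdefault(g, []).append(oi)
        # one sign per metabolite: mixed signs on correlated OTUs would cancel
        met_signs = np.ones(len(link_met_ids))
        met_signs[: int(round(cfg.frac_negative_links * len(link_met_ids)))] = -1.0
        rng.shuffle(met_signs)
        li = 0
        for mi, ident in enumerate(link_met_ids):
            members = by_guild[mi % cfg.n_guilds]
            chosen = rng.choice(members, size=cfg.links_per_metabolite, replace=False)
            for oi in chosen:
                if li >= cfg.n_planted_links:
                    break
                links.append((otu_ids[int(oi)], ident, float(met_signs[mi])))
                li += 1
    else:
        for li, oi in enumerate(link_otus):
            ident = link_met_ids[li % len(link_met_ids)] if link_met_ids else None
            links.append((otu_ids[oi], ident, float(signs[li])))

    # masses on a jittered grid: distinct identities separated by > 0.01 m/z
    slots = 80.0 + 0.05 * np.arange(n_ident)
    rng.shuffle(slots)
    masses = slots + rng.uniform(-0.015, 0.015, size=n_ident)
    rts = rng.uniform(0.3, 9.0, size=n_ident)
    modes = rng.choice(["ESI+", "ESI-"], size=n_ident)
    met_meta = pd.DataFrame({"mass": masses, "rt": rts, "mode": modes},
                            index=pd.Index(identities, name="metabolite_identity"))
    met_scale = pd.Series(rng.normal(0.0, 0.8, size=n_ident), index=met_meta.index)

    # pathway profile: the linked pathway's abundance across OTUs is a monotone
    # function of each OTU's planted effect on that metabolite, plus noise
    pathway_ids = [f"PWY{i:04d}" for i in range(cfg.n_pathways)]
    pw_base = rng.normal(0.0, 0.5, size=(cfg.n_otus, cfg.n_pathways))
    pathway_link = []
    for mi, ident in enumerate(link_met_ids):
        pw = pathway_ids[mi % cfg.n_pathways]
        pathway_link.append((ident, pw))
        col = pathway_ids.index(pw)
        for (otu, lident, sign) in links:
            if lident == ident:
                oi = otu_ids.index(otu)
                pw_base[oi, col] += 1.5 * sign
    pw_abund = np.exp(pw_base)
    pw_abund = pw_abund / pw_abund.sum(axis=1, keepdims=True)
    pathways = PathwayProfile(pd.DataFrame(pw_abund, index=pd.Index(otu_ids, name="otu_id"),
                                           columns=pathway_ids))

    taxonomy = _taxonomy(cfg.n_otus, rng)
    taxonomy.index = pd.Index(otu_ids, name="otu_id")
    tree = _yule_newick(otu_ids, rng)

    return {
        "otu_ids": otu_ids, "mu": mu, "C": C,
        "guild_members": {otu_ids[i]: f"guild_{g + 1}" for i, g in guild_members.items()},
        "links": links, "module_assignment": module_assignment,
        "shared_ids": shared_ids, "unique": {REGIONS[0]: unique1, REGIONS[1]: unique2},
        "met_meta": met_meta, "met_scale": met_scale,
        "pathways": pathways, "pathway_link": pathway_link,
        "taxonomy": taxonomy, "tree": tree,
        "chol": np.linalg.cholesky(C),
    }


def _draw_region(cfg: SynthConfig, plan: dict, rng, region: str):
    n = cfg.n_subjects
    otu_ids = plan["otu_ids"]
    sample_ids = [f"subj{i + 1:03d}" for i in range(n)]

    eps = rng.standard_normal((n, cfg.n_otus))
    log_abund = plan["mu"] + eps @ plan["chol"].T
    frac = np.exp(log_abund - log_abund.max(axis=1, keepdims=True))
    frac = frac / frac.sum(axis=1, keepdims=True)
    depth = rng.poisson(cfg.read_depth_mean, size=n)
    counts = np.empty((n, cfg.n_otus), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depth[i], frac[i])
    otu_table = OtuTable(
        pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                     columns=pd.Index(otu_ids, name="otu_id")),
        plan["taxonomy"],
    )
    rel = counts / depth[:, None]

    identities = list(plan["shared_ids"]) + list(plan["unique"][region])
    prefix = region[:3]
    fids = [f"{prefix}_{k:04d}" for k in range(len(identities))]
    fmap = pd.Series(fids, index=pd.Index(identities, name="metabolite_identity"))

    module_labels = sorted(set(plan["module_assignment"].values()))
    factors = {m: rng.standard_normal(n) for m in module_labels}

    # per-metabolite link contributions: Gaussian scores of the linked OTUs'
    # observed relative abundance, averaged when several OTUs feed one metabolite
    link_contrib: dict[str, np.ndarray] = {}
    link_counts: dict[str, int] = {}
    for (otu, ident, sign) in plan["links"]:
        z = gaussian_scores(rel[:, otu_ids.index(otu)]) * sign
        link_contrib[ident] = link_contrib.get(ident, 0.0) + z
        link_counts[ident] = link_counts.get(ident, 0) + 1

    w_mod = cfg.module_corr
    w_link = spearman_to_pearson_weight(cfg.link_effect)
    values = np.empty((n, len(identities)))
    for k, ident in enumerate(identities):
        noise = rng.standard_normal(n)
        module = plan["module_assignment"].get(ident)
        if module is not None:
            values[:, k] = math.sqrt(w_mod) * factors[module] + math.sqrt(1.0 - w_mod) * noise
        elif ident in link_contrib:
            s = link_contrib[ident] / math.sqrt(link_counts[ident])
            values[:, k] = math.sqrt(w_link) * s + math.sqrt(1.0 - w_link) * noise
        else:
            values[:, k] = noise
    scale = plan["met_scale"].loc[identities].to_numpy()
    intensities = np.exp(0.6 * values + scale) * 1.0e4

    meta = plan["met_meta"].loc[identities]
    feature_meta = pd.DataFrame({
        "mz": meta["mass"].to_numpy() + rng.normal(0.0, cfg.mass_jitter_sd, len(identities)),
        "rt": np.maximum(meta["rt"].to_numpy() + rng.normal(0.0, cfg.rt_jitter_sd, len(identities)), 0.0),
        "mode": meta["mode"].to_numpy(),
    }, index=pd.Index(fids, name="feature_id"))
    met_table = MetaboliteTable(
        pd.DataFrame(intensities, index=pd.Index(sample_ids, name="sample_id"),
                     columns=pd.Index(fids, name="feature_id")),
        feature_meta,
    )
    bundle = DatasetBundle(region, otu_table, met_table, plan["pathways"], plan["tree"])
    factor_df = pd.DataFrame(factors, index=pd.Index(sample_ids, name="sample_id")) \
        if factors else pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    return bundle, fmap, factor_df


def study_null_config(seed: int) -> SynthConfig:
    """The emulated study's dimensions with *no* planted structure:
    46 subjects, 300 OTUs, 200 metabolites, independent basis abundances.
    Used for false-discovery and calibration checks."""
    return SynthConfig(seed=seed, n_subjects=46, n_otus=300, n_metabolites=200,
                       n_modules=0, n_planted_links=0, n_guilds=0, guild_size=0,
                       guild_corr=0.0, shared_metabolite_fraction=0.7)


def study_planted_config(seed: int) -> SynthConfig:
    """The emulated study's dimensions with the full planted structure:
    3 metabolite modules (15/20/25 members at within-correlation 0.8),
    30 OTU-metabolite links targeting |Spearman| 0.6 (30% negative), and two
    10-OTU guilds with basis correlation 0.7."""
    return SynthConfig(seed=seed, n_subjects=46, n_otus=300, n_metabolites=200,
                       n_modules=3, module_sizes=(15, 20, 25), n_planted_links=30,
                       link_effect=0.6, frac_negative_links=0.3, n_guilds=2,
                       guild_size=10, guild_corr=0.7, shared_metabolite_fraction=0.7)


def generate_paired_dataset(cfg: SynthConfig):
    """Generate (region1, region2, truth) under the planted-structure model.

    Byte-identical outputs for identical configs (the master seed spawns
    independent streams for the shared structure and each region).
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_struct, s_r1, s_r2 = ss.spawn(3)
    plan = _plan_structure(cfg, np.random.default_rng(s_struct))
    bundle1, fmap1, factors1 = _draw_region(cfg, plan, np.random.default_rng(s_r1), REGIONS[0])
    bundle2, fmap2, factors2 = _draw_region(cfg, plan, np.random.default_rng(s_r2), REGIONS[1])

    link_rows = []
    for (otu, ident, sign) in plan["links"]:
        link_rows.append({
            "otu_id": otu, "metabolite_identity": ident, "sign": sign,
            "feature_region1": fmap1.get(ident), "feature_region2": fmap2.get(ident),
        })
    link_list = pd.DataFrame(link_rows, columns=["otu_id", "metabolite_identity", "sign",
                                                 "feature_region1", "feature_region2"])
    shared_pairs = pd.DataFrame({
        "feature_region1": [fmap1[i] for i in plan["shared_ids"]],
        "feature_region2": [fmap2[i] for i in plan["shared_ids"]],
        "metabolite_identity": plan["shared_ids"],
    })
    truth = GroundTruth(
        link_list=link_list,
        module_assignment=pd.Series(plan["module_assignment"], dtype=object),
        guild_assignment=pd.Series(plan["guild_members"], dtype=object),
        basis_correlation=pd.DataFrame(plan["C"], index=plan["otu_ids"], columns=plan["otu_ids"]),
        pathway_link=pd.DataFrame(plan["pathway_link"],
                                  columns=["metabolite_identity", "pathway_id"]),
        shared_metabolite_pairs=shared_pairs,
        feature_map={REGIONS[0]: fmap1, REGIONS[1]: fmap2},
        module_factors={REGIONS[0]: factors1, REGIONS[1]: factors2},
    )
    return bundle1, bundle2, truth
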