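"""End-to-end orchestration of the paired-region inter-omic analysis.

Stage order: preprocess -> modules -> network -> concordance -> clusters ->
function -> community -> identify. Every stage writes tab-delimited outputs
into the configured output directory and registers them in a manifest of
SHA-256 content hashes; re-running with the same config and master seed
reproduces identical hashes. The master seed deterministically spawns
per-stage, per-region seeds so stages stay independent.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as _clusters
from . import community as _community
from . import concordance as _concordance
from . import functional as _functional
from . import identity as _identity
from . import io as _io
from . import modules as _modules
from . import network as _network
from ._utils import child_seed, logger

STAGES = ("preprocess", "modules", "network", "concordance", "clusters",
          "function", "community", "identify")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the analysis's canonical values:
    rarefaction depth 30,000; detection in >= 2 samples; 18% prevalence;
    q < 0.2; minimum module size 10; 1,000 community permutations; 20 ppm;
    cross-region match tolerances 0.005 m/z and 0.04 min; SparCC
    supplementary thresholds +/-0.2."""

    inputs: dict = field(default_factory=dict)  # region -> {otu_table, metabolites, pathways, tree}
    output_dir: str = "syntropy_out"
    seed: int = 0
    rarefaction_depth: int = 30_000
    min_detection_samples: int = 2
    prevalence_fraction: float = 0.18
    community_min_samples: int = 6
    q_threshold: float = 0.2
    soft_power: int | str = "auto"
    min_module_size: int = 10
    n_clusters: int | str = "auto"
    k_range: tuple = (2, 3, 4, 5, 6, 7)
    prediction_strength_threshold: float = 0.8
    prediction_strength_splits: int = 20
    n_permutations: int = 1000
    ordination_permutations: int = 999
    ppm: float = 20.0
    match_dmass: float = 0.005
    match_drt: float = 0.04
    sparcc_thresholds: tuple = (0.2, -0.2)
    min_otus_concordance: int = 5
    community_min_group: int = 4
    community_max_groups: int = 8
    min_significant_otus: int = 2
    compound_db: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known - {"simulate"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("k_range", "sparcc_thresholds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Holds per-region state between stages; see :func:`run_pipeline`."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.written: list[Path] = []

    # -- helpers ---------------------------------------------------------
    def _write(self, df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = self.out / name
        df.to_csv(path, sep="\t", index=index, lineterminator="\n")
        self.written.append(path)
        return path

    @property
    def regions(self) -> list[str]:
        return list(self.cfg.inputs)

    def _seed(self, stage: str, region: str | None = None) -> int:
        tokens = [STAGES.index(stage)]
        if region is not None:
            tokens.append(self.regions.index(region))
        return child_seed(self.cfg.seed, *tokens)

    # -- stages ----------------------------------------------------------
    def preprocess(self) -> None:
        cfg = self.cfg
        for region, paths in cfg.inputs.items():
            otus = _io.read_otu_table(paths["otu_table"])
            otus = _io.rarefy(otus, cfg.rarefaction_depth, seed=self._seed("preprocess", region))
            otus = _io.filter_min_samples(otus, cfg.min_detection_samples)
            otus_prev = _io.filter_prevalence(otus, cfg.prevalence_fraction)
            otus_comm = _io.filter_min_samples(otus, cfg.community_min_samples)
            mets = _io.read_metabolite_table(paths["metabolites"])
            mets = mets.__class__(mets.intensities.loc[otus.sample_ids], mets.feature_meta)
            mets = _io.filter_prevalence(mets, cfg.prevalence_fraction)
            pathways = _io.read_pathway_profile(paths["pathways"]) if paths.get("pathways") else None
            tree = Path(paths["tree"]).read_text() if paths.get("tree") else None
            self.state[region] = {
                "otus": otus_prev, "otus_community": otus_comm, "metabolites": mets,
                "pathways": pathways, "tree": tree,
            }
            _io.write_otu_table(otus_prev, self.out / f"{region}_otus_preprocessed.tsv")
            self.written.append(self.out / f"{region}_otus_preprocessed.tsv")
            _io.write_metabolite_table(mets, self.out / f"{region}_metabolites_preprocessed.tsv")
            self.written.append(self.out / f"{region}_metabolites_preprocessed.tsv")
            logger.info("preprocess[%s]: %d samples, %d OTUs, %d metabolites", region,
                        len(otus_prev.sample_ids), len(otus_prev.otu_ids), len(mets.feature_ids))

    def modules(self) -> None:
        cfg = self.cfg
        for region, st in self.state.items():
            x = np.log(st["metabolites"].intensities + 1.0)
            ms = _modules.build_modules(x, power=cfg.soft_power, min_size=cfg.min_module_size)
            st["modules"] = ms
            st["analytes"] = _modules.combine_with_unclustered(ms, x)
            meta = st["metabolites"].feature_meta
            table = pd.DataFrame({
                "feature_id": ms.assignment.index,
                "mode": meta.loc[ms.assignment.index, "mode"].to_numpy(),
                "mz": meta.loc[ms.assignment.index, "mz"].to_numpy(),
                "rt": meta.loc[ms.assignment.index, "rt"].to_numpy(),
                "module_label": ms.assignment.to_numpy(),
            })
            self._write(table, f"{region}_module_assignment.tsv")
            logger.info("modules[%s]: power=%s, %d modules, %d unclustered", region,
                        ms.power, len(ms.module_labels),
                        int((ms.assignment == _modules.UNCLUSTERED).sum()))

    def network(self) -> None:
        cfg = self.cfg
        for region, st in self.state.items():
            net = _network.spearman_all_pairs(st["otus"], st["analytes"])
            net = _network.add_qvalues(net)
            sig = _network.significant_edges(net, cfg.q_threshold)
            st["net_full"], st["net_sig"] = net, sig
            self._write(sig.edges, f"{region}_significant_edges.tsv")
            summ = _network.summarize_network(sig, st["otus"].otu_ids, st["otus"].taxonomy)
            rows = [{"metric": "total_edges", "value": summ.total_edges},
                    {"metric": "unique_otu_nodes", "value": summ.unique_otu_nodes},
                    {"metric": "unique_analyte_nodes", "value": summ.unique_analyte_nodes},
                    {"metric": "mean_edges_per_otu", "value": summ.mean_edges_per_otu},
                    {"metric": "mean_edges_per_analyte", "value": summ.mean_edges_per_analyte}]
            rows += [{"metric": f"ratio_{ph}", "value": v} for ph, v in sorted(summ.per_phylum_ratio.items())]
            self._write(pd.DataFrame(rows), f"{region}_network_summary.tsv")
            genus = _network.bin_by_genus(sig, st["otus"].taxonomy, st["otus"].relative_abundance())
            self._write(genus.reset_index(), f"{region}_genus_interactions.tsv")
            logger.info("network[%s]: %d significant edges (q<%g)", region, len(sig), cfg.q_threshold)

    def concordance(self) -> None:
        cfg = self.cfg
        rows = []
        for region, st in self.state.items():
            seed = self._seed("concordance", region)
            pca_m = _concordance.pca_euclidean(st["otus"].relative_abundance(), 2)
            pca_x = _concordance.pca_euclidean(st["analytes"], 2)
            pro = _concordance.procrustes_test(pca_m, pca_x, cfg.ordination_permutations, seed=seed)
            coi = _concordance.coinertia_rv(st["otus"].relative_abundance(), st["analytes"],
                                            cfg.ordination_permutations, seed=seed + 1)
            st["procrustes"], st["coinertia"] = pro, coi
            rows.append({"region": region, "statistic": "procrustes_m12_squared",
                         "value": pro.statistic, "p": pro.p_value})
            rows.append({"region": region, "statistic": "RV", "value": coi.statistic,
                         "p": coi.p_value})
            w = coi.per_feature_weights.copy()
            w.insert(0, "region", region)
            self._write(w, f"{region}_coinertia_weights.tsv")
        self._write(pd.DataFrame(rows), "concordance.tsv")

    def clusters(self) -> None:
        cfg = self.cfg
        for region, st in self.state.items():
            profiles = _clusters.correlation_profile_matrix(
                st["net_full"], st["net_sig"], cfg.min_significant_otus)
            k_star, curve = _clusters.prediction_strength(
                profiles, [k for k in cfg.k_range if 2 * k <= profiles.shape[0]],
                n_splits=cfg.prediction_strength_splits,
                threshold=cfg.prediction_strength_threshold,
                seed=self._seed("clusters", region))
            k = max(2, k_star) if cfg.n_clusters == "auto" else int(cfg.n_clusters)
            ca = _clusters.cluster_otus(profiles, k)
            st["cluster_assignment"], st["ps_curve"] = ca, curve
            out = pd.DataFrame({"otu_id": ca.labels.index,
                                "taxonomy": st["otus"].taxonomy.loc[ca.labels.index].to_numpy(),
                                "cluster": ca.labels.to_numpy()})
            self._write(out, f"{region}_cluster_assignment.tsv")
            self._write(curve, f"{region}_prediction_strength.tsv")
            comp = _clusters.cluster_composition(ca, st["otus"].taxonomy)
            self._write(comp.reset_index(), f"{region}_cluster_composition.tsv")
            logger.info("clusters[%s]: predicted k*=%d, cut to k=%d", region, k_star, k)
        if len(self.regions) == 2:
            r1, r2 = self.regions
            shared = [o for o in self.state[r1]["cluster_assignment"].labels.index
                      if o in set(self.state[r2]["cluster_assignment"].labels.index)]
            overlap = _clusters.cross_region_overlap(
                self.state[r1]["cluster_assignment"], self.state[r2]["cluster_assignment"], shared)
            self._write(overlap, "cluster_overlap.tsv")

    def function(self) -> None:
        cfg = self.cfg
        db = _identity.read_compound_db(cfg.compound_db) if cfg.compound_db \
            else _identity.load_demo_compound_db()
        for region, st in self.state.items():
            if st["pathways"] is None:
                logger.warning("function[%s]: no pathway profile supplied; stage skipped", region)
                continue
            kw = _functional.cluster_pathway_tests(st["pathways"], st["cluster_assignment"])
            self._write(kw.reset_index(), f"{region}_cluster_pathway_tests.tsv")
            id_map = _identity.pathway_candidates(st["metabolites"], db, ppm=cfg.ppm)
            conc = _functional.metabolite_metagenome_concordance(
                st["net_sig"], st["net_full"], st["pathways"], id_map,
                min_otus=cfg.min_otus_concordance)
            st["concordance_records"] = conc
            self._write(conc, f"{region}_metabolite_metagenome_concordance.tsv")

    def community(self) -> None:
        cfg = self.cfg
        for region, st in self.state.items():
            table = st["otus_community"]
            if st["tree"] is None:
                logger.warning("community[%s]: no phylogeny supplied; using a "
                               "unit-branch taxonomy cladogram as a surrogate", region)
                st["tree"] = _community.taxonomy_cladogram(table.taxonomy)
            support = st["net_sig"].edges.groupby("analyte_id")["otu_id"].nunique()
            groups = support[support >= cfg.community_min_group] \
                .sort_values(ascending=False).head(cfg.community_max_groups)
            rows = []
            for gi, analyte in enumerate(groups.index):
                edges = st["net_sig"].edges
                sub = edges[edges["analyte_id"] == analyte]
                members = [o for o in sub["otu_id"].unique() if o in set(table.otu_ids)]
                if len(members) < cfg.community_min_group:
                    continue
                res = _community.group_structure_test(
                    table, members, n_perm=cfg.n_permutations,
                    thresholds=cfg.sparcc_thresholds,
                    seed=self._seed("community", region) + gi,
                    group_id=str(analyte), tree=st["tree"],
                    association_rhos=sub["rho"].to_numpy())
                row = res.to_row()
                row["region"] = region
                rows.append(row)
            if rows:
                self._write(pd.DataFrame(rows), f"{region}_community_structure.tsv")

    def identify(self) -> None:
        cfg = self.cfg
        db = _identity.read_compound_db(cfg.compound_db) if cfg.compound_db \
            else _identity.load_demo_compound_db()
        for region, st in self.state.items():
            ann = _identity.annotate_table(st["metabolites"], db, ppm=cfg.ppm)
            if len(ann):
                ann = ann.assign(kegg_pathways=ann["kegg_pathways"].map("|".join))
            self._write(ann, f"{region}_putative_ids.tsv")
        if len(self.regions) == 2:
            r1, r2 = self.regions
            matches = _identity.match_across_regions(
                self.state[r1]["metabolites"], self.state[r2]["metabolites"],
                cfg.match_dmass, cfg.match_drt)
            self._write(matches, "shared_metabolites.tsv")

    # -- driver ----------------------------------------------------------
    def run(self, stages=None) -> dict:
        wanted = list(STAGES) if stages is None else list(stages)
        upto = max(STAGES.index(s) for s in wanted)
        for stage in STAGES[: upto + 1]:
            try:
                getattr(self, stage)()
            except Exception as exc:
                raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        manifest = {str(p.relative_to(self.out)): _sha256(p) for p in sorted(set(self.written))}
        with open(self.out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the analysis (all stages, or everything up to the ones named) and
    return the output manifest of SHA-256 hashes."""
    return Pipeline(cfg).run(stages=stages)
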