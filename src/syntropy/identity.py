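"""Putative metabolite identification and cross-region feature matching.

Identification is adduct-aware exact-mass lookup: the observed m/z is
corrected for each adduct of the acquisition mode ([M+H]+ / [M+Na]+ in ESI+,
[M-H]- / [M+Cl]- in ESI-) and the implied neutral mass is matched against a
compound table inside a relative ppm window (default 20 ppm). Cross-region
matching declares two features the same metabolite when BOTH the mass
difference (<= 0.005 m/z) and the retention-time difference (<= 0.04 min)
are within tolerance, with greedy one-to-one resolution of multi-hits.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import MetaboliteTable

PROTON = 1.007276466  # H+ (H minus the electron mass)
SODIUM_ION = 22.989218
CHLORIDE_ION = 34.968853

#: Fixed adduct table: (mode, name, m/z shift relative to the neutral mass).
ADDUCT_RULES = (
    ("ESI+", "[M+H]+", +PROTON),
    ("ESI+", "[M+Na]+", +SODIUM_ION),
    ("ESI-", "[M-H]-", -PROTON),
    ("ESI-", "[M+Cl]-", +CHLORIDE_ION),
)


@dataclass
class CompoundDb:
    """Compound lookup table with monoisotopic masses and KEGG pathway labels.

    ``records`` columns: compound_id, name, monoisotopic_mass, source_db,
    kegg_pathways (list), origin_class (mammalian | bacterial | plant |
    unknown).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.records["compound_id"].duplicated().any():
            raise ValueError("duplicate compound ids")
        if (self.records["monoisotopic_mass"] <= 0).any():
            raise ValueError("monoisotopic masses must be positive")

    def __len__(self) -> int:
        return len(self.records)


def read_compound_db(path) -> CompoundDb:
    df = pd.read_csv(path, sep="\t")
    df["kegg_pathways"] = df["kegg_pathways"].fillna("").map(
        lambda s: [p for p in str(s).split("|") if p])
    if "origin_class" not in df:
        df["origin_class"] = "unknown"
    return CompoundDb(df)


def load_demo_compound_db() -> CompoundDb:
    """The small compound table bundled for demonstrations and pipeline runs.

    A synthetic stand-in for the large public compound databases: a few dozen
    gut-relevant compounds with masses computed from their formulas.
    """
    with resources.as_file(resources.files("syntropy.data") / "compounds_demo.tsv") as p:
        return read_compound_db(p)


def putative_ids(mz: float, mode: str, db: CompoundDb, ppm: float = 20.0,
                 mz_range: tuple = (50.0, 850.0), origin_filter=None) -> pd.DataFrame:
    """Candidate compounds for one observed m/z, sorted by |ppm error|.

    For each adduct rule of the acquisition mode, the neutral mass
    mz - shift is compared against each compound's monoisotopic mass;
    candidates within ``ppm`` (inclusive) are returned annotated with the
    adduct and signed ppm error. ``origin_filter`` optionally restricts the
    result to given origin classes. An empty frame is a valid result.
    """
    if not mz_range[0] <= mz <= mz_range[1]:
        raise ValueError(f"m/z {mz} outside instrument range {mz_range}")
    rows = []
    masses = db.records["monoisotopic_mass"].to_numpy(float)
    for rule_mode, adduct, shift in ADDUCT_RULES:
        if rule_mode != mode:
            continue
        neutral = mz - shift
        err_ppm = (neutral - masses) / masses * 1e6
        hit = np.abs(err_ppm) <= ppm
        for idx in np.nonzero(hit)[0]:
            rec = db.records.iloc[idx]
            rows.append({"compound_id": rec["compound_id"], "name": rec["name"],
                         "adduct": adduct, "ppm_error": float(err_ppm[idx]),
                         "kegg_pathways": rec["kegg_pathways"],
                         "origin_class": rec.get("origin_class", "unknown")})
    out = pd.DataFrame(rows, columns=["compound_id", "name", "adduct", "ppm_error",
                                      "kegg_pathways", "origin_class"])
    if origin_filter is not None and len(out):
        out = out[out["origin_class"].isin(set(origin_filter))]
    return out.reindex(out["ppm_error"].abs().sort_values(kind="mergesort").index).reset_index(drop=True)


def annotate_table(table: MetaboliteTable, db: CompoundDb, ppm: float = 20.0,
                   mz_range: tuple = (50.0, 850.0)) -> pd.DataFrame:
    """Putative IDs for every feature of a table (long format)."""
    frames = []
    for fid, meta in table.feature_meta.iterrows():
        if not mz_range[0] <= meta["mz"] <= mz_range[1]:
            continue
        cands = putative_ids(meta["mz"], meta["mode"], db, ppm=ppm, mz_range=mz_range)
        if len(cands):
            cands.insert(0, "feature_id", fid)
            frames.append(cands)
    if not frames:
        return pd.DataFrame(columns=["feature_id", "compound_id", "name", "adduct",
                                     "ppm_error", "kegg_pathways", "origin_class"])
    return pd.concat(frames, ignore_index=True)


def pathway_candidates(table: MetaboliteTable, db: CompoundDb, ppm: float = 20.0) -> dict:
    """feature_id -> [(compound name, pathway), ...] for the concordance stage."""
    ann = annotate_table(table, db, ppm=ppm)
    id_map: dict = {}
    for _, row in ann.iterrows():
        for pw in row["kegg_pathways"]:
            pair = (row["name"], pw)
            id_map.setdefault(row["feature_id"], [])
            if pair not in id_map[row["feature_id"]]:
                id_map[row["feature_id"]].append(pair)
    return id_map


def match_across_regions(a: MetaboliteTable, b: MetaboliteTable,
                         max_dmass: float = 0.005, max_drt: float = 0.04) -> pd.DataFrame:
    """Greedy one-to-one matching of features between two regions.

    A pair qualifies only when BOTH |delta m/z| <= ``max_dmass`` AND
    |delta RT| <= ``max_drt`` hold and the ion mode agrees; qualifying pairs
    are consumed in ascending combined normalized distance (ties broken by
    smaller mass difference), so the match set is symmetric in the two
    tables. Unmatched features are listed with a missing partner.
    """
    fa = a.feature_meta
    fb = b.feature_meta
    cands = []
    for mode in sorted(set(fa["mode"]) & set(fb["mode"])):
        ma = fa[fa["mode"] == mode]
        mb = fb[fb["mode"] == mode]
        dm = np.abs(ma["mz"].to_numpy()[:, None] - mb["mz"].to_numpy()[None, :])
        dr = np.abs(ma["rt"].to_numpy()[:, None] - mb["rt"].to_numpy()[None, :])
        ok = (dm <= max_dmass) & (dr <= max_drt)
        for i, j in zip(*np.nonzero(ok)):
            score = dm[i, j] / max_dmass + dr[i, j] / max_drt
            cands.append((score, dm[i, j], str(ma.index[i]), str(mb.index[j]),
                          ma.index[i], mb.index[j], dr[i, j]))
    cands.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    used_a: set = set()
    used_b: set = set()
    rows = []
    for score, dmass, _, _, ia, jb, drt in cands:
        if ia in used_a or jb in used_b:
            continue
        used_a.add(ia)
        used_b.add(jb)
        rows.append({"feature_region1": ia, "feature_region2": jb,
                     "d_mass": float(dmass), "d_rt": float(drt), "matched": True})
    for ia in fa.index:
        if ia not in used_a:
            rows.append({"feature_region1": ia, "feature_region2": None,
                         "d_mass": np.nan, "d_rt": np.nan, "matched": False})
    for jb in fb.index:
        if jb not in used_b:
            rows.append({"feature_region1": None, "feature_region2": jb,
                         "d_mass": np.nan, "d_rt": np.nan, "matched": False})
    return pd.DataFrame(rows, columns=["feature_region1", "feature_region2",
                                       "d_mass", "d_rt", "matched"])
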