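"""Tables, trees, and the preprocessing filters applied before any analysis.

The on-disk dialects are deliberately plain: a classic tab-delimited OTU table
(rows = OTUs, columns = samples, trailing ``taxonomy`` column), a feature table
with per-feature m/z, retention time and ion mode followed by per-sample
intensities, an OTU x pathway relative-abundance table, and newick trees.
All writers emit UTF-8 with LF endings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import get_rng, logger

TAXONOMY_COL = "taxonomy"
_RANKS = 7


class ParseError(ValueError):
    """Raised for malformed input tables; message carries the line number."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Sample x OTU count table with a 7-rank taxonomy string per OTU.

    ``counts`` is samples x OTUs (non-negative integers); ``taxonomy`` maps
    every OTU id to a ``k__;p__;c__;o__;f__;g__;s__`` style string (ranks may
    be empty).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"OTUs lacking taxonomy: {sorted(missing)[:5]}")
        self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1).replace(0, np.nan)
        return self.counts.div(totals, axis=0).fillna(0.0)

    def __eq__(self, other) -> bool:  # round-trip convenience
        return (
            isinstance(other, OtuTable)
            and self.counts.shape == other.counts.shape
            and self.counts.equals(other.counts)
            and self.taxonomy.equals(other.taxonomy)
        )


@dataclass
class MetaboliteTable:
    """Sample x feature intensity table with (m/z, RT, ion mode) metadata.

    ``feature_meta`` is indexed by feature id with columns ``mz`` (m/z),
    ``rt`` (minutes) and ``mode`` (``ESI+``/``ESI-``).
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        meta = self.feature_meta.reindex(self.intensities.columns)
        if meta["mz"].isna().any():
            raise ValueError("every feature needs mz/rt/mode metadata")
        if (meta["mz"] <= 0).any():
            raise ValueError("mz must be positive")
        if (meta["rt"] < 0).any():
            raise ValueError("rt must be non-negative")
        self.feature_meta = meta

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list:
        return list(self.intensities.columns)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MetaboliteTable)
            and self.intensities.equals(other.intensities)
            and np.allclose(self.feature_meta[["mz", "rt"]], other.feature_meta[["mz", "rt"]])
            and list(self.feature_meta["mode"]) == list(other.feature_meta["mode"])
        )


@dataclass
class PathwayProfile:
    """OTU x KEGG-pathway relative genomic proportions (imputed metagenomes)."""

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("pathway abundances must be non-negative")

    @property
    def otu_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def pathway_ids(self) -> list:
        return list(self.abundance.columns)

    def renormalized(self) -> "PathwayProfile":
        totals = self.abundance.sum(axis=1).replace(0, np.nan)
        return PathwayProfile(self.abundance.div(totals, axis=0).fillna(0.0))


# ---------------------------------------------------------------------------
# taxonomy helpers
# ---------------------------------------------------------------------------

def split_ranks(tax: str) -> list[str]:
    parts = [p.strip() for p in str(tax).split(";")]
    parts += [""] * (_RANKS - len(parts))
    return parts[:_RANKS]


def _rank_value(tax: str, idx: int, prefix: str) -> str | None:
    val = split_ranks(tax)[idx]
    if val in ("", prefix):
        return None
    return val[len(prefix):] if val.startswith(prefix) else val


def phylum_of(tax: str) -> str | None:
    return _rank_value(tax, 1, "p__")


def genus_of(tax: str) -> str | None:
    """Genus = rank 6 of the 7-rank string; empty or bare ``g__`` is unresolved."""
    return _rank_value(tax, 5, "g__")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_rows(path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_otu_table(path, otus_as_rows: bool = True) -> OtuTable:
    """Read a classic tab-delimited OTU table.

    Default dialect: rows = OTUs, columns = samples, final column = taxonomy.
    ``otus_as_rows=False`` reads the transpose (rows = samples, final row =
    taxonomy).
    """
    rows = _read_rows(path)
    if not rows:
        raise ParseError("empty file")
    header = rows[0]
    width = len(header)
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(f"line {ln}: expected {width} fields, got {len(row)}")
    if not otus_as_rows:
        rows = [list(r) for r in zip(*rows)]
        header = rows[0]
    if header[-1] != TAXONOMY_COL:
        raise ParseError(f"line 1: last column must be '{TAXONOMY_COL}', got '{header[-1]}'")
    sample_ids = header[1:-1]
    otu_ids, tax, data = [], [], []
    for ln, row in enumerate(rows[1:], start=2):
        otu_ids.append(row[0])
        tax.append(row[-1])
        vals = []
        for col, cell in zip(sample_ids, row[1:-1]):
            try:
                v = int(cell)
            except ValueError as exc:
                raise ParseError(f"line {ln}, sample '{col}': not an integer count: '{cell}'") from exc
            if v < 0:
                raise ParseError(f"line {ln}, sample '{col}': negative count '{cell}'")
            vals.append(v)
        data.append(vals)
    if len(set(otu_ids)) != len(otu_ids):
        raise ParseError("duplicate OTU ids")
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError("duplicate sample ids")
    counts = pd.DataFrame(
        np.array(data, dtype=np.int64).T if data else np.zeros((len(sample_ids), 0), dtype=np.int64),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(otu_ids, name="otu_id"),
    )
    return OtuTable(counts, pd.Series(tax, index=counts.columns, name=TAXONOMY_COL, dtype=object))


def write_otu_table(table: OtuTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#OTU ID\t" + "\t".join(map(str, table.sample_ids)) + f"\t{TAXONOMY_COL}\n")
        mat = table.counts.to_numpy().T
        for i, otu in enumerate(table.otu_ids):
            row = "\t".join(str(int(v)) for v in mat[i]) if mat.shape[1] else ""
            sep = "\t" if mat.shape[1] else ""
            fh.write(f"{otu}\t{row}{sep}{table.taxonomy.iloc[i]}\n")


def read_metabolite_table(path) -> MetaboliteTable:
    rows = _read_rows(path)
    if not rows:
        raise ParseError("empty file")
    header = rows[0]
    if header[:4] != ["feature_id", "mz", "rt", "mode"]:
        raise ParseError("line 1: header must start with feature_id, mz, rt, mode")
    sample_ids = header[4:]
    fids, meta, data = [], [], []
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"line {ln}: expected {len(header)} fields, got {len(row)}")
        fids.append(row[0])
        try:
            meta.append((float(row[1]), float(row[2]), row[3]))
            data.append([float(c) for c in row[4:]])
        except ValueError as exc:
            raise ParseError(f"line {ln}: non-numeric value") from exc
    idx = pd.Index(fids, name="feature_id")
    intens = pd.DataFrame(
        np.array(data, float).T if data else np.zeros((len(sample_ids), 0)),
        index=pd.Index(sample_ids, name="sample_id"), columns=idx,
    )
    fm = pd.DataFrame(meta, index=idx, columns=["mz", "rt", "mode"]) if meta else pd.DataFrame(
        columns=["mz", "rt", "mode"], index=idx)
    return MetaboliteTable(intens, fm)


def write_metabolite_table(table: MetaboliteTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\tmz\trt\tmode\t" + "\t".join(map(str, table.sample_ids)) + "\n")
        mat = table.intensities.to_numpy().T
        for i, fid in enumerate(table.feature_ids):
            m = table.feature_meta.iloc[i]
            vals = "\t".join(repr(float(v)) for v in mat[i])
            fh.write(f"{fid}\t{float(m['mz'])!r}\t{float(m['rt'])!r}\t{m['mode']}\t{vals}\n")


def read_pathway_profile(path) -> PathwayProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "otu_id"
    return PathwayProfile(df)


def write_pathway_profile(profile: PathwayProfile, path) -> None:
    profile.abundance.rename_axis("otu_id").to_csv(path, sep="\t", lineterminator="\n")


def read_tree(path):
    """Read a newick phylogeny as an ``skbio.TreeNode``."""
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def write_tree(newick: str, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(newick.rstrip("\n") + "\n")


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

def _as_frame(table):
    if isinstance(table, OtuTable):
        return table.counts, "otu"
    if isinstance(table, MetaboliteTable):
        return table.intensities, "metabolite"
    return table, None


def _rebuild(table, frame):
    if isinstance(table, OtuTable):
        return OtuTable(frame, table.taxonomy.loc[frame.columns])
    if isinstance(table, MetaboliteTable):
        return MetaboliteTable(frame, table.feature_meta.loc[frame.columns])
    return frame


def rarefy(table: OtuTable, depth: int = 30_000, seed=None) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (with a logged
    warning), mirroring standard practice. Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = get_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped[:10])
    out = np.empty((len(keep), table.counts.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    counts = pd.DataFrame(out, index=pd.Index(keep, name="sample_id"), columns=table.counts.columns)
    return OtuTable(counts, table.taxonomy)


def filter_min_samples(table, min_samples: int, detection: float = 0.0):
    """Keep features detected (value > ``detection``) in >= ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    frame, _ = _as_frame(table)
    keep = (frame > detection).sum(axis=0) >= min_samples
    return _rebuild(table, frame.loc[:, keep])


def filter_prevalence(table, min_fraction: float = 0.18, background: float = 0.0):
    """Drop analytes measured above background in fewer than ``min_fraction`` of subjects.

    The boundary is inclusive: prevalence exactly equal to ``min_fraction`` is
    retained ("fewer than" is a strict removal rule).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    frame, _ = _as_frame(table)
    n = frame.shape[0]
    if n == 0:
        return _rebuild(table, frame)
    detected = (frame > background).sum(axis=0)
    # integer comparison avoids float-boundary surprises at exactly 18%
    keep = detected >= math.ceil(min_fraction * n - 1e-9)
    return _rebuild(table, frame.loc[:, keep])
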