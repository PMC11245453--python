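"""Data model and readers/writers for OTU tables, metadata, taxonomy, trees and rule files.

The in-memory convention throughout the package is *taxa as rows, samples as
columns*, matching the layout amplicon pipelines usually emit.  The central
container is :class:`OtuTable`, a thin validated wrapper around a pandas
DataFrame of non-negative integer counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

__all__ = [
    "REGIMES",
    "SEASONS",
    "RANKS",
    "OtuTable",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "lineage_of",
    "read_tree",
    "write_tree",
    "read_function_rules",
    "write_function_rules",
    "relative_abundance",
    "aggregate_by_rank",
    "rarefy",
]

#: Fertilization regimes: untreated control, chemical fertilizer, organic
#: fertilizer and compound microbial (Bacillus-based) fertilizer.
REGIMES = ("CK", "CF", "OF", "CMF")

#: Sampling seasons (months spanning wet and dry periods of a subtropical year).
SEASONS = ("Apr", "Jul", "Oct", "Jan")

#: Fixed taxonomy rank order, kingdom through genus.  Unassigned ranks are
#: empty strings, never dropped.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class OtuTable:
    """A validated taxa-by-samples count matrix.

    Parameters
    ----------
    data :
        DataFrame with taxon ids as the index and sample ids as columns,
        holding non-negative integer counts.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_arrays(cls, counts, taxon_ids, sample_ids) -> "OtuTable":
        df = pd.DataFrame(np.asarray(counts), index=list(taxon_ids), columns=list(sample_ids))
        return cls(df)

    # -- accessors ---------------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def filter_taxa(self, keep) -> "OtuTable":
        """Return a new table restricted to ``keep`` (iterable of taxon ids)."""
        keep = [t for t in self.taxon_ids if t in set(keep)]
        return OtuTable(self.data.loc[keep])

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValueError(f"duplicate taxon id(s): {dups}")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise ValueError(f"duplicate sample id(s): {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(~np.isfinite(arr.astype(float))):
            raise ValueError("counts must be finite")
        frac, _ = np.modf(arr.astype(float))
        bad = np.argwhere(frac != 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-integer count at taxon {df.index[i]!r}, sample {df.columns[j]!r}: {arr[i, j]}"
            )
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at taxon {df.index[i]!r}, sample {df.columns[j]!r}: {arr[i, j]}"
            )
        zero = df.sum(axis=0) == 0
        if zero.any():
            raise ValueError(f"all-zero sample(s): {list(df.columns[zero])}")
        # normalize dtype and axis naming
        self.data = df.astype(np.int64)
        self.data.index.name = None
        self.data.columns.name = None


def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table from ``path``.

    TSV dialect: first column holds taxon ids, header row holds sample ids.
    BIOM v1 (JSON) and v2 (HDF5) are both accepted via the biom-format
    library.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return OtuTable(df)
    if format == "biom":
        import biom

        bt = biom.load_table(str(path))
        df = pd.DataFrame(
            bt.matrix_data.toarray(),
            index=[str(i) for i in bt.ids("observation")],
            columns=[str(s) for s in bt.ids("sample")],
        )
        return OtuTable(df)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        out = table.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")
        return
    if format == "biom":
        import biom

        bt = biom.Table(
            table.counts.astype(float), table.taxon_ids, table.sample_ids
        )
        # fixed creation date keeps equal tables byte-identical on disk
        from datetime import datetime

        with open(path, "w") as fh:
            bt.to_json("rhizoasm", direct_io=fh, creation_date=datetime(1970, 1, 1))
        return
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame, table: OtuTable | None = None) -> pd.DataFrame:
    required = {"sample_id", "regime", "season", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = sorted(set(meta["sample_id"][meta["sample_id"].duplicated()]))
        raise ValueError(f"duplicate metadata sample id(s): {dups}")
    bad = set(meta["regime"]) - set(REGIMES)
    if bad:
        raise ValueError(f"unknown regime value(s) {sorted(bad)}; expected one of {REGIMES}")
    bad = set(meta["season"]) - set(SEASONS)
    if bad:
        raise ValueError(f"unknown season value(s) {sorted(bad)}; expected one of {SEASONS}")
    if (meta["replicate"].astype(int) < 1).any():
        raise ValueError("replicate must be a positive integer")
    meta["replicate"] = meta["replicate"].astype(int)
    if table is not None:
        unmatched = set(table.sample_ids) - set(meta["sample_id"])
        if unmatched:
            raise ValueError(f"samples without metadata: {sorted(unmatched)}")
    return meta


def read_metadata(path, table: OtuTable | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta, table)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV (taxon_id + kingdom..genus columns) into a DataFrame
    indexed by taxon id.  Missing rank columns are created empty."""
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "taxon_id" not in tax.columns:
        raise ValueError("taxonomy file must have a 'taxon_id' column")
    tax = tax.set_index("taxon_id")
    for rank in RANKS:
        if rank not in tax.columns:
            tax[rank] = ""
    return tax[list(RANKS)]


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    out = tax.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def lineage_of(tax: pd.DataFrame, taxon_id: str) -> dict:
    """Total lookup: unknown taxa get an all-unassigned lineage with a warning."""
    if taxon_id in tax.index:
        return {r: tax.at[taxon_id, r] for r in RANKS}
    warnings.warn(f"taxon {taxon_id!r} missing from taxonomy; treating as unassigned")
    return {r: "" for r in RANKS}


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("tree has a negative branch length")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# function / guild rules
# ---------------------------------------------------------------------------

def read_function_rules(path) -> pd.DataFrame:
    rules = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"match_rank", "match_value", "function_label"}
    missing = required - set(rules.columns)
    if missing:
        raise ValueError(f"rules file missing column(s): {sorted(missing)}")
    if "trophic_mode" not in rules.columns:
        rules["trophic_mode"] = ""
    if (rules["match_value"] == "").any():
        raise ValueError("rule with empty match_value")
    valid_ranks = set(RANKS) | {"otu"}
    bad = set(rules["match_rank"]) - valid_ranks
    if bad:
        raise ValueError(f"rule(s) reference unknown rank(s): {sorted(bad)}")
    return rules[["match_rank", "match_value", "function_label", "trophic_mode"]]


def write_function_rules(rules: pd.DataFrame, path) -> None:
    rules.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances; every column sums to 1."""
    sums = table.data.sum(axis=0)
    if (sums == 0).any():
        raise ValueError(f"zero-sum sample(s): {list(sums.index[sums == 0])}")
    return table.data / sums


def aggregate_by_rank(
    table: OtuTable,
    taxonomy: pd.DataFrame,
    rank: str,
    others_threshold: float = 0.005,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Collapse a table to relative abundances at ``rank`` with an "Others" row.

    Groups whose mean relative abundance across all samples falls below
    ``others_threshold`` (default 0.5%) are pooled into "Others".  With
    ``per_sample=True`` the pooling criterion is instead "below threshold in
    every sample".  Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if not (0 <= others_threshold < 1):
        raise ValueError("others_threshold must be in [0, 1)")
    rel = relative_abundance(table)
    labels = []
    for t in table.taxon_ids:
        lab = lineage_of(taxonomy, t)[rank] if t not in taxonomy.index else taxonomy.at[t, rank]
        labels.append(lab if lab else "Unassigned")
    grouped = rel.groupby(pd.Index(labels, name=rank)).sum()
    if per_sample:
        low = (grouped < others_threshold).all(axis=1)
    else:
        low = grouped.mean(axis=1) < others_threshold
    if low.any():
        others = grouped.loc[low].sum(axis=0)
        grouped = grouped.loc[~low]
        grouped.loc["Others"] = others
    return grouped


def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Optional preprocessing hook: subsample each sample to ``depth`` reads
    without replacement.  Samples shallower than ``depth`` raise."""
    sums = table.data.sum(axis=0)
    shallow = sums[sums < depth]
    if len(shallow):
        raise ValueError(f"sample(s) shallower than depth {depth}: {list(shallow.index)}")
    rng = np.random.default_rng(seed)
    out = np.zeros(table.shape, dtype=np.int64)
    counts = table.counts
    for j in range(counts.shape[1]):
        col = counts[:, j]
        reads = np.repeat(np.arange(len(col)), col)
        picked = rng.choice(reads, size=depth, replace=False)
        out[:, j] = np.bincount(picked, minlength=len(col))
    return OtuTable.from_arrays(out, table.taxon_ids, table.sample_ids)
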