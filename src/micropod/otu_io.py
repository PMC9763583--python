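"""OTU-table, taxonomy, metadata and tree I/O plus taxon-level aggregation.

The count table is the universal input of the pipeline.  Files may store
samples as rows or OTUs as rows; orientation is *declared*, never guessed
(default ``otus-as-rows``, the common dialect), because a silently
transposed table is the classic microbiome-pipeline bug.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

#: SILVA 138 renamed several phyla; both spellings appear in the wild.
PHYLUM_SYNONYMS = {
    "Bacteroidota": "Bacteroidetes",
    "Firmicutes_A": "Firmicutes",
    "Bacillota": "Firmicutes",
}


class OtuTableError(ValueError):
    """Raised when a count table violates its structural contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise OtuTableError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Integer count matrix with sample rows and OTU columns.

    Invariants: unique ids, counts >= 0, at least one sample and one OTU,
    and every per-sample total strictly positive.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size == 0:
            raise OtuTableError("table must contain at least 1 sample and 1 OTU")
        if not np.issubdtype(counts.dtype, np.number):
            raise OtuTableError("counts must be numeric")
        if np.any(~np.isfinite(counts.astype(float))):
            raise OtuTableError("counts must be finite")
        if np.any(counts < 0):
            raise OtuTableError("counts must be nonnegative")
        if not np.allclose(counts, np.round(counts.astype(float))):
            raise OtuTableError("counts must be integers")
        counts = np.round(counts.astype(float)).astype(np.int64)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        totals = counts.sum(axis=1)
        empty = np.flatnonzero(totals == 0)
        if empty.size:
            raise OtuTableError(
                f"sample {self.sample_ids[empty[0]]!r} has zero total count"
            )
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def select_otus(self, otu_ids) -> "OtuTable":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in pos]
        if missing:
            raise OtuTableError(f"OTUs absent from table: {missing}")
        idx = [pos[o] for o in otu_ids]
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx])


@dataclass
class RelAbundanceTable:
    """Per-sample proportions on the same axes as an :class:`OtuTable`."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError("values shape does not match ids")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise OtuTableError("relative abundances must lie in [0, 1]")
        row_sums = values.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise OtuTableError("each sample's proportions must sum to 1")
        self.values = values

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


def to_relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Divide each sample's counts by its total."""
    totals = table.sample_totals().astype(float)
    values = table.counts / totals[:, None]
    return RelAbundanceTable(list(table.sample_ids), list(table.otu_ids), values)


# ---------------------------------------------------------------------------
# file I/O


def read_otu_table(path, fmt: str = "tsv", orientation: str = "otus-as-rows") -> OtuTable:
    """Read a count table from ``tsv`` or ``biom-json``.

    ``orientation`` applies to the TSV dialect only and must be declared by
    the caller (``otus-as-rows`` or ``samples-as-rows``); BIOM fixes rows as
    observations by specification.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "otus-as-rows":
            df = df.T
        elif orientation != "samples-as-rows":
            raise OtuTableError(f"unknown orientation {orientation!r}")
        return OtuTable.from_dataframe(df)
    if fmt == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        return _from_biom_json(doc)
    raise OtuTableError(f"unknown format {fmt!r}")


def _from_biom_json(doc: dict) -> OtuTable:
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"])
    return OtuTable(sample_ids, otu_ids, mat.T)


def write_otu_table(table: OtuTable, path, fmt: str = "tsv",
                    orientation: str = "otus-as-rows") -> None:
    if fmt == "tsv":
        df = table.to_dataframe()
        if orientation == "otus-as-rows":
            df = df.T
            df.index.name = "#OTU ID"
        else:
            df.index.name = "#Sample ID"
        df.to_csv(path, sep="\t")
        return
    if fmt == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "micropod",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise OtuTableError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage (domain ... genus)."""

    lineages: dict[str, tuple[str, ...]]
    ranks: tuple[str, ...] = RANKS

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            if len(lin) > len(self.ranks):
                raise OtuTableError(
                    f"lineage for {otu!r} longer than declared ranks"
                )

    def taxon_at(self, otu_id: str, rank: str) -> str:
        """Taxon label at ``rank``, or the reserved unclassified label."""
        if rank not in self.ranks:
            raise OtuTableError(f"unknown rank {rank!r}")
        depth = self.ranks.index(rank)
        lin = self.lineages.get(otu_id, ())
        if depth < len(lin) and lin[depth]:
            return lin[depth]
        return UNCLASSIFIED


def read_taxonomy(path) -> TaxonomyMap:
    """Read a 2-column TSV of ``otu_id<TAB>domain;phylum;...;genus``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu", "lineage"],
                     dtype=str, comment="#")
    lineages = {}
    for otu, lin in zip(df["otu"], df["lineage"]):
        if otu in lineages:
            raise OtuTableError(f"duplicate OTU id in taxonomy: {otu!r}")
        lineages[otu] = tuple(x.strip() for x in str(lin).split(";"))
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        for otu, lin in tax.lineages.items():
            fh.write(f"{otu}\t{';'.join(lin)}\n")


def aggregate_by_rank(table: OtuTable, tax: TaxonomyMap, rank: str) -> OtuTable:
    """Sum counts over OTUs sharing the lineage prefix at ``rank``.

    OTUs without an annotation at that rank are pooled under the reserved
    ``unclassified`` label so per-sample totals are conserved.
    """
    taxa = [tax.taxon_at(o, rank) for o in table.otu_ids]
    order: list[str] = []
    cols: dict[str, list[int]] = {}
    for j, t in enumerate(taxa):
        if t not in cols:
            cols[t] = []
            order.append(t)
        cols[t].append(j)
    agg = np.column_stack([table.counts[:, cols[t]].sum(axis=1) for t in order])
    return OtuTable(list(table.sample_ids), order, agg)


def fb_ratio(table: OtuTable, tax: TaxonomyMap,
             synonyms: dict[str, str] | None = None) -> pd.Series:
    """Per-sample Firmicutes/Bacteroidetes count ratio.

    Samples with zero Bacteroidetes are reported as NaN (undefined), not
    infinity.  Phylum spelling variants are folded via ``synonyms``.
    """
    syn = dict(PHYLUM_SYNONYMS)
    if synonyms:
        syn.update(synonyms)
    phyla = aggregate_by_rank(table, tax, "phylum")
    canonical = [syn.get(p, p) for p in phyla.otu_ids]
    firm = np.zeros(phyla.n_samples)
    bact = np.zeros(phyla.n_samples)
    has_f = has_b = False
    for j, p in enumerate(canonical):
        if p == "Firmicutes":
            firm += phyla.counts[:, j]
            has_f = True
        elif p == "Bacteroidetes":
            bact += phyla.counts[:, j]
            has_b = True
    if not (has_f or has_b):
        raise OtuTableError("neither Firmicutes nor Bacteroidetes annotated")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bact > 0, firm / np.maximum(bact, 1e-300), np.nan)
    return pd.Series(ratio, index=table.sample_ids, name="fb_ratio")


# ---------------------------------------------------------------------------
# metadata and trees

METADATA_COLUMNS = ("group", "age", "sex", "ALB", "Pro24h", "SCr", "cohort")
CLINICAL_COLUMNS = ("ALB", "Pro24h", "SCr")


def read_metadata(path, group_levels=None) -> pd.DataFrame:
    """Read sample metadata CSV indexed by sample id."""
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta, group_levels=group_levels)


def validate_metadata(meta: pd.DataFrame, group_levels=None) -> pd.DataFrame:
    if meta.index.has_duplicates:
        raise OtuTableError("duplicate sample ids in metadata")
    if "group" not in meta.columns:
        raise OtuTableError("metadata must declare a 'group' column")
    if group_levels is not None:
        extra = set(meta["group"].dropna()) - set(group_levels)
        if extra:
            raise OtuTableError(f"unexpected group levels: {sorted(extra)}")
    for col in ("age",) + CLINICAL_COLUMNS:
        if col in meta.columns:
            vals = pd.to_numeric(meta[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise OtuTableError(f"metadata column {col!r} has negative values")
    return meta


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; negative branch lengths are rejected."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise OtuTableError(f"negative branch length at {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
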