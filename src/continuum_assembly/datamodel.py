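"""Shared data model and I/O for community tables, metadata, and trees.

Conventions used throughout the package:

* community tables are stored **samples as rows, taxa as columns** with
  non-negative integer counts;
* sample and taxon identifiers are matched by exact, case-sensitive string
  comparison;
* relative abundances are computed per sample row at the point of use and
  never stored;
* phylogenies are rooted :class:`skbio.TreeNode` objects whose tip set must
  cover the community table's taxa. Missing branch lengths are read as 0
  with a logged warning (a zero-length branch contributes nothing to
  phylogenetic diversity or patristic distance). Mid-point rooting of an
  unrooted input tree is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "region",
    "habitat",
    "lifestyle",
    "latitude",
    "longitude",
)


class CommunityTable:
    """A samples × taxa matrix of non-negative integer counts.

    Parameters
    ----------
    data :
        DataFrame with sample IDs as the index and taxon IDs as columns.
        Counts must be non-negative integers; empty (all-zero) samples are
        rejected unless ``drop_empty=True``, in which case they are dropped
        with a logged warning.
    """

    def __init__(self, data: pd.DataFrame, drop_empty: bool = False):
        if data.index.has_duplicates:
            dups = sorted(data.index[data.index.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dups}")
        if data.columns.has_duplicates:
            dups = sorted(data.columns[data.columns.duplicated()].unique())
            raise ValueError(f"duplicate taxon IDs: {dups}")
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("community table must have >=1 sample and >=1 taxon")
        values = data.to_numpy()
        if not np.issubdtype(np.asarray(values).dtype, np.number):
            raise ValueError("community table contains non-numeric entries")
        bad = np.argwhere((values < 0) | (values != np.floor(values)))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                "counts must be non-negative integers; offending entry at "
                f"sample {data.index[i]!r}, taxon {data.columns[j]!r} = {values[i, j]!r}"
            )
        data = data.astype(np.int64)
        empty = data.sum(axis=1) == 0
        if empty.any():
            if not drop_empty:
                raise ValueError(
                    f"empty samples (zero total counts): {list(data.index[empty])}"
                )
            logger.warning("dropping %d empty sample(s): %s",
                           int(empty.sum()), list(data.index[empty]))
            data = data.loc[~empty]
            if data.shape[0] == 0:
                raise ValueError("all samples are empty")
        self.data = data

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        return self.data.div(self.data.sum(axis=1), axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence matrix."""
        return self.data > 0

    def subset_samples(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(sample_ids)])

    def subset_taxa(self, taxon_ids, drop_empty: bool = True) -> "CommunityTable":
        return CommunityTable(self.data[list(taxon_ids)], drop_empty=drop_empty)

    def __eq__(self, other) -> bool:
        return isinstance(other, CommunityTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CommunityTable({self.n_samples} samples x {self.n_taxa} taxa)"


def read_community_table(path, orientation: str = "samples_as_rows",
                         drop_empty: bool = False) -> CommunityTable:
    """Read a TSV count table (one header row, first column = ID).

    ``orientation='taxa_as_rows'`` transposes the input into the internal
    samples-as-rows convention.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "taxa_as_rows":
        df = df.T
    return CommunityTable(df, drop_empty=drop_empty)


def write_community_table(table: CommunityTable, path,
                          orientation: str = "samples_as_rows") -> None:
    """Write a community table as TSV; round-trips bit-exactly."""
    df = table.data if orientation == "samples_as_rows" else table.data.T
    df.to_csv(path, sep="\t", index_label="id")


def read_newick_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0.

    Raises a hard error on unparseable Newick or duplicate tip labels.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError with position info
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    return _prepare_tree(tree)


def _prepare_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen, dups = set(), set()
        for t in tips:
            (dups if t in seen else seen).add(t)
        raise ValueError(f"duplicate tip labels: {sorted(dups)}")
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    if n_missing:
        logger.warning("%d branch length(s) missing; set to 0", n_missing)
    return tree


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata (CSV or TSV) indexed by ``sample_id``.

    Requires columns region, habitat, lifestyle, latitude, longitude;
    additional numeric columns (salinity, temperature, ...) pass through as
    environmental covariates. Validates coordinate ranges and the
    lifestyle/habitat consistency rule (lifestyle is missing iff the
    habitat is sediment).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(path, sep=sep)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    if meta.index.name == "sample_id":
        meta = meta.reset_index()
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample IDs in metadata: {dups}")
    lat, lon = meta["latitude"].astype(float), meta["longitude"].astype(float)
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude outside [-180, 180]")
    sediment = meta["habitat"].astype(str) == "sediment"
    lifestyle_na = meta["lifestyle"].isna() | (meta["lifestyle"].astype(str) == "NA")
    bad = meta.loc[sediment != lifestyle_na, "sample_id"]
    if len(bad):
        raise ValueError(
            "lifestyle must be NA exactly for sediment samples; offending: "
            f"{list(bad)}"
        )
    return meta.set_index("sample_id")


@dataclass
class ValidationReport:
    """Findings from cross-validating a table, metadata, and tree."""

    samples_missing_metadata: list = field(default_factory=list)
    taxa_missing_from_tree: list = field(default_factory=list)
    empty_samples: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.samples_missing_metadata
                    or self.taxa_missing_from_tree
                    or self.empty_samples)

    def raise_if_findings(self) -> None:
        if not self.empty:
            raise ValueError(f"dataset validation failed: {self}")


def validate_dataset(table: CommunityTable,
                     meta: pd.DataFrame | None = None,
                     tree: TreeNode | None = None,
                     strict: bool = True):
    """Cross-check a community table against metadata and a phylogeny.

    Strict mode raises on any finding. Lenient mode drops offending samples
    (missing metadata, zero totals) from the returned table and logs counts;
    taxa absent from the tree are reported but never dropped (the tree is
    only needed by phylogenetic stages, which may subset).

    Returns ``(report, table)`` where ``table`` is the (possibly reduced)
    community table.
    """
    report = ValidationReport()
    sums = table.data.sum(axis=1)
    report.empty_samples = [str(s) for s in sums.index[sums == 0]]
    if meta is not None:
        known = set(meta.index.astype(str))
        report.samples_missing_metadata = [
            s for s in table.sample_ids if s not in known
        ]
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        report.taxa_missing_from_tree = [
            t for t in table.taxon_ids if t not in tips
        ]
    if strict:
        report.raise_if_findings()
        return report, table
    drop = set(report.empty_samples) | set(report.samples_missing_metadata)
    if drop:
        logger.warning("dropping %d sample(s) during lenient validation", len(drop))
        keep = [s for s in table.sample_ids if s not in drop]
        table = table.subset_samples(keep)
    return report, table
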