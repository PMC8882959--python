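"""OTU count table and sample metadata containers with classic TSV I/O.

The on-disk format is the classic tab-separated OTU table: rows are OTUs,
the first header cell is ``#OTU ID``, columns are samples, and an optional
trailing ``taxonomy`` column carries a semicolon-ranked lineage string.
Metadata is a TSV with columns ``sample_id``, ``population`` and
``endosymbiont_status`` (``infected`` / ``uninfected``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MetadataMismatchError

OTU_HEADER = "#OTU ID"
TAXONOMY_COL = "taxonomy"
STATUS_VALUES = ("infected", "uninfected")


@dataclass
class OTUTable:
    """Nonnegative integer count matrix, OTUs x samples.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as index and sample ids as columns.
    taxonomy
        Optional per-OTU lineage string, indexed like ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise InvalidArgumentError("duplicate OTU ids")
        if self.counts.columns.has_duplicates:
            raise InvalidArgumentError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise InvalidArgumentError("negative counts")
        self.counts = self.counts.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_empty_otus(self) -> "OTUTable":
        keep = self.counts.sum(axis=1) > 0
        tax = self.taxonomy[keep] if self.taxonomy is not None else None
        return OTUTable(self.counts.loc[keep], tax)


@dataclass
class SampleMetadata:
    """Per-sample population label and endosymbiont infection flag."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        required = {"population", "endosymbiont_status"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InvalidArgumentError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.frame["endosymbiont_status"]) - set(STATUS_VALUES)
        if bad:
            raise InvalidArgumentError(f"unknown endosymbiont_status values: {sorted(bad)}")
        if self.frame.index.has_duplicates:
            raise InvalidArgumentError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def population_of(self, sample_ids) -> pd.Series:
        """Map sample ids to population labels; unmapped samples are an error."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise MetadataMismatchError(f"samples without metadata: {missing}")
        return self.frame.loc[list(sample_ids), "population"]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.frame["population"]:
            seen.setdefault(p)
        return list(seen)

    def infected_populations(self) -> list[str]:
        sub = self.frame[self.frame["endosymbiont_status"] == "infected"]
        return sorted(set(sub["population"]))


def read_otu_table(path) -> OTUTable:
    """Read a classic tab-separated OTU table (``#OTU ID`` header)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index.name = OTU_HEADER
    taxonomy = None
    if TAXONOMY_COL in df.columns:
        taxonomy = df[TAXONOMY_COL].astype(str)
        df = df.drop(columns=[TAXONOMY_COL])
    return OTUTable(df, taxonomy)


def write_otu_table(table: OTUTable, path) -> None:
    df = table.counts.copy()
    df.index.name = OTU_HEADER
    if table.taxonomy is not None:
        df[TAXONOMY_COL] = table.taxonomy
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path):
    """Read a labeled square distance matrix TSV into skbio's container."""
    from skbio.stats.distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
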