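"""Read, validate, normalise and reshape the standard metagenomic profile formats.

The pipeline consumes four tab-separated dialects:

* MetaPhlAn2-style merged taxonomic tables — first column holds a
  pipe-delimited, rank-prefixed lineage (``k__...|p__...|...``), one column
  per sample, values conventionally in percent.
* HUMAnN2-style gene-family / pathway tables — first column is the feature
  id, optionally stratified by the contributing taxon as
  ``feature|g__Genus.s__Species`` (or ``feature|unclassified``).
* A sample-metadata table (``sample group achrab age gender birth_mode``).
* A per-sample viral alignment-depth summary (``sample reference mean_depth``).

All tables are held in :class:`AbundanceTable`, a thin wrapper around a
features x samples :class:`pandas.DataFrame` that tracks its normalisation
state so percent data is never renormalised twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_RANK = dict(zip(RANK_PREFIXES, RANKS))


@dataclass(frozen=True)
class TaxonLineage:
    """An ordered, rank-prefixed taxonomic lineage such as ``k__Bacteria|p__Firmicutes``."""

    names: tuple[str, ...]

    @classmethod
    def parse(cls, text: str) -> "TaxonLineage":
        parts = tuple(text.split("|"))
        if not parts or not all(p[:3] in _PREFIX_TO_RANK for p in parts):
            raise FormatError(f"not a rank-prefixed lineage: {text!r}")
        order = [RANK_PREFIXES.index(p[:3]) for p in parts]
        if order != list(range(order[0], order[0] + len(order))) or order[0] != 0:
            raise FormatError(f"lineage ranks out of canonical order: {text!r}")
        return cls(parts)

    @property
    def terminal_rank(self) -> str:
        return _PREFIX_TO_RANK[self.names[-1][:3]]

    @property
    def terminal_name(self) -> str:
        return self.names[-1][3:]

    def __str__(self) -> str:
        return "|".join(self.names)


_STRAT_SPECIES_RE = re.compile(r"\.?s__([^.|]+)")


def parse_stratification(feature_id: str) -> tuple[str, str | None]:
    """Split a HUMAnN2-style feature id into (base id, species tag).

    ``UniRef90_X|g__Prevotella.s__Prevotella_copri`` -> ``("UniRef90_X",
    "Prevotella_copri")``; the ``unclassified`` suffix is preserved as its
    own pseudo-species; an unstratified id returns ``(id, None)``.
    """
    if "|" not in feature_id:
        return feature_id, None
    base, taxon = feature_id.split("|", 1)
    if taxon == "unclassified":
        return base, "unclassified"
    m = _STRAT_SPECIES_RE.search(taxon)
    return base, (m.group(1) if m else taxon)


@dataclass
class AbundanceTable:
    """A features x samples non-negative abundance matrix.

    Parameters
    ----------
    data
        DataFrame indexed by feature id (full lineage or stratified id, which
        guarantees uniqueness) with one column per sample.
    normalization
        ``"raw"``, ``"relative"`` (columns sum to 1) or ``"percent"``
        (columns sum to 100). Tracked explicitly so conversions are applied
        at most once.
    has_lineages
        Whether feature ids are parseable rank-prefixed lineages.
    """

    data: pd.DataFrame
    normalization: str = "raw"
    has_lineages: bool = False

    def __post_init__(self) -> None:
        if self.normalization not in ("raw", "relative", "percent"):
            raise ValueError(f"unknown normalization state {self.normalization!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature rows: {dupes[:3]}")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("negative abundance values")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def lineages(self) -> dict[str, TaxonLineage]:
        if not self.has_lineages:
            raise DataError("table has no lineage-typed features")
        return {f: TaxonLineage.parse(f) for f in self.features}

    def feature_ranks(self) -> pd.Series:
        """Terminal rank per feature (``"unranked"`` for non-lineage ids)."""
        if not self.has_lineages:
            return pd.Series("unranked", index=self.data.index)
        return pd.Series(
            {f: lin.terminal_rank for f, lin in self.lineages().items()}, dtype=object
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"unknown samples: {missing[:3]}")
        return replace(self, data=self.data[list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "AbundanceTable":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise DataError(f"unknown features: {missing[:3]}")
        return replace(self, data=self.data.loc[list(feature_ids)])


@dataclass
class SampleMetadata:
    """Per-sample clinical metadata: group, AChRAb titre, age, gender, birth mode."""

    data: pd.DataFrame  # indexed by sample id

    REQUIRED = ("group",)
    COLUMNS = ("group", "achrab", "age", "gender", "birth_mode")

    def __post_init__(self) -> None:
        if "group" not in self.data.columns or self.data["group"].isna().any():
            raise FormatError("metadata must carry a non-missing 'group' column")
        bad = set(self.data["group"].unique()) - {"case", "control"}
        if bad:
            raise FormatError(f"group values must be case/control, got {sorted(bad)}")
        if "achrab" in self.data.columns:
            ach = pd.to_numeric(self.data["achrab"], errors="coerce")
            if (ach.dropna() < 0).any():
                raise FormatError("AChRAb levels must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def group(self) -> pd.Series:
        return self.data["group"]

    def case_ids(self) -> list[str]:
        return list(self.data.index[self.data["group"] == "case"])

    def control_ids(self) -> list[str]:
        return list(self.data.index[self.data["group"] == "control"])


@dataclass
class DepthTable:
    """Mean alignment depth (fold-coverage) per sample and viral reference."""

    data: pd.DataFrame  # columns: sample, reference, mean_depth

    def __post_init__(self) -> None:
        required = {"sample", "reference", "mean_depth"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"depth table needs columns {sorted(required)}")
        if (self.data["mean_depth"] < 0).any():
            raise FormatError("negative alignment depth")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_taxonomic_table(path: str | Path, units: str = "percent") -> AbundanceTable:
    """Read a MetaPhlAn2-style merged table.

    ``units="percent"`` (the MetaPhlAn2 convention) converts values to
    fractions on load and marks the table ``relative``; ``units="raw"``
    preserves the stored numbers and state.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    values = df.apply(pd.to_numeric)
    for f in values.index:
        TaxonLineage.parse(f)  # validates rank order
    if units == "percent":
        table = AbundanceTable(values / 100.0, normalization="relative", has_lineages=True)
    elif units == "raw":
        table = AbundanceTable(values, normalization="raw", has_lineages=True)
    else:
        raise ValueError(f"units must be 'percent' or 'raw', got {units!r}")
    return table


def write_taxonomic_table(table: AbundanceTable, path: str | Path, units: str = "raw") -> None:
    data = table.data * 100.0 if units == "percent" else table.data
    out = data.copy()
    out.index.name = "ID"
    out.to_csv(path, sep="\t")


def read_gene_family_table(path: str | Path) -> AbundanceTable:
    """Read a HUMAnN2-style gene-family or pathway table (stratification via ``|``)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=1, header=None)
    df.columns = header[1:]
    df.index = df.index.astype(str)
    df.index.name = None
    return AbundanceTable(df.apply(pd.to_numeric), normalization="raw")


def write_gene_family_table(
    table: AbundanceTable, path: str | Path, feature_label: str = "# Gene Family"
) -> None:
    out = table.data.copy()
    out.index.name = feature_label
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    out = metadata.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_depth_table(path: str | Path) -> DepthTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "reference": str})
    return DepthTable(df)


def write_depth_table(depths: DepthTable, path: str | Path) -> None:
    depths.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reshaping operations
# ---------------------------------------------------------------------------

def filter_by_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Keep only features whose terminal lineage rank equals ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ranks = table.feature_ranks()
    keep = ranks.index[ranks == rank]
    return replace(table, data=table.data.loc[keep])


def split_stratified(table: AbundanceTable) -> tuple[AbundanceTable, AbundanceTable]:
    """Partition a functional table into unstratified and taxon-stratified rows."""
    strat_mask = table.data.index.str.contains(r"\|", regex=True)
    unstrat = replace(table, data=table.data.loc[~strat_mask])
    strat = replace(table, data=table.data.loc[strat_mask])
    return unstrat, strat


def species_tags(table: AbundanceTable) -> dict[str, str | None]:
    """Species tag per stratified feature id (None for unstratified features)."""
    return {f: parse_stratification(f)[1] for f in table.features}


def aggregate_to_ranks(
    table: AbundanceTable, ranks: Iterable[str] = RANKS[1:]
) -> AbundanceTable:
    """Build a combined multi-level table by summing terminal-rank features
    up to each requested ancestor rank (the merged-profile convention:
    one row per clade at every taxonomic level)."""
    lineages = table.lineages()
    frames = []
    for rank in ranks:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        depth = RANKS.index(rank) + 1
        groups: dict[str, list[str]] = {}
        for f, lin in lineages.items():
            if len(lin.names) < depth:
                continue
            groups.setdefault("|".join(lin.names[:depth]), []).append(f)
        agg = pd.DataFrame(
            {clade: table.data.loc[members].sum(axis=0) for clade, members in groups.items()}
        ).T
        frames.append(agg)
    combined = pd.concat(frames)
    combined = combined[~combined.index.duplicated()]
    return AbundanceTable(
        combined, normalization=table.normalization, has_lineages=True
    )


def renormalize(table: AbundanceTable, target: str = "relative") -> AbundanceTable:
    """Close each sample column to sum 1 (``relative``) or 100 (``percent``)."""
    if target not in ("relative", "percent"):
        raise ValueError(f"target must be 'relative' or 'percent', got {target!r}")
    sums = table.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise DataError(f"zero-sum sample(s): {zero}")
    scale = 1.0 if target == "relative" else 100.0
    return AbundanceTable(
        table.data.div(sums, axis=1) * scale,
        normalization=target,
        has_lineages=table.has_lineages,
    )


def call_viral_presence(
    depths: DepthTable, min_mean_depth: float = 2.0
) -> set[tuple[str, str]]:
    """Call a virus present where mean alignment depth strictly exceeds the cutoff.

    The default cutoff of 2.0 fold-coverage follows the convention of calling
    presence only "over two" average alignment depth; the boundary itself is
    therefore absent.
    """
    if min_mean_depth < 0:
        raise ValueError("min_mean_depth must be >= 0")
    hits = depths.data[depths.data["mean_depth"] > min_mean_depth]
    return {(row.sample, row.reference) for row in hits.itertuples(index=False)}
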