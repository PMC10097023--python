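"""Reading, writing and reshaping OTU abundance tables.

On-disk format is plain TSV: first column holds identifiers, ``#``-prefixed
lines are comments, and taxonomy is carried as Greengenes-style lineage
strings (``k__Bacteria;p__Firmicutes;...;s__``). Orientation (samples in rows
vs columns) is auto-detected against the trait table when available and can
be forced with a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
UNCLASSIFIED = "unclassified"


class FormatError(ValueError):
    """A malformed input table (duplicate ids, negative counts, bad lineage)."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a 7-rank lineage string into a rank -> name mapping.

    Missing trailing ranks and empty fields (``g__``) map to empty strings.
    """
    parts = [p.strip() for p in lineage.split(";")]
    out = dict.fromkeys(RANKS, "")
    for i, part in enumerate(parts[: len(RANKS)]):
        for pref in RANK_PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        out[RANKS[i]] = part.strip()
    return out


def format_lineage(row: pd.Series) -> str:
    return ";".join(pref + str(row.get(rank, "") or "")
                    for pref, rank in zip(RANK_PREFIXES, RANKS))


@dataclass
class AbundanceTable:
    """Samples x OTUs count matrix plus per-OTU taxonomy.

    ``counts`` is a pandas DataFrame indexed by sample id with OTU-id columns;
    ``taxonomy`` is indexed by OTU id with the seven rank columns (empty
    strings where unassigned). Validation enforces unique identifiers and
    finite non-negative counts.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate OTU identifiers: {dups[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if not np.all(np.isfinite(values)):
            raise FormatError("non-finite counts")
        if (values < 0).any():
            bad = self.counts.columns[(values < 0).any(axis=0)].tolist()
            raise FormatError(f"negative counts in OTU(s) {bad[:5]}")
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                "", index=self.counts.columns, columns=list(RANKS)
            )
        else:
            unknown = self.taxonomy.index.difference(self.counts.columns)
            if len(unknown):
                raise FormatError(
                    f"taxonomy references unknown OTU(s): {unknown[:5].tolist()}"
                )
            self.taxonomy = self.taxonomy.reindex(
                self.counts.columns, fill_value=""
            )[list(RANKS)].fillna("")

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def rank_labels(self, rank: str) -> pd.Series:
        """Per-OTU labels at a rank, empty pooled into 'unclassified'."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lab = self.taxonomy[rank].astype(str)
        return lab.where(lab.str.len() > 0, UNCLASSIFIED)


def read_abundance(
    path,
    taxonomy_path=None,
    *,
    samples_in_rows: bool | None = None,
    trait_sample_ids=None,
) -> AbundanceTable:
    """Read an OTU table (TSV) and optional taxonomy table.

    Orientation is resolved in this order: the explicit ``samples_in_rows``
    flag; identifier overlap with ``trait_sample_ids``; identifier overlap
    with the taxonomy table; otherwise rows are assumed to be samples.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None

    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)

    if samples_in_rows is None:
        samples_in_rows = _detect_orientation(df, trait_sample_ids, taxonomy)
    if not samples_in_rows:
        df = df.T

    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric counts in {path}: {exc}") from exc
    return AbundanceTable(counts=counts, taxonomy=taxonomy)


def _detect_orientation(df, trait_sample_ids, taxonomy) -> bool:
    if trait_sample_ids is not None:
        ids = set(map(str, trait_sample_ids))
        in_rows = len(ids & set(df.index))
        in_cols = len(ids & set(df.columns))
        if in_rows != in_cols:
            return in_rows > in_cols
    if taxonomy is not None:
        otus = set(taxonomy.index)
        otu_rows = len(otus & set(df.index))
        otu_cols = len(otus & set(df.columns))
        if otu_rows != otu_cols:
            return otu_cols > otu_rows
    return True


def read_taxonomy(path) -> pd.DataFrame:
    """Read OTU -> lineage TSV (two columns: id, lineage string)."""
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].tolist()
        raise FormatError(f"duplicate OTU identifiers in taxonomy: {dups[:5]}")
    lineages = raw.iloc[:, 0].astype(str)
    parsed = pd.DataFrame(
        [parse_lineage(s) for s in lineages], index=raw.index
    )
    return parsed


def write_abundance(table: AbundanceTable, path, taxonomy_path=None,
                    header_comments=()) -> None:
    """Write counts (and optionally taxonomy) back to TSV round-trippably."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        out = table.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            fh.write("otu_id\tlineage\n")
            for otu, row in table.taxonomy.iterrows():
                fh.write(f"{otu}\t{format_lineage(row)}\n")


def read_traits(path) -> pd.DataFrame:
    """Read the per-sample trait table (sample, age, sex, group, longevity)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        raise FormatError("duplicate sample identifiers in trait table")
    if "longevity" in df and "age" in df:
        both = df[["age", "longevity"]].dropna()
        expected = (both["age"] >= 90).astype(int)
        if not (both["longevity"].astype(int) == expected).all():
            bad = both.index[both["longevity"].astype(int) != expected]
            raise FormatError(
                f"longevity flag inconsistent with age >= 90 for {bad[:5].tolist()}"
            )
    return df


def write_traits(traits: pd.DataFrame, path, header_comments=()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        out = traits.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")


def aggregate_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts over OTUs sharing a taxonomic rank label.

    Empty labels pool into ``unclassified`` so per-sample totals are conserved
    exactly (integer arithmetic: nothing is dropped).
    """
    labels = table.rank_labels(rank)
    agg = table.counts.T.groupby(labels, sort=False).sum().T
    # sort taxa for stable output, keeping 'unclassified' last
    order = sorted(agg.columns, key=lambda c: (c == UNCLASSIFIED, c))
    agg = agg[order]
    tax = pd.DataFrame("", index=agg.columns, columns=list(RANKS))
    tax[rank] = [c if c != UNCLASSIFIED else "" for c in agg.columns]
    return AbundanceTable(counts=agg, taxonomy=tax)


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample fractions; rows sum to 1. All-zero samples are an error."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {zero.index[:5].tolist()}")
    return table.counts.div(totals, axis=0)


def group_otu_overlap(table: AbundanceTable, traits: pd.DataFrame,
                      group_field: str = "group") -> dict[frozenset, int]:
    """Venn-style exclusive OTU counts across sample groups.

    For every non-empty group combination, count OTUs present (count > 0 in at
    least one sample) in exactly those groups. Cells are disjoint and sum to
    the number of OTUs present anywhere.
    """
    joined = traits.loc[traits.index.intersection(table.counts.index)]
    groups = joined[group_field].astype(str)
    unique_groups = sorted(groups.unique())
    if len(unique_groups) < 2:
        raise ValueError("group_otu_overlap requires at least two groups")
    presence = {}
    for g in unique_groups:
        samples = groups.index[groups == g]
        presence[g] = (table.counts.loc[samples].sum(axis=0) > 0)
    result: dict[frozenset, int] = {}
    for r in range(1, len(unique_groups) + 1):
        for combo in itertools.combinations(unique_groups, r):
            mask = np.ones(table.n_otus, dtype=bool)
            for g in unique_groups:
                if g in combo:
                    mask &= presence[g].to_numpy()
                else:
                    mask &= ~presence[g].to_numpy()
            result[frozenset(combo)] = int(mask.sum())
    return result
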