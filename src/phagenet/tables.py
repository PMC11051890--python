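"""Abundance tables, taxonomy and sample metadata: containers, validation, TSV I/O.

The universal input of every downstream stage is an :class:`AbundanceTable` —
a taxa × samples matrix of non-negative abundances on a fixed-total (TPM-like)
scale, together with a taxonomy map (taxon → domain/phylum/order/family) and
per-sample metadata (group, diet, host order, host family). Files are plain
tab-separated text:

* abundance TSV — first column ``taxon_id``, remaining columns sample ids;
* taxonomy TSV — columns ``taxon_id, domain, phylum, order, family``;
* metadata TSV — columns ``sample_id, group, diet, host_order, host_family``.

Rows and columns are aligned by id, never by position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("bacteria", "phage")

TAXONOMY_COLS = ["domain", "phylum", "order", "family"]
METADATA_COLS = ["group", "diet", "host_order", "host_family"]


@dataclass
class AbundanceTable:
    """Taxa × samples abundance matrix with taxonomy and sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative abundances; index = taxon ids, columns = sample ids.
    taxonomy : pandas.DataFrame
        Indexed by taxon id with columns ``domain, phylum, order, family``;
        must cover exactly the taxa of `values`.
    metadata : pandas.DataFrame
        Indexed by sample id with columns ``group, diet, host_order,
        host_family``; must cover exactly the samples of `values`.
    """

    values: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise ValueError(f"missing value at taxon {v.index[i]!r}, sample {v.columns[j]!r}")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        missing_tax = v.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValueError(f"taxa missing from taxonomy: {missing_tax.tolist()}")
        missing_meta = v.columns.difference(self.metadata.index)
        if len(missing_meta):
            raise ValueError(f"samples missing from metadata: {missing_meta.tolist()}")
        # align (and drop extraneous taxonomy/metadata rows) by id
        self.taxonomy = self.taxonomy.loc[v.index, TAXONOMY_COLS]
        self.metadata = self.metadata.loc[v.columns, METADATA_COLS]
        bad = set(self.taxonomy["domain"]) - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown domains {sorted(bad)}; expected one of {DOMAINS}")
        if self.metadata["group"].isna().any():
            missing = self.metadata.index[self.metadata["group"].isna()].tolist()
            raise ValueError(f"samples without a group: {missing}")

    # -- basic accessors ---------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return self.metadata["group"].drop_duplicates().tolist()

    # -- subsetting --------------------------------------------------------

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "AbundanceTable":
        idx = pd.Index(taxon_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown taxa: {missing.tolist()}")
        return AbundanceTable(self.values.loc[idx], self.taxonomy.loc[idx], self.metadata)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown samples: {missing.tolist()}")
        return AbundanceTable(self.values[idx], self.taxonomy, self.metadata.loc[idx])

    def subset_domain(self, domain: str) -> "AbundanceTable":
        _check_domain(domain)
        keep = self.taxonomy.index[self.taxonomy["domain"] == domain]
        return self.subset_taxa(keep)

    def subset_group(self, group: str) -> "AbundanceTable":
        keep = self.metadata.index[self.metadata["group"] == group]
        if not len(keep):
            raise KeyError(f"unknown group: {group!r}")
        return self.subset_samples(keep)

    def split_by_group(self) -> dict[str, "AbundanceTable"]:
        return {g: self.subset_group(g) for g in self.groups()}


@dataclass
class PresenceAbsenceTable:
    """Binary taxa × samples matrix derived from an abundance table."""

    values: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("presence/absence values must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


def _check_domain(domain: str) -> None:
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to sum 1.

    Raises
    ------
    ValueError
        If any sample column is all zero (no relative composition exists).
    """
    totals = table.values.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample columns: {zero}")
    return AbundanceTable(table.values / totals, table.taxonomy, table.metadata)


def top_k_by_abundance(
    table: AbundanceTable, domain: str, k: int, statistic: str = "mean"
) -> AbundanceTable:
    """Keep the ``k`` most abundant taxa of one domain; other domains untouched.

    Abundance rank statistic is the mean abundance across the table's samples
    (configurable: ``mean``, ``sum`` or ``prevalence``). Ties at rank k are
    broken by lexicographic taxon id, so the output is deterministic. If the
    domain has fewer than ``k`` taxa they are all retained.
    """
    _check_domain(domain)
    if k < 1:
        raise ValueError("k must be >= 1")
    in_domain = table.taxonomy["domain"] == domain
    sub = table.values.loc[in_domain]
    if statistic == "mean":
        score = sub.mean(axis=1)
    elif statistic == "sum":
        score = sub.sum(axis=1)
    elif statistic == "prevalence":
        score = (sub > 0).mean(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    ranked = score.to_frame("score").reset_index(names="taxon_id")
    ranked = ranked.sort_values(["score", "taxon_id"], ascending=[False, True])
    keep = set(ranked["taxon_id"].head(k))
    mask = (~in_domain) | table.values.index.isin(keep)
    return table.subset_taxa(table.values.index[mask])


def to_presence_absence(table: AbundanceTable, threshold: float = 0.0) -> PresenceAbsenceTable:
    """Binarize: 1 where abundance is strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    pa = (table.values > threshold).astype(int)
    return PresenceAbsenceTable(pa, table.taxonomy, table.metadata)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_tables(abundance_path, taxonomy_path, metadata_path) -> AbundanceTable:
    """Read the abundance/taxonomy/metadata TSV trio into a validated table."""
    values = pd.read_csv(abundance_path, sep="\t", index_col="taxon_id")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="taxon_id", dtype=str)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id", dtype=str)
    values.columns = values.columns.astype(str)
    return AbundanceTable(values, taxonomy, metadata)


def write_tables(table: AbundanceTable, out_dir, prefix: str = "community") -> dict[str, str]:
    """Write the TSV trio; returns the written paths keyed by role."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "abundance": os.path.join(out_dir, f"{prefix}_abundance.tsv"),
        "taxonomy": os.path.join(out_dir, f"{prefix}_taxonomy.tsv"),
        "metadata": os.path.join(out_dir, f"{prefix}_metadata.tsv"),
    }
    table.values.to_csv(paths["abundance"], sep="\t", index_label="taxon_id")
    table.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="taxon_id")
    table.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    return paths
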