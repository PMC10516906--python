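"""Shared domain containers used by every pipeline stage.

All labelled structures align by identifier, never by position: a
:class:`CountTable` meeting a phylogeny, or two distance matrices meeting in
a Mantel test, are matched through their sample/taxon ids so that column
order on disk can never silently scramble an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file or in-memory structure violates a contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dupes = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise FormatError(f"duplicate {what} identifier(s): {sorted(set(dupes))}")


@dataclass
class CountTable:
    """Integer sample × taxon abundance matrix.

    Parameters
    ----------
    counts
        DataFrame with samples as the index and taxa as the columns. Values
        must be nonnegative integers (or integral floats, which are cast).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(list(df.index.astype(str)), "sample")
        _check_unique(list(df.columns.astype(str)), "taxon")
        values = df.to_numpy()
        if values.size == 0:
            raise FormatError("count table is empty")
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count table contains non-numeric cells")
        if np.any(~np.isfinite(values.astype(float))):
            raise FormatError("count table contains non-finite cells")
        if np.any(values < 0):
            raise FormatError("count table contains negative counts")
        if not np.allclose(values, np.round(values.astype(float))):
            raise FormatError("count table contains non-integer counts")
        self.counts = df.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised relative abundances; errors on all-zero samples."""
        totals = self.sample_totals()
        empty = totals.index[totals == 0].tolist()
        if empty:
            raise FormatError(f"sample(s) with zero total counts: {empty}")
        return self.counts.div(totals, axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return CountTable(self.counts.loc[list(sample_ids)].copy())


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal.

    Ordinary distance matrices (Bray–Curtis, patristic) must be nonnegative.
    Signed score matrices (e.g. a matrix of βNTI z-scores used as a Mantel
    input) are stored with ``signed=True``, which lifts only the
    nonnegativity requirement.
    """

    labels: list[str]
    values: np.ndarray
    signed: bool = field(default=False)

    def __post_init__(self) -> None:
        self.labels = [str(label) for label in self.labels]
        _check_unique(self.labels, "label")
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise FormatError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if np.any(~np.isfinite(values)):
            raise FormatError("distance matrix contains non-finite entries")
        if not np.allclose(values, values.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric within 1e-12")
        if np.any(np.diag(values) != 0):
            raise FormatError("distance matrix diagonal is not exactly zero")
        if not self.signed and np.any(values < 0):
            raise FormatError("distance matrix contains negative entries")
        # exact symmetry after validation keeps round-trips bit-stable
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        labels = [str(label) for label in labels]
        missing = [label for label in labels if label not in self.labels]
        if missing:
            raise KeyError(f"unknown label(s): {missing}")
        idx = [self.labels.index(label) for label in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.signed)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class GeneTable:
    """Gene read counts with per-gene lengths and per-sample mapped totals.

    ``counts`` is genes × samples; ``gene_lengths`` is in base pairs;
    ``total_mapped`` is the per-sample total mapped-read count used as the
    RPKM denominator (it may exceed the column sums when reads map to genes
    outside the table).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    total_mapped: pd.Series

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index.astype(str)), "gene")
        _check_unique(list(self.counts.columns.astype(str)), "sample")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()].tolist()
            raise FormatError(f"gene(s) without a length: {missing}")
        if (self.gene_lengths <= 0).any():
            raise FormatError("gene lengths must be positive")
        self.total_mapped = self.total_mapped.reindex(self.counts.columns)
        if self.total_mapped.isna().any():
            missing = self.total_mapped.index[self.total_mapped.isna()].tolist()
            raise FormatError(f"sample(s) without a mapped-read total: {missing}")
        colsums = self.counts.sum(axis=0)
        if (self.total_mapped < colsums).any():
            bad = self.total_mapped.index[self.total_mapped < colsums].tolist()
            raise FormatError(
                f"total mapped reads below column sum for sample(s): {bad}"
            )


def validate_metadata(metadata: pd.DataFrame, samples: Sequence[str],
                      group_column: str = "group") -> pd.Series:
    """Return the group label per sample, erroring on missing labels."""
    if group_column not in metadata.columns:
        raise FormatError(f"metadata lacks a '{group_column}' column")
    groups = metadata[group_column]
    groups.index = groups.index.astype(str)
    missing = [s for s in samples if s not in groups.index or pd.isna(groups[s])]
    if missing:
        raise FormatError(f"sample(s) without a group label: {missing}")
    return groups.loc[list(samples)].astype(str)
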