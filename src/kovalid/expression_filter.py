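"""CPM computation and minimum-expression filtering of a count matrix.

Counts per million are computed against raw library sizes (column sums); a
gene passes the expression floor when its CPM reaches a threshold in a
minimum fraction of samples.  The default floor — CPM >= 1 in at least 25%
of samples — is the conventional pre-filter applied before differential
expression.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountsMatrix",
    "read_counts",
    "compute_cpm",
    "filter_expressed",
    "write_gene_list",
]


class LibrarySizeError(ValueError):
    """A sample has zero total counts; CPM is undefined for it."""


@dataclass
class CountsMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_counts(path: str | os.PathLike, sep: str | None = None) -> CountsMatrix:
    """Read a gene x sample count table (genes in rows, header row).

    The delimiter is sniffed from the extension (.csv -> comma, else tab)
    unless given explicitly.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountsMatrix(df)


def compute_cpm(m: CountsMatrix) -> pd.DataFrame:
    """cpm[g, s] = counts[g, s] / library_size[s] * 1e6."""
    sizes = m.library_sizes
    zero = sizes[sizes == 0]
    if len(zero):
        raise LibrarySizeError(
            f"zero library size for sample(s): {', '.join(map(str, zero.index))}"
        )
    return m.counts.div(sizes, axis=1) * 1e6


def filter_expressed(
    m: CountsMatrix,
    min_cpm: float = 1.0,
    min_sample_frac: float = 0.25,
    strict: bool = False,
) -> list[str]:
    """Gene ids passing the expression floor.

    A gene is retained when its CPM is >= *min_cpm* in at least
    ``ceil(min_sample_frac * n_samples)`` samples.  With ``strict=True``
    the sample requirement becomes strictly more than
    ``min_sample_frac * n_samples`` (floor + 1), for workflows that read
    "in more than 25% of samples" literally; the two differ only when the
    fraction lands on an integer.
    """
    if not (0 < min_sample_frac <= 1):
        raise ValueError("min_sample_frac must be in (0, 1]")
    cpm = compute_cpm(m)
    n = len(m.sample_ids)
    raw = min_sample_frac * n
    needed = math.floor(raw) + 1 if strict else math.ceil(raw)
    passing = (cpm >= min_cpm).sum(axis=1) >= needed
    return list(m.counts.index[passing])


def write_gene_list(genes: list[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
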