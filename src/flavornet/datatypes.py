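"""Shared in-memory containers for count data and sample metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene-level fragment counts with gene lengths and the sample design.

    Parameters
    ----------
    counts
        Integer DataFrame, genes (rows) x libraries (columns).
    lengths
        Transcript length in bp per gene, indexed like ``counts``.
    samples
        Sample sheet indexed by library id with at least a ``stage``
        column (and typically ``replicate``), one row per count column.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][0]
            raise ValueError(f"missing length for gene {missing!r}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        unknown = self.counts.columns.difference(self.samples.index)
        if len(unknown):
            raise ValueError(f"libraries missing from sample sheet: {list(unknown)}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            r, c = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"library {self.counts.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        """Total mapped fragments per library (column sums)."""
        return self.counts.sum(axis=0)

    def stage_libraries(self, stage: str) -> list[str]:
        libs = [c for c in self.counts.columns if self.samples.loc[c, "stage"] == stage]
        if not libs:
            raise ValueError(f"stage {stage!r} not present in sample sheet")
        return libs
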