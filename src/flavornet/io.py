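"""Tabular I/O shared by all pipeline stages.

All tables are tab-separated UTF-8 with '.' decimals and no quoting.
Schemas: counts.tsv (gene_id + one integer column per library),
lengths.tsv (gene_id, length_bp), samples.tsv (library_id, stage,
replicate), traits.tsv (library_id + one column per trait).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix


def read_count_matrix(counts_path, lengths_path, samples_path) -> CountMatrix:
    """Read and validate a count matrix with lengths and sample sheet.

    Rejects duplicate gene ids, non-integer or negative cells, libraries
    absent from the sample sheet, and genes without a length.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    counts.columns.name = "library_id"
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id {dup!r} in {counts_path}")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        frac, _ = np.modf(vals.astype(float))
        if np.abs(frac).max() > 0:
            r, c = np.argwhere(np.abs(frac) > 0)[0]
            raise ValueError(
                f"non-integer count at gene {counts.index[r]!r}, "
                f"library {counts.columns[c]!r} in {counts_path}"
            )
        counts = counts.astype(np.int64)
    if (counts.to_numpy() < 0).any():
        r, c = np.argwhere(counts.to_numpy() < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[r]!r}, "
            f"library {counts.columns[c]!r} in {counts_path}"
        )
    lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["length_bp"]
    samples = pd.read_csv(samples_path, sep="\t", index_col="library_id")
    return CountMatrix(counts=counts, lengths=lengths, samples=samples)


def read_traits(path) -> pd.DataFrame:
    traits = pd.read_csv(path, sep="\t", index_col="library_id")
    if not np.isfinite(traits.to_numpy(dtype=float)).all():
        raise ValueError(f"non-finite trait value in {path}")
    return traits


def read_qpcr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path, index_label: str = "gene_id") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path
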