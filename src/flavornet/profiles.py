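"""FPKM computation, expression binning, and ripening-profile groups.

Differentially expressed genes are classified by the signs of their
significant changes over the two stage intervals (S1->S2, S2->S3) into
four groups: I monotone up, II up-then-down, III monotone down, IV
down-then-up.  Genes with no significant change in either interval, or
with a change exceeding 32-fold, are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CountMatrix

#: Bin edges for the 9-colour absolute-expression scale (top bin closed).
FIG3_EDGES = (0.0, 0.1, 0.7, 2.0, 4.0, 8.0, 20.0, 100.0, 1000.0, 12500.0)

#: Bin edges for the 12-colour scale; the last bin is unbounded above.
FIG56_EDGES = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0, 1024.0)

DEFAULT_FOLD_CAP_LOG2 = 5.0  # 2**5 = 32-fold

GROUPS = ("I", "II", "III", "IV", "excluded")


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    fpkm[g, s] = 1e9 * count[g, s] / (library_total[s] * length_bp[g]).
    Invariant to scaling counts and library totals together.
    """
    totals = counts.library_sizes()
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"library {bad!r} has zero total fragments")
    lengths = counts.lengths.to_numpy(dtype=float)
    fpkm = 1e9 * counts.counts.to_numpy(dtype=float) / (
        totals.to_numpy(dtype=float)[None, :] * lengths[:, None]
    )
    return pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.library_ids)


def bin_expression(fpkm, scheme: str = "fig3"):
    """1-based colour-bin index of an FPKM value.

    Intervals are half-open [lo, hi); the top bin is closed above at the
    scheme maximum for ``"fig3"`` (9 bins) and unbounded for ``"fig56"``
    (12 bins).  Accepts scalars or arrays.
    """
    arr = np.asarray(fpkm, dtype=float)
    if (arr < 0).any() if arr.ndim else arr < 0:
        raise ValueError("FPKM must be non-negative")
    if scheme == "fig3":
        edges = np.array(FIG3_EDGES)
        if (arr > edges[-1]).any() if arr.ndim else arr > edges[-1]:
            raise ValueError(f"value exceeds top bin edge {edges[-1]}")
        idx = np.minimum(np.searchsorted(edges, arr, side="right"), len(edges) - 1)
    elif scheme == "fig56":
        edges = np.array(FIG56_EDGES)
        idx = np.minimum(np.searchsorted(edges, arr, side="right"), len(edges))
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    return int(idx) if arr.ndim == 0 else idx.astype(int)


def _signs(de: pd.DataFrame) -> pd.Series:
    s = np.sign(de["log2ratio"]).astype(int)
    s[~de["is_deg"]] = 0
    return s


_GROUP_MAP = {
    (1, 1): "I",
    (1, 0): "I",
    (0, 1): "I",
    (1, -1): "II",
    (-1, -1): "III",
    (-1, 0): "III",
    (0, -1): "III",
    (-1, 1): "IV",
    (0, 0): "excluded",
}


def classify_profiles(
    de_12: pd.DataFrame,
    de_23: pd.DataFrame,
    fold_cap_log2: float | None = DEFAULT_FOLD_CAP_LOG2,
    single_significant: str = "monotone",
) -> pd.DataFrame:
    """Assign each gene to one of the four ripening-profile groups.

    Parameters
    ----------
    de_12, de_23
        Pairwise DE tables (from :func:`~flavornet.detest.run_pairwise_de`)
        for the first and second stage interval, covering the same genes.
    fold_cap_log2
        Genes whose larger |log2 ratio| exceeds this cap (default 5,
        i.e. a 32-fold change) are excluded; ``None`` disables the cap.
    single_significant
        ``"monotone"`` folds patterns significant in only one interval
        into groups I/III; ``"excluded"`` drops them instead.

    Returns a DataFrame with columns group, sign_12, sign_23,
    log2ratio_12, log2ratio_23.
    """
    if not de_12.index.equals(de_23.index):
        only = de_12.index.symmetric_difference(de_23.index)
        raise ValueError(f"gene sets differ between comparisons (e.g. {list(only[:3])})")
    if single_significant not in ("monotone", "excluded"):
        raise ValueError("single_significant must be 'monotone' or 'excluded'")

    s12 = _signs(de_12)
    s23 = _signs(de_23)
    group = pd.Series(
        [_GROUP_MAP[(a, b)] for a, b in zip(s12, s23)], index=de_12.index, dtype=object
    )
    if single_significant == "excluded":
        one_sided = (s12 == 0) ^ (s23 == 0)
        group[one_sided] = "excluded"
    if fold_cap_log2 is not None:
        capped = np.maximum(de_12["log2ratio"].abs(), de_23["log2ratio"].abs()) > fold_cap_log2
        group[capped] = "excluded"
    return pd.DataFrame(
        {
            "group": group,
            "sign_12": s12,
            "sign_23": s23,
            "log2ratio_12": de_12["log2ratio"],
            "log2ratio_23": de_23["log2ratio"],
        }
    )
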