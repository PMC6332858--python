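"""Exact two-library differential-expression test and DEG screening.

The test asks whether a gene with ``x`` fragments out of ``N1`` in one
library and ``y`` out of ``N2`` in another is expressed equally in both.
Fragment counts for a gene occupying a small fraction of a library are
modelled as Poisson; marginalising the unknown Poisson mean gives the
conditional probability of observing ``i`` fragments in library 2 given
``x`` in library 1::

    p(i | x) = (N2/N1)^i * (x+i)! / ( x! * i! * (1 + N2/N1)^(x+i+1) )

which, summed over i, is a proper probability mass (a negative-binomial
law with size x+1 and success probability 1/(1+N2/N1)).  The two-sided
p-value doubles the smaller tail of the cumulative sum up to ``y``.

Genes are screened as differentially expressed when the
Benjamini-Hochberg FDR is below 0.001 (strict) and the absolute log2
FPKM ratio is at least 1 (inclusive).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix

# exp() underflows to 0 below ~ -745; terms smaller than this contribute
# nothing representable to a linear-space sum
_LOG_FLOOR = math.log(1e-320)

DEFAULT_FDR = 0.001
DEFAULT_MIN_ABS_LOG2 = 1.0
DEFAULT_EPSILON = 0.01


def ac_term(i: int, x: int, ratio: float) -> float:
    """Single term p(i|x) of the equal-expression probability sum.

    ``ratio`` is N2/N1.  Computed in log space via log-gamma for
    numerical range; exact to double precision for desk-scale counts.
    """
    if i < 0 or x < 0:
        raise ValueError("i and x must be non-negative")
    if ratio <= 0:
        raise ValueError("ratio N2/N1 must be positive")
    log_term = (
        i * math.log(ratio)
        + gammaln(x + i + 1)
        - gammaln(x + 1)
        - gammaln(i + 1)
        - (x + i + 1) * math.log1p(ratio)
    )
    return math.exp(log_term)


def _log_terms(i: np.ndarray, x: int, ratio: float) -> np.ndarray:
    return (
        i * math.log(ratio)
        + gammaln(x + i + 1.0)
        - gammaln(x + 1.0)
        - gammaln(i + 1.0)
        - (x + i + 1.0) * math.log1p(ratio)
    )


def _lower_sum(x: int, y: int, ratio: float) -> float:
    """S = sum_{i=0}^{y} p(i|x), compensated linear-space summation."""
    i = np.arange(y + 1, dtype=np.float64)
    lt = _log_terms(i, x, ratio)
    keep = lt >= _LOG_FLOOR
    return math.fsum(np.exp(lt[keep]).tolist()) if keep.any() else 0.0


def _upper_tail(x: int, y: int, ratio: float) -> float:
    """T = sum_{i=y+1}^{inf} p(i|x), summed directly until convergence.

    Used instead of 1 - S when S > 0.5: subtracting near-unity sums
    destroys the relative accuracy of very small p-values.
    """
    total = 0.0
    i0 = y + 1
    chunk = max(64, x + 1)
    while True:
        i = np.arange(i0, i0 + chunk, dtype=np.float64)
        lt = _log_terms(i, x, ratio)
        vals = np.where(lt >= _LOG_FLOOR, np.exp(np.maximum(lt, _LOG_FLOOR)), 0.0)
        total = math.fsum([total, *vals.tolist()])
        # terms decay geometrically once i exceeds the mode ~ ratio*(x+1);
        # stop when the last term cannot move the sum at double precision
        if vals[-1] <= total * 1e-18 + 5e-324 and i0 + chunk > (ratio + 1.0) * (x + 2):
            return total
        i0 += chunk


def ac_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact p-value for equal expression of one gene.

    Parameters
    ----------
    x, y
        Fragments uniquely mapped to the gene in library 1 and 2.
    n1, n2
        Total fragments in library 1 and 2.

    Returns
    -------
    float in (0, 1].  Symmetric under swapping (x, n1) with (y, n2).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    ratio = n2 / n1
    s = _lower_sum(x, y, ratio)
    if s <= 0.5:
        p = 2.0 * s
    else:
        p = 2.0 * _upper_tail(x, y, ratio)
    return min(max(p, 5e-324), 1.0)


def ac_pvalue_many(x: Iterable[int], y: Iterable[int], n1: float, n2: float) -> np.ndarray:
    """Vectorised :func:`ac_pvalue` over per-gene count pairs."""
    xa = np.asarray(list(x), dtype=np.int64)
    ya = np.asarray(list(y), dtype=np.int64)
    return np.array([ac_pvalue(int(xi), int(yi), n1, n2) for xi, yi in zip(xa, ya)])


def bh_adjust(pvalues: Iterable[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment of raw p-values.

    ``method`` is ``"bh"`` (Benjamini-Hochberg step-up, default) or
    ``"bonferroni"``.  Returns adjusted values clipped to <= 1; an empty
    input yields an empty array.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


def log2_ratio(fpkm_a: float, fpkm_b: float, epsilon: float = DEFAULT_EPSILON):
    """log2 fold change of the later stage (b) over the earlier (a).

    A small additive ``epsilon`` (default 0.01 FPKM) keeps zero-FPKM
    genes finite.  Accepts scalars or arrays.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    a = np.asarray(fpkm_a, dtype=float)
    b = np.asarray(fpkm_b, dtype=float)
    if (a < 0).any() if a.ndim else a < 0:
        raise ValueError("FPKM must be non-negative")
    if (b < 0).any() if b.ndim else b < 0:
        raise ValueError("FPKM must be non-negative")
    out = np.log2((b + epsilon) / (a + epsilon))
    return float(out) if out.ndim == 0 else out


def run_pairwise_de(
    counts: CountMatrix,
    stage_a: str,
    stage_b: str,
    fdr_threshold: float = DEFAULT_FDR,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    epsilon: float = DEFAULT_EPSILON,
    correction: str = "bh",
    mode: str = "pooled",
) -> pd.DataFrame:
    """Screen differentially expressed genes between two stages.

    Replicate libraries are pooled (summed) within each stage so the
    two-library test applies directly; ``mode="replicate-median"``
    instead takes the median p-value over all replicate pairs.

    Returns a DataFrame indexed by gene_id with columns
    x, y, N1, N2, pvalue, fdr, log2ratio, is_deg.  ``log2ratio`` is
    oriented later stage (b) over earlier stage (a).
    """
    if counts.counts.shape[0] == 0:
        raise ValueError("empty gene set")
    libs_a = counts.stage_libraries(stage_a)
    libs_b = counts.stage_libraries(stage_b)
    xa = counts.counts[libs_a].sum(axis=1)
    yb = counts.counts[libs_b].sum(axis=1)
    n1 = int(xa.sum())
    n2 = int(yb.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("a stage has zero total fragments")

    if mode == "pooled":
        pvals = ac_pvalue_many(xa.to_numpy(), yb.to_numpy(), n1, n2)
    elif mode == "replicate-median":
        per_lib = counts.counts.sum(axis=0)
        pmat = [
            ac_pvalue_many(
                counts.counts[la].to_numpy(),
                counts.counts[lb].to_numpy(),
                int(per_lib[la]),
                int(per_lib[lb]),
            )
            for la in libs_a
            for lb in libs_b
        ]
        pvals = np.median(np.vstack(pmat), axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # FPKM from the pooled pseudo-libraries, matching the x/N1 semantics
    lengths = counts.lengths.to_numpy(dtype=float)
    fpkm_a = 1e9 * xa.to_numpy(dtype=float) / (n1 * lengths)
    fpkm_b = 1e9 * yb.to_numpy(dtype=float) / (n2 * lengths)
    l2r = log2_ratio(fpkm_a, fpkm_b, epsilon)

    fdr = bh_adjust(pvals, method=correction)
    is_deg = (fdr < fdr_threshold) & (np.abs(l2r) >= min_abs_log2)
    return pd.DataFrame(
        {
            "x": xa.to_numpy(),
            "y": yb.to_numpy(),
            "N1": n1,
            "N2": n2,
            "pvalue": pvals,
            "fdr": fdr,
            "log2ratio": l2r,
            "is_deg": is_deg,
        },
        index=counts.gene_ids,
    )
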