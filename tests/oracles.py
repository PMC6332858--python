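"""Independent reference implementations used only to check results.

These deliberately avoid the code paths they verify: exact rational
arithmetic for the two-library test, a triple loop for topological
overlap, and the incomplete-beta form of the Pearson t-test p-value.
"""

from fractions import Fraction
from math import factorial

import numpy as np
from scipy.special import betainc


def exact_ac_pvalue(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided equal-expression p-value in exact rational arithmetic."""
    ratio = Fraction(n2, n1)
    s = Fraction(0)
    for i in range(y + 1):
        s += (
            ratio**i
            * Fraction(factorial(x + i), factorial(x) * factorial(i))
            / (1 + ratio) ** (x + i + 1)
        )
    return 2 * min(s, 1 - s)


def brute_force_tom(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of a symmetric adjacency."""
    n = adj.shape[0]
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def constant_adjacency_tom(n: int, a: float) -> float:
    """Closed-form off-diagonal TOM of a complete graph with weight a."""
    return ((n - 2) * a * a + a) / ((n - 2) * a + 1.0)


def pearson_p_incomplete_beta(r: float, n: int) -> float:
    """Two-sided Pearson test p-value via the regularised incomplete beta."""
    return float(betainc((n - 2) / 2.0, 0.5, 1.0 - r * r))
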