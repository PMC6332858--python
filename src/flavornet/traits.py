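"""Module-trait and gene-trait association, candidates, hubs, export.

Module eigengenes are correlated (Pearson) against measured trait
profiles -- here metabolite concentrations such as sucrose, malic acid,
beta-ionone or gamma-decalactone -- with a two-sided Student-t p-value
on n-2 degrees of freedom.  Within trait-associated modules, candidate
genes are those whose own expression correlates with a trait above a
threshold (default |r| > 0.91, strict), and intramodular hubs are high
module-membership genes (kME) ranked by intramodular connectivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .detest import bh_adjust

DEFAULT_R_THRESHOLD = 0.91
DEFAULT_KME_THRESHOLD = 0.9
DEFAULT_TOP_K_PER_MODULE = 5
DEFAULT_MODULE_P_THRESHOLD = 0.001


def correlation_test(u, v) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value.

    t = r * sqrt(n-2) / sqrt(1-r^2) against Student t with n-2 degrees
    of freedom; r = +/-1 returns p = 0.  Requires n >= 4 and nonzero
    variance in both vectors.
    """
    ua = np.asarray(u, dtype=float)
    va = np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ValueError("length mismatch")
    n = ua.size
    if n < 4:
        raise ValueError("need at least 4 paired samples")
    if ua.std() == 0 or va.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.clip(np.corrcoef(ua, va)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def module_trait_matrix(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, correct: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p for every (module eigengene, trait) pair.

    Libraries must match and be identically ordered.  By default no
    multiplicity correction is applied (each cell is reported as is);
    ``correct="bh"`` adjusts the grid with Benjamini-Hochberg.
    """
    if not eigengenes.index.equals(traits.index):
        raise ValueError("eigengene and trait tables must share ordered library ids")
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        for t in traits.columns:
            r.loc[m, t], p.loc[m, t] = correlation_test(eigengenes[m], traits[t])
    if correct == "bh":
        flat = bh_adjust(np.clip(p.to_numpy().ravel(), 1e-300, 1.0))
        p = pd.DataFrame(flat.reshape(p.shape), index=p.index, columns=p.columns)
    return r, p


def significant_modules(
    r: pd.DataFrame, p: pd.DataFrame, p_threshold: float = DEFAULT_MODULE_P_THRESHOLD
) -> list:
    """Modules whose best trait association is significant (p < threshold)."""
    return [m for m in p.index if (p.loc[m] < p_threshold).any()]


def select_candidate_genes(
    fpkm: pd.DataFrame,
    traits: pd.DataFrame,
    partition: pd.Series,
    modules: list,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Trait-correlated genes within the significant modules.

    Gene expression (log2(FPKM+1) by default) is correlated against
    every trait; genes whose best |r| is strictly above ``r_threshold``
    are kept, with their best trait recorded.
    """
    if not modules:
        raise ValueError("empty module list")
    expr = np.log2(fpkm + 1.0) if log_transform else fpkm
    genes = partition.index[partition.isin(modules)]
    rows = []
    tvals = {t: traits[t].to_numpy(dtype=float) for t in traits.columns}
    for g in genes:
        x = expr.loc[g, traits.index].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        best_r, best_t = 0.0, None
        for t, tv in tvals.items():
            r = float(np.corrcoef(x, tv)[0, 1])
            if abs(r) > abs(best_r):
                best_r, best_t = r, t
        if abs(best_r) > r_threshold:
            rows.append((g, int(partition[g]), best_t, best_r))
    return pd.DataFrame(
        rows, columns=["gene_id", "module", "best_trait", "gene_trait_r"]
    ).set_index("gene_id")


def identify_hubs(
    expr: pd.DataFrame,
    eigengenes: pd.DataFrame,
    partition: pd.Series,
    adjacency: pd.DataFrame,
    kme_threshold: float = DEFAULT_KME_THRESHOLD,
    top_k_per_module: int = DEFAULT_TOP_K_PER_MODULE,
) -> pd.DataFrame:
    """Intramodular hub genes.

    kME_g = cor(expression of g, eigengene of g's module);
    intramodular connectivity is the soft-adjacency row sum restricted
    to the gene's own module.  Hubs are genes with kME >= threshold,
    ranked by intramodular connectivity, at most ``top_k_per_module``
    per module.  Output is sorted by (module, -connectivity) and is
    invariant to gene input order.
    """
    rows = []
    for m in eigengenes.columns:
        genes = partition.index[partition == m]
        e = eigengenes[m].to_numpy(dtype=float)
        sub = adjacency.loc[genes, genes].to_numpy(dtype=float)
        k_in = sub.sum(axis=1) - 1.0  # drop the unit diagonal
        for g, ki in zip(genes, k_in):
            x = expr.loc[g].to_numpy(dtype=float)
            kme = float(np.corrcoef(x, e)[0, 1])
            rows.append((g, int(m), kme, float(ki)))
    df = pd.DataFrame(rows, columns=["gene_id", "module", "kME", "intramodular_k"])
    df = df.sort_values(
        ["module", "intramodular_k", "gene_id"], ascending=[True, False, True]
    ).set_index("gene_id")
    df["is_hub"] = False
    for m in df["module"].unique():
        eligible = df.index[(df["module"] == m) & (df["kME"] >= kme_threshold)]
        df.loc[eligible[:top_k_per_module], "is_hub"] = True
    return df


def export_network_edges(
    weights: pd.DataFrame,
    genes,
    weight_threshold: float,
    fmt: str = "tsv",
    path=None,
):
    """Thresholded undirected edge list for network visualisation.

    Edges (a, b, w) with w >= ``weight_threshold``, a < b
    lexicographically, no self-edges.  ``fmt="tsv"`` returns a
    source/target/weight DataFrame; ``fmt="sif"`` returns Cytoscape SIF
    lines ``source coexp target``.  If ``path`` is given the result is
    also written there.
    """
    if not 0.0 <= weight_threshold <= 1.0:
        raise ValueError("weight threshold must lie in [0, 1]")
    genes = [g for g in genes]
    missing = set(genes) - set(weights.index)
    if missing:
        raise ValueError(f"genes absent from the weight matrix: {sorted(missing)[:3]}")
    sub = weights.loc[genes, genes]
    rows = []
    ordered = sorted(genes)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            w = float(sub.loc[a, b])
            if w >= weight_threshold:
                rows.append((a, b, w))
    if fmt == "tsv":
        out = pd.DataFrame(rows, columns=["source", "target", "weight"])
        if path is not None:
            out.to_csv(path, sep="\t", index=False)
        return out
    if fmt == "sif":
        lines = [f"{a}\tcoexp\t{b}" for a, b, _ in rows]
        if path is not None:
            with open(path, "w") as fh:
                fh.write("\n".join(lines) + ("\n" if lines else ""))
        return lines
    raise ValueError(f"unknown format {fmt!r}")
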