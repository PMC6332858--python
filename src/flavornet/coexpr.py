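"""Unsigned weighted co-expression network: adjacency, topological
overlap, module detection, eigengenes, and eigengene-based merging.

The network follows the weighted co-expression construction standard in
transcriptomics: pairwise Pearson correlation of expression profiles,
raised element-wise to a soft-thresholding power beta (default 16) after
taking absolute values ("unsigned", so anti-correlated genes are
connected), then converted to a topological overlap similarity that
rewards shared neighbourhoods.  Modules are branches of an
average-linkage dendrogram on 1 - TOM, cut at a fixed quantile of the
maximum merge height and pruned to a minimum size (default 30).  Each
module is summarised by its eigengene -- the leading singular sample
vector of the standardised module expression -- and modules whose
eigengenes are closer than a merge height (default 0.25, i.e.
correlation > 0.75) are fused.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_BETA = 16.0
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_CUT_QUANTILE = 0.99
DEFAULT_MERGE_CUT_HEIGHT = 0.25


def filter_expressed(fpkm: pd.DataFrame, min_mean: float = 1.0) -> pd.Index:
    """Genes whose mean FPKM across libraries is strictly above ``min_mean``.

    Zero-variance genes are additionally dropped: their correlation with
    anything is undefined.  Raises if no gene survives.
    """
    mean_ok = fpkm.mean(axis=1) > min_mean
    var_ok = fpkm.std(axis=1) > 0
    keep = fpkm.index[mean_ok & var_ok]
    if len(keep) == 0:
        raise ValueError(
            f"no gene passes the expression filter (mean FPKM > {min_mean}, non-constant)"
        )
    return keep


def soft_adjacency(expr: pd.DataFrame, beta: float = DEFAULT_BETA, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency.

    ``expr`` is genes x samples (any monotone transform of expression;
    the pipeline uses log2(FPKM+1)).  Unsigned: a_ij = |cor(i,j)|**beta.
    Signed: a_ij = ((1 + cor)/2)**beta.  Diagonal is fixed at 1.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples for a meaningful network")
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance gene in expression matrix; filter first")
    cor = np.corrcoef(x)
    cor = np.clip(cor, -1.0, 1.0)
    if signed:
        adj = ((1.0 + cor) / 2.0) ** beta
    else:
        adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    adj = (adj + adj.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu * a_uj over u != i, j and k_i the connectivity
    (off-diagonal row sum).  TOM_ii = 1.
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    l = a0 @ a0  # includes u=i and u=j only via zeroed diagonal: already excluded
    num = l + a0
    den = np.minimum.outer(k, k) + 1.0 - a0
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _renumber_by_size(labels: np.ndarray, index: pd.Index) -> pd.Series:
    """Relabel modules 1..M by decreasing size (ties: first-seen order)."""
    out = np.zeros(len(labels), dtype=int)
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for pos, lab in enumerate(labels):
        if lab == 0:
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        first.setdefault(lab, pos)
    order = sorted(sizes, key=lambda m: (-sizes[m], first[m]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    for pos, lab in enumerate(labels):
        if lab != 0:
            out[pos] = remap[lab]
    return pd.Series(out, index=index, name="module")


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_quantile: float = DEFAULT_CUT_QUANTILE,
) -> pd.Series:
    """Cut the 1-TOM average-linkage dendrogram into modules.

    A static cut at ``cut_quantile`` times the maximum merge height
    separates tight branches (modules) from the loose background;
    clusters smaller than ``min_module_size`` are left unassigned
    (label 0).  Modules are numbered 1..M by decreasing size.
    """
    n = tom.shape[0]
    if n < min_module_size:
        warnings.warn(
            f"{n} genes < min_module_size={min_module_size}; all left unassigned",
            stacklevel=2,
        )
        return pd.Series(np.zeros(n, dtype=int), index=tom.index, name="module")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    cut = cut_quantile * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = set(sizes.index[sizes >= min_module_size])
    labels = np.array([lab if lab in keep else 0 for lab in raw])
    return _renumber_by_size(labels, tom.index)


def prune_membership(
    expr: pd.DataFrame,
    partition: pd.Series,
    min_kme: float = 0.85,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> pd.Series:
    """Drop weak module members by module membership (kME).

    A static dendrogram cut attaches chance-correlated background genes
    to module branches; genes whose |cor(expression, module eigengene)|
    falls below ``min_kme`` are returned to the unassigned pool
    (unsigned membership, matching the unsigned adjacency).  Modules
    falling below ``min_module_size`` afterwards are dissolved.
    """
    labels = partition.copy()
    if not (labels > 0).any():
        return labels
    eig, _ = module_eigengenes(expr, labels)
    x = expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    for m in eig.columns:
        e = eig[m].to_numpy()
        ez = (e - e.mean()) / e.std()
        kme = xz @ ez / len(e)
        members = labels == m
        weak = members.to_numpy() & (np.abs(kme) < min_kme)
        labels[weak] = 0
    sizes = labels[labels > 0].value_counts()
    for m in sizes.index[sizes < min_module_size]:
        labels[labels == m] = 0
    return _renumber_by_size(labels.to_numpy(), labels.index)


def module_eigengenes(
    expr: pd.DataFrame, partition: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene (leading sample singular vector) per module.

    Each gene is standardised across samples; the eigengene of a module
    is the first right-singular vector of its standardised genes x
    samples block, unit Euclidean norm, with sign oriented so that its
    correlation with the module's mean standardised profile is
    non-negative.

    Returns (eigengenes: samples x modules, variance_explained per
    module -- the fraction of standardised variance carried by the
    leading component).
    """
    modules = sorted(set(partition[partition > 0]))
    eig = {}
    varexp = {}
    for m in modules:
        genes = partition.index[partition == m]
        if len(genes) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        block = expr.loc[genes].to_numpy(dtype=float)
        sd = block.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"zero-variance gene in module {m}")
        z = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[m] = e
        varexp[m] = float(s[0] ** 2 / np.sum(s**2))
    eigengenes = pd.DataFrame(eig, index=expr.columns)
    eigengenes.columns.name = "module"
    return eigengenes, pd.Series(varexp, name="variance_explained")


def merge_modules(
    expr: pd.DataFrame,
    partition: pd.Series,
    merge_cut_height: float = DEFAULT_MERGE_CUT_HEIGHT,
    max_iter: int = 20,
) -> pd.Series:
    """Fuse modules whose eigengenes are highly correlated.

    Modules are clustered (average linkage) on 1 - cor(eigengene_a,
    eigengene_b); clusters joined below ``merge_cut_height`` are merged,
    eigengenes recomputed, and the step repeated until no merge occurs.
    """
    labels = partition.copy()
    for _ in range(max_iter):
        modules = sorted(set(labels[labels > 0]))
        if len(modules) <= 1:
            break
        eig, _ = module_eigengenes(expr, labels)
        cor = np.corrcoef(eig.to_numpy(dtype=float).T)
        diss = np.clip(1.0 - cor, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        diss = (diss + diss.T) / 2.0
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        remap = {m: int(g) for m, g in zip(modules, groups)}
        labels = labels.map(lambda lab: 0 if lab == 0 else remap[lab])
    return _renumber_by_size(labels.to_numpy(), labels.index)
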