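"""Phylogenetic signal (Blomberg's K) with occurrence-level resampling.

K compares the observed trait variance ratio against its Brownian-motion
expectation on the tree:

    K = (MSE0 / MSE) / [(tr(C) - n / (1' C^-1 1)) / (n - 1)]

with C the shared-path-length (Brownian) covariance matrix, MSE0 the mean
squared deviation from the phylogenetically weighted root estimate, and MSE
its C^-1-metric counterpart. Under Brownian motion E[K] ~ 1; K < 1 indicates
weaker signal than the Brownian expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTraitSet",
    "KEstimate",
    "read_tree",
    "phylo_vcv",
    "blomberg_k",
    "k_resampled",
    "k_significance",
]


def read_tree(path=None, newick: str | None = None) -> dendropy.Tree:
    """Newick tree with branch lengths; taxon labels must be unique."""
    if (path is None) == (newick is None):
        raise ValueError("provide exactly one of path or newick")
    if path is not None:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    else:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels in tree")
    return tree


def phylo_vcv(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion variance-covariance matrix.

    C[i, j] = shared root-to-MRCA path length of tips i and j; the diagonal
    holds root-to-tip depths. Returns (C, taxon labels) with labels sorted.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("tree needs at least 2 tips")
    # root-to-node depths
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        if el < 0:
            raise ValueError("negative branch length")
        depth[id(node)] = (depth[id(node.parent_node)] if node.parent_node else 0.0) + \
            (el if node.parent_node else 0.0)
    labels = sorted(leaf.taxon.label for leaf in leaves)
    leaf_by_label = {leaf.taxon.label: leaf for leaf in leaves}
    n = len(labels)
    # ancestor sets for MRCA lookup
    ancestors = {}
    for lab in labels:
        node = leaf_by_label[lab]
        chain = []
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        ancestors[lab] = chain
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        C[i, i] = depth[id(leaf_by_label[a])]
        anc_a = set(ancestors[a])
        for j in range(i + 1, n):
            b = labels[j]
            mrca = next(x for x in ancestors[b] if x in anc_a)
            C[i, j] = C[j, i] = depth[mrca]
    if np.all(C == 0):
        raise ValueError("tree has zero depth everywhere")
    return C, labels


def _k_stats(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Precompute C^-1 and the Brownian expectation denominator."""
    n = C.shape[0]
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    denom_norm = float(ones @ Cinv @ ones)
    expected = (np.trace(C) - n / denom_norm) / (n - 1)
    return Cinv, expected


def blomberg_k(tree_or_C, x, labels: list[str] | None = None) -> float:
    """Blomberg's K for one trait vector.

    ``tree_or_C`` is a dendropy tree or a precomputed C matrix; ``x`` is
    aligned to ``labels`` (or, for a tree, to its sorted tip labels).
    Constant traits return 0 (degenerate, no variance).
    """
    if isinstance(tree_or_C, dendropy.Tree):
        C, tip_labels = phylo_vcv(tree_or_C)
        if labels is not None:
            order = [labels.index(t) for t in tip_labels]
            x = np.asarray(x, dtype=float)[order]
    else:
        C = np.asarray(tree_or_C, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 tips")
    if C.shape != (n, n):
        raise ValueError("trait vector does not match the tree")
    Cinv, expected = _k_stats(C)
    return _k_from_parts(C, Cinv, expected, x[None, :])[0]


def _k_from_parts(C, Cinv, expected, X: np.ndarray) -> np.ndarray:
    """Vectorized K over rows of X (replicates x tips)."""
    n = X.shape[1]
    ones = np.ones(n)
    w = Cinv @ ones
    ahat = (X @ w) / (ones @ w)           # phylogenetic mean per replicate
    resid = X - ahat[:, None]
    mse0 = (resid ** 2).sum(axis=1) / (n - 1)
    mse = np.einsum("ri,ij,rj->r", resid, Cinv, resid) / (n - 1)
    out = np.zeros(len(X))
    # constant trait vectors are degenerate: K defined as 0
    ok = (np.ptp(X, axis=1) > 0) & (mse > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[ok] = (mse0[ok] / mse[ok]) / expected
    return out


@dataclass
class PhyloTraitSet:
    """Tree plus per-taxon occurrence-level trait samples.

    ``samples`` maps taxon label -> DataFrame (rows = occurrences, columns =
    climate variables). Every tip must have at least one sample row.
    """

    tree: dendropy.Tree
    samples: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = tips - set(self.samples)
        if missing:
            raise ValueError(f"no samples for tips: {sorted(missing)}")
        empty = [t for t in tips if len(self.samples[t]) == 0]
        if empty:
            raise ValueError(f"zero sample rows for: {sorted(empty)}")
        cols = None
        for t in tips:
            c = list(self.samples[t].columns)
            if cols is None:
                cols = c
            elif set(c) != set(cols):
                raise ValueError("inconsistent variable names across taxa")

    @property
    def variables(self) -> list[str]:
        first = next(iter(self.samples.values()))
        return list(first.columns)


@dataclass
class KEstimate:
    variable: str
    mean_k: float
    se_k: float
    n_resamples: int


def k_resampled(pts: PhyloTraitSet, variable: str, n_resamples: int = 10_000,
                seed: int | None = None) -> KEstimate:
    """K under occurrence-level resampling.

    Each resample draws one occurrence row per taxon (uniformly, with
    replacement) and computes K on those tip values; reported are the mean
    and the standard error of the mean over resamples.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    C, labels = phylo_vcv(pts.tree)
    Cinv, expected = _k_stats(C)
    rng = np.random.default_rng(seed)
    cols = []
    for lab in labels:
        vals = pts.samples[lab][variable].to_numpy(dtype=float)
        idx = rng.integers(0, len(vals), size=n_resamples)
        cols.append(vals[idx])
    X = np.column_stack(cols)
    ks = _k_from_parts(C, Cinv, expected, X)
    if n_resamples > 1 and np.ptp(ks) > 0:
        se = float(ks.std(ddof=1) / np.sqrt(n_resamples))
    else:
        se = 0.0
    return KEstimate(variable=variable, mean_k=float(ks.mean()), se_k=se,
                     n_resamples=n_resamples)


def k_significance(tree: dendropy.Tree, x, n_perm: int = 999,
                   seed: int | None = None) -> tuple[float, float]:
    """Optional randomization test: shuffle tip values, p = fraction of
    permuted K >= observed (with the +1 correction)."""
    C, labels = phylo_vcv(tree)
    Cinv, expected = _k_stats(C)
    x = np.asarray(x, dtype=float)
    k_obs = _k_from_parts(C, Cinv, expected, x[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    k_null = _k_from_parts(C, Cinv, expected, perms)
    p = (np.sum(k_null >= k_obs) + 1.0) / (n_perm + 1.0)
    return float(k_obs), float(p)
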