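"""Pairwise Spearman correlation of morphometric traits and trait clustering.

All landmark coordinates (x1..x15, y1..y15) and all harmonic coefficients
(A1..D20) are rank-correlated pairwise across leaves.  The resulting
correlation matrix doubles as a distance matrix (d = 1 - rho) for
agglomerative clustering of the traits, which groups traits that co-vary —
e.g. the asymmetric B and C harmonic coefficients, which are near-independent
of the symmetric shape traits, separate from the A/D block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TraitCorrelationMatrix",
    "TraitClustering",
    "spearman_matrix",
    "cluster_traits",
    "linkage_to_newick",
]


@dataclass
class TraitCorrelationMatrix:
    """Symmetric Spearman rho and p matrices over named traits."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: int
    constant_traits: list[str]

    def neg_log10_p(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return -np.log10(self.p)

    def display_matrix(self) -> pd.DataFrame:
        """Lower triangle rho, upper triangle -log10 p (the figure layout)."""
        rho = self.rho.to_numpy()
        out = self.neg_log10_p().to_numpy().copy()
        lower = np.tril_indices(len(rho), k=-1)
        out[lower] = rho[lower]
        np.fill_diagonal(out, 1.0)
        return pd.DataFrame(out, index=self.rho.index, columns=self.rho.columns)


def spearman_matrix(traits) -> TraitCorrelationMatrix:
    """Tie-corrected Spearman rho and two-sided p for every trait pair.

    p-values use the t approximation ``t = rho sqrt((n-2)/(1-rho^2))``.
    Constant traits have undefined correlations; their pairs are recorded as
    missing (NaN) with a warning and the trait names are listed in
    ``constant_traits``.
    """
    if isinstance(traits, pd.DataFrame):
        df = traits
    else:
        arr = np.asarray(traits, dtype=float)
        df = pd.DataFrame(arr, columns=[f"t{i}" for i in range(arr.shape[1])])
    if df.shape[0] < 5:
        raise ValueError("need at least 5 samples for a correlation matrix")
    values = df.to_numpy(dtype=float)
    names = list(df.columns)

    constant = [c for c, v in zip(names, values.T) if np.ptp(v) == 0 or not np.all(np.isfinite(v))]
    if constant:
        warnings.warn(f"traits with undefined correlations (constant): {constant}")

    n = values.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, values)  # mid-ranks: tie-corrected
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.atleast_2d(rho)
        # two-sided p from t = rho sqrt((n-2) / (1 - rho^2))
        r = np.clip(rho, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isinf(t)] = 0.0

    for c in constant:
        i = names.index(c)
        rho[i, :] = np.nan
        rho[:, i] = np.nan
        p[i, :] = np.nan
        p[:, i] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)

    return TraitCorrelationMatrix(
        rho=pd.DataFrame(rho, index=names, columns=names),
        p=pd.DataFrame(p, index=names, columns=names),
        n=df.shape[0],
        constant_traits=constant,
    )


@dataclass
class TraitClustering:
    """Agglomerative clustering of traits from correlation distances."""

    linkage: np.ndarray          # scipy linkage matrix
    trait_names: list[str]       # order corresponding to linkage leaf ids
    leaf_order: list[str]        # dendrogram left-to-right trait order
    method: str
    distance: str

    def newick(self) -> str:
        return linkage_to_newick(self.linkage, self.trait_names)

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child_a", "child_b", "height", "size"]
        )


def cluster_traits(
    corr: TraitCorrelationMatrix,
    linkage: str = "complete",
    distance: str = "one_minus_rho",
) -> TraitClustering:
    """Hierarchically cluster traits on correlation-derived distances.

    ``distance`` is ``"one_minus_rho"`` (signed, d in [0, 2]) or
    ``"one_minus_abs_rho"``.  Traits with undefined correlations are excluded
    first; trait names are sorted before clustering so that exact distance
    ties resolve deterministically (lexicographically).
    """
    usable = sorted(c for c in corr.rho.columns if c not in corr.constant_traits)
    if len(usable) < 2:
        raise ValueError("need at least 2 traits with defined correlations")
    rho = corr.rho.loc[usable, usable].to_numpy()
    if distance == "one_minus_rho":
        d = 1.0 - rho
    elif distance == "one_minus_abs_rho":
        d = 1.0 - np.abs(rho)
    else:
        raise ValueError("distance must be 'one_minus_rho' or 'one_minus_abs_rho'")
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    order = [usable[i] for i in hierarchy.leaves_list(Z)]
    return TraitClustering(
        linkage=Z, trait_names=usable, leaf_order=order, method=linkage, distance=distance
    )


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
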