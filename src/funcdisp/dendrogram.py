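"""Trait dendrograms: hierarchical clustering of species in trait space.

All dispersion metrics downstream consume the *cophenetic* distances implied
by a dendrogram rather than the raw trait distances, following the
dendrogram-based tradition of functional-diversity analysis. The default
linkage is UPGMA (average linkage), the standard choice for trait
dendrograms in ecology; complete and single linkage are available for
sensitivity checks. Cophenetic matrices are ultrametric by construction.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from skbio import TreeNode

from ._errors import ValidationError
from .distance import TraitDistanceMatrix, euclidean_distance, gower_distance
from .traits import CATEGORICAL, TraitTable

#: Key of the combined all-traits dendrogram in :func:`build_all_dendrograms`.
MULTI_TRAIT = "multi_trait"

_LINKAGE_METHODS = ("average", "complete", "single")


class TraitDendrogram:
    """Rooted ultrametric clustering of a species pool.

    Attributes
    ----------
    linkage_matrix:
        scipy linkage encoding of the merge sequence.
    labels:
        Species labels in input order (the tree's leaf set).
    cophenetic:
        :class:`TraitDistanceMatrix` of cophenetic (tree) distances; this is
        what the dispersion metrics use.
    """

    def __init__(self, linkage_matrix: np.ndarray, labels, method: str, name: str = ""):
        self.linkage_matrix = np.asarray(linkage_matrix, dtype=float)
        self.labels = [str(x) for x in labels]
        self.method = method
        self.name = name
        coph = cophenet(self.linkage_matrix)
        from scipy.spatial.distance import squareform

        self.cophenetic = TraitDistanceMatrix(
            squareform(coph), self.labels, name=f"cophenetic:{name}", validate=False
        )

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences.

        Leaf-to-leaf path length through the tree equals the cophenetic
        distance (each side contributes half of the merge height).
        """
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitDendrogram({self.n_leaves} leaves, {self.method}, name={self.name!r})"


def build_dendrogram(
    dist: TraitDistanceMatrix, method: str = "average", name: str | None = None
) -> TraitDendrogram:
    """Cluster a distance matrix into an ultrametric dendrogram (UPGMA default)."""
    if method not in _LINKAGE_METHODS:
        raise ValidationError(
            f"unsupported linkage {method!r}; choose from {_LINKAGE_METHODS}"
        )
    if len(dist) < 2:
        raise ValidationError("need at least 2 species to build a dendrogram")
    Z = linkage(dist.condensed(), method=method)
    return TraitDendrogram(Z, dist.labels, method, name=name or dist.name)


def build_all_dendrograms(
    traits: TraitTable, method: str = "average"
) -> dict[str, TraitDendrogram]:
    """One dendrogram per single trait plus one multi-trait dendrogram.

    Single categorical traits use Gower distance; single continuous traits
    use Euclidean distance on the z-standardized trait; the combined
    multi-trait dendrogram (key :data:`MULTI_TRAIT`) uses Gower over all
    declared traits.
    """
    out: dict[str, TraitDendrogram] = {}
    for t in traits.trait_names:
        if traits.kind(t) == CATEGORICAL:
            d = gower_distance(traits, [t])
        else:
            d = euclidean_distance(traits, t)
        out[t] = build_dendrogram(d, method=method, name=t)
    out[MULTI_TRAIT] = build_dendrogram(
        gower_distance(traits), method=method, name=MULTI_TRAIT
    )
    return out


def is_ultrametric(dist: TraitDistanceMatrix, rtol: float = 1e-9, atol: float = 1e-9) -> bool:
    """Check the ultrametric triple inequality d(a,b) <= max(d(a,c), d(b,c)).

    Exhaustive over all triples; intended for pools of modest size (<= a few
    hundred species).
    """
    D = dist.values
    n = len(dist)
    for c in range(n):
        # for each "witness" c: d(a,b) must not exceed max(d(a,c), d(b,c))
        m = np.maximum(D[:, c][:, None], D[None, :, c])
        if not (D <= m * (1 + rtol) + atol).all():
            return False
    return True
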