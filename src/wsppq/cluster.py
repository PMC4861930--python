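"""Redundancy clustering of regulated categories.

GO-style annotations are hierarchical, so significant categories often
share most of their member proteins.  To report non-redundant biology the
regulated categories are clustered on the Jaccard similarity of their
quantified member sets (average linkage on distance 1 - J, tree cut at a
configurable height), and one representative per cluster is picked — the
member with the largest |Zc|, falling back to the largest category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError, EmptyInputError
from .io import CategoryDB

__all__ = ["CategorySimilarity", "ClusterAssignment",
           "category_similarity", "cluster_categories"]


@dataclass
class CategorySimilarity:
    """Symmetric Jaccard matrix over categories (quantified members only)."""

    category_ids: list[str]
    matrix: np.ndarray  # shape (n, n), unit diagonal, values in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.category_ids,
                            columns=self.category_ids)


@dataclass
class ClusterAssignment:
    """A partition of categories with one representative per cluster."""

    clusters: dict[int, list[str]]
    representatives: dict[int, str]
    cut: float
    linkage_table: pd.DataFrame  # merge order + heights; redraws the dendrogram

    def labels(self) -> dict[str, int]:
        return {cid: k for k, members in self.clusters.items() for cid in members}


def category_similarity(db: CategoryDB, category_ids: list[str],
                        quantified_ids: set[str]) -> CategorySimilarity:
    """Pairwise Jaccard index on member sets intersected with the
    quantified proteome; categories with no quantified member are dropped
    with a warning."""
    sets = {}
    for cid in category_ids:
        members = db.members(cid) & quantified_ids
        if not members:
            warnings.warn(f"category {cid!r} has no quantified member; dropped")
            continue
        sets[cid] = members
    ids = sorted(sets)
    if len(ids) < 2:
        raise EmptyInputError("need >= 2 categories with quantified members")
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[ids[i]], sets[ids[j]]
            mat[i, j] = mat[j, i] = len(a & b) / len(a | b)
    return CategorySimilarity(ids, mat)


def cluster_categories(sim: CategorySimilarity, cut: float = 0.75,
                       scores: Mapping[str, float] | None = None,
                       sizes: Mapping[str, int] | None = None) -> ClusterAssignment:
    """Average-linkage clustering on distance 1 - Jaccard, cut at ``cut``.

    Category ids are processed in sorted order so the merge sequence (and
    therefore the partition) is independent of input order, including on
    tied distances.  The representative of each cluster is the member with
    the largest \\|score\\| (typically Zc), falling back to the largest size
    and then to the lexicographically smallest id.
    """
    if not 0 < cut < 1:
        raise ConfigError("cut must lie in (0, 1)")
    ids = sim.category_ids
    if sorted(ids) != ids:
        order = np.argsort(np.asarray(ids, dtype=object))
        ids = [ids[i] for i in order]
        mat = sim.matrix[np.ix_(order, order)]
    else:
        mat = sim.matrix
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(z, t=cut, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for cid, lab in zip(ids, flat):
        clusters.setdefault(int(lab), []).append(cid)
    # relabel clusters deterministically by their smallest member id
    ordered = sorted(clusters.values(), key=lambda ms: min(ms))
    clusters = {i + 1: sorted(ms) for i, ms in enumerate(ordered)}

    def rep_key(cid: str):
        score = abs(scores[cid]) if scores and cid in scores else float("-inf")
        size = sizes.get(cid, 0) if sizes else 0
        return (-score, -size, cid)

    reps = {k: min(ms, key=rep_key) for k, ms in clusters.items()}
    ltab = pd.DataFrame(z, columns=["left", "right", "height", "n_leaves"])
    return ClusterAssignment(clusters, reps, cut, ltab)
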