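"""Phylogenetic beta-diversity: unweighted UniFrac between plots or forest
types, UPGMA clustering of the distance matrix, and jackknife support for
the clusters.

UniFrac here is the presence/absence (unweighted) form: the fraction of
branch length leading to descendants of exactly one of the two communities,
out of the branch length leading to descendants of at least one.  Branches
ancestral to neither community, and the path above the MRCA of the pooled
community, are excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .phylo import Phylogeny, PhyloError

__all__ = [
    "unifrac",
    "unifrac_matrix",
    "upgma",
    "jackknife_support",
    "ClusterNode",
    "Dendrogram",
]


class _TreeIndex:
    """Per-edge tip masks for fast repeated UniFrac evaluation."""

    def __init__(self, tree: Phylogeny):
        self.labels = tree.tip_labels
        self.index = {l: i for i, l in enumerate(self.labels)}
        n = len(self.labels)
        root = tree.root

        nodes = [nd for nd in tree.dendropy_tree.postorder_node_iter()]
        masks: dict = {}
        edge_masks, edge_lengths, edge_nodes = [], [], []
        for nd in nodes:
            if nd.is_leaf():
                m = np.zeros(n, dtype=bool)
                m[self.index[nd.taxon.label if nd.taxon else nd.label]] = True
            else:
                m = np.zeros(n, dtype=bool)
                for c in nd.child_nodes():
                    m |= masks[c]
            masks[nd] = m
            if nd is not root:
                if nd.edge.length is None:
                    raise PhyloError("UniFrac requires branch lengths on all edges")
                edge_masks.append(m)
                edge_lengths.append(nd.edge.length)
                edge_nodes.append(nd)
        self.edge_masks = np.array(edge_masks)          # (edges, tips)
        self.edge_lengths = np.array(edge_lengths)      # (edges,)
        self._node_masks = masks
        self._nodes = nodes
        self._root = root

    def tip_mask(self, species: Iterable[str]) -> np.ndarray:
        m = np.zeros(len(self.labels), dtype=bool)
        for s in species:
            if s not in self.index:
                raise PhyloError(f"species {s!r} not in tree")
            m[self.index[s]] = True
        return m

    def mrca_mask(self, union: np.ndarray) -> np.ndarray:
        """Tip mask of the MRCA of the tips flagged in *union*."""
        best = self._node_masks[self._root]
        for nd in self._nodes:
            m = self._node_masks[nd]
            if m.sum() < best.sum() and (m | union).sum() == m.sum():
                best = m
        return best

    def distance(self, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
        if not mask_a.any() or not mask_b.any():
            raise PhyloError("UniFrac undefined for an empty community")
        union = mask_a | mask_b
        inside = self.mrca_mask(union)
        # edges strictly within the MRCA subtree: edge tip set is a proper
        # subset of the MRCA tip set
        edge_tip_counts = self.edge_masks.sum(axis=1)
        within = (
            ((self.edge_masks & ~inside[None, :]).sum(axis=1) == 0)
            & (edge_tip_counts < inside.sum())
        )
        in_a = (self.edge_masks & mask_a[None, :]).any(axis=1)
        in_b = (self.edge_masks & mask_b[None, :]).any(axis=1)
        unique = within & (in_a ^ in_b)
        shared = within & (in_a & in_b)
        num = self.edge_lengths[unique].sum()
        den = num + self.edge_lengths[shared].sum()
        if den == 0:
            return 0.0
        return float(num / den)


def unifrac(
    tree: Phylogeny,
    comm_a: Iterable[str],
    comm_b: Iterable[str],
    _index: _TreeIndex | None = None,
) -> float:
    """Unweighted UniFrac distance between two species sets, in [0, 1]."""
    idx = _index if _index is not None else _TreeIndex(tree)
    return idx.distance(idx.tip_mask(comm_a), idx.tip_mask(comm_b))


def unifrac_matrix(
    tree: Phylogeny,
    comm: CommunityMatrix,
    group_by: str = "plot",
) -> pd.DataFrame:
    """Pairwise UniFrac over pooled species sets per plot or metadata group."""
    pooled = comm.pooled_counts(group_by)
    idx = _TreeIndex(tree)
    groups = list(pooled.index)
    masks = {
        g: idx.tip_mask(pooled.columns[pooled.loc[g] > 0]) for g in groups
    }
    for g in groups:
        if not masks[g].any():
            raise PhyloError(f"group {g!r} has no species")
    D = np.zeros((len(groups), len(groups)))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            D[i, j] = D[j, i] = idx.distance(masks[groups[i]], masks[groups[j]])
    return pd.DataFrame(D, index=groups, columns=groups)


# -- UPGMA -----------------------------------------------------------------


@dataclass
class ClusterNode:
    """Node of a UPGMA dendrogram.

    ``height`` is the average between-cluster dissimilarity at the merge
    (leaves sit at height 0); ``support`` is the jackknife proportion, when
    computed.
    """

    labels: frozenset[str]
    height: float = 0.0
    children: list["ClusterNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    root: ClusterNode

    def nodes(self) -> list[ClusterNode]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return out

    def clades(self) -> set[frozenset[str]]:
        """Label bipartitions: tip sets of the internal nodes."""
        return {nd.labels for nd in self.nodes() if not nd.is_leaf}

    def to_newick(self) -> str:
        def fmt(nd: ClusterNode, parent_height: float) -> str:
            length = parent_height - nd.height
            if nd.is_leaf:
                return f"{next(iter(nd.labels))}:{length:g}"
            inner = ",".join(fmt(c, nd.height) for c in nd.children)
            sup = "" if nd.support is None else f"{nd.support:g}"
            return f"({inner}){sup}:{length:g}"

        root = self.root
        inner = ",".join(fmt(c, root.height) for c in root.children)
        sup = "" if root.support is None else f"{root.support:g}"
        return f"({inner}){sup};"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA (average-linkage) clustering of a symmetric distance matrix.

    Merge heights equal the average inter-cluster dissimilarity at the
    merge.  Ties are broken by lexicographic label order, so the result is
    deterministic.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    D = dist.to_numpy(dtype=float)
    if list(dist.columns) != labels or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("UPGMA requires a symmetric distance matrix")

    clusters: dict[int, ClusterNode] = {
        i: ClusterNode(labels=frozenset([l])) for i, l in enumerate(labels)
    }
    sizes = {i: 1 for i in clusters}
    dmat: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    sort_key = {i: (min(c.labels),) for i, c in clusters.items()}
    next_id = len(labels)

    while len(clusters) > 1:
        best = min(
            dmat.items(),
            key=lambda kv: (
                kv[1],
                min(sort_key[kv[0][0]], sort_key[kv[0][1]]),
                max(sort_key[kv[0][0]], sort_key[kv[0][1]]),
            ),
        )
        (i, j), h = best
        a, b = clusters.pop(i), clusters.pop(j)
        merged = ClusterNode(labels=a.labels | b.labels, height=h, children=[a, b])
        na, nb = sizes.pop(i), sizes.pop(j)
        new_d = {}
        for k in clusters:
            dik = dmat[(min(i, k), max(i, k))]
            djk = dmat[(min(j, k), max(j, k))]
            new_d[k] = (na * dik + nb * djk) / (na + nb)
        dmat = {
            (p, q): v for (p, q), v in dmat.items()
            if i not in (p, q) and j not in (p, q)
        }
        for k, v in new_d.items():
            dmat[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        sort_key[next_id] = (min(merged.labels),)
        next_id += 1

    return Dendrogram(root=next(iter(clusters.values())))


def jackknife_support(
    tree: Phylogeny,
    comm: CommunityMatrix,
    group_by: str = "forest_type",
    n_reps: int = 100,
    subsample_size: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> Dendrogram:
    """Jackknifed UPGMA of the group-level UniFrac matrix.

    Each replicate subsamples *subsample_size* individuals per group
    without replacement (default: the smallest group total), recomputes the
    UniFrac matrix and its UPGMA dendrogram, and the support of each node
    in the full-data dendrogram is the fraction of replicates whose
    dendrogram contains the same label bipartition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = comm.pooled_counts(group_by)
    totals = pooled.sum(axis=1)
    if subsample_size is None:
        subsample_size = int(totals.min())
    if subsample_size < 1 or subsample_size > totals.min():
        raise ValueError(
            f"subsample size {subsample_size} exceeds the smallest group total "
            f"({int(totals.min())})"
        )

    idx = _TreeIndex(tree)
    groups = list(pooled.index)
    full_masks = {g: idx.tip_mask(pooled.columns[pooled.loc[g] > 0]) for g in groups}
    full = _matrix_from_masks(idx, groups, full_masks)
    dendro = upgma(full)

    counts = {nd.labels: 0 for nd in dendro.nodes() if not nd.is_leaf}
    for _ in range(n_reps):
        masks = {}
        for g in groups:
            sub = rng.multivariate_hypergeometric(
                pooled.loc[g].to_numpy(), subsample_size
            )
            masks[g] = idx.tip_mask(pooled.columns[sub > 0])
        rep = upgma(_matrix_from_masks(idx, groups, masks))
        for clade in rep.clades():
            if clade in counts:
                counts[clade] += 1

    for nd in dendro.nodes():
        if not nd.is_leaf:
            nd.support = counts[nd.labels] / n_reps
    return dendro


def _matrix_from_masks(idx: _TreeIndex, groups, masks) -> pd.DataFrame:
    D = np.zeros((len(groups), len(groups)))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            D[i, j] = D[j, i] = idx.distance(masks[groups[i]], masks[groups[j]])
    return pd.DataFrame(D, index=groups, columns=groups)
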