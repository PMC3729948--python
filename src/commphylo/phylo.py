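"""Phylogeny data model, newick I/O, bladj age interpolation, and the
pairwise distance / correlation matrices on which the diversity metrics are
built.

The tree is stored as a :class:`dendropy.Tree`; this module adds the thin,
validated surface the rest of the package works against.  Ages and branch
lengths are in millions of years (Myr) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloError",
    "NewickParseError",
    "Phylogeny",
    "AgeConstraints",
    "parse_newick",
    "bladj_date",
    "cophenetic_distances",
    "phylo_correlation",
]


class PhyloError(ValueError):
    """Invalid tree, constraint set, or tree-dependent computation."""


class NewickParseError(PhyloError):
    """Malformed newick input."""


class Phylogeny:
    """A rooted phylogeny with optional branch lengths and node labels.

    Thin wrapper over :class:`dendropy.Tree` enforcing the invariants the
    analysis needs: a single root, unique tip labels, and non-negative branch
    lengths where present.  Polytomies are allowed and retained as-is
    (family-level backbone trees are typically unresolved below family).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        if not text or not text.strip():
            raise NewickParseError("empty newick string")
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"newick parse error: {exc}") from exc
        if tree.seed_node is None or not list(tree.leaf_node_iter()):
            raise NewickParseError("newick string contains no tips")
        return cls(tree)

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate tip labels: {dups}")
        if any(l is None for l in labels):
            raise NewickParseError("unlabelled tip")
        for node in self._tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise PhyloError(
                    f"negative branch length {node.edge.length} at "
                    f"{node.taxon.label if node.taxon else node.label}"
                )

    # -- basic accessors --------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def tip_labels(self) -> list[str]:
        return [t.taxon.label if t.taxon else t.label
                for t in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def internal_labels(self) -> list[str]:
        return [n.label for n in self._tree.preorder_internal_node_iter()
                if n.label]

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- geometry ----------------------------------------------------------

    def has_branch_lengths(self) -> bool:
        """True when every non-root edge carries a length."""
        root = self.root
        return all(
            n.edge.length is not None
            for n in self._tree.preorder_node_iter()
            if n is not root
        )

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance of every node from the root (root = 0).

        Raises :class:`PhyloError` if a non-root edge lacks a length.
        """
        depths: dict[dendropy.Node, float] = {}
        root = self.root
        for node in self._tree.preorder_node_iter():
            if node is root:
                depths[node] = 0.0
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else (node.label or "<unlabelled>")
                raise PhyloError(f"missing branch length above node {name!r}")
            depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def tip_depths(self) -> pd.Series:
        depths = self.node_depths()
        return pd.Series(
            {(
                n.taxon.label if n.taxon else n.label
            ): depths[n] for n in self._tree.leaf_node_iter()},
            dtype=float,
        )

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.tip_depths().to_numpy()
        return bool(d.size and (d.max() - d.min()) <= tol * max(1.0, d.max()))

    def total_branch_length(self) -> float:
        root = self.root
        return float(sum(
            n.edge.length or 0.0
            for n in self._tree.preorder_node_iter()
            if n is not root
        ))


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Branch lengths absent from the string stay absent (they are not coerced
    to zero); internal node labels are preserved for age calibration.
    """
    return Phylogeny.from_newick(text)


@dataclass
class AgeConstraints:
    """Ages (Myr before present) for labelled internal nodes.

    The on-disk dialect is PHYLOCOM's ages file: two tab-separated columns,
    ``node_label<TAB>age``, ``#`` comments allowed.
    """

    ages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, age in self.ages.items():
            if not math.isfinite(age) or age < 0:
                raise PhyloError(f"invalid age {age!r} for node {label!r}")

    @classmethod
    def from_file(cls, path) -> "AgeConstraints":
        ages: dict[str, float] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 2:
                    raise PhyloError(
                        f"{path}:{lineno}: expected 'label<TAB>age', got {raw!r}"
                    )
                label, age_s = parts[0].strip(), parts[1].strip()
                if label in ages:
                    raise PhyloError(f"{path}:{lineno}: duplicate label {label!r}")
                try:
                    ages[label] = float(age_s)
                except ValueError as exc:
                    raise PhyloError(
                        f"{path}:{lineno}: non-numeric age {age_s!r}"
                    ) from exc
        return cls(ages)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# node_label<TAB>age (Myr)\n")
            for label, age in self.ages.items():
                fh.write(f"{label}\t{age:g}\n")

    def __contains__(self, label: str) -> bool:
        return label in self.ages

    def __getitem__(self, label: str) -> float:
        return self.ages[label]


def bladj_date(tree: Phylogeny, ages: AgeConstraints) -> Phylogeny:
    """Assign ages to undated internal nodes by even interpolation (bladj).

    Nodes named in *ages* are fixed; tips are fixed at age 0.  Every undated
    node on a path between two dated nodes receives an age spaced evenly
    between them.  An undated node interpolates between its nearest dated
    ancestor and the oldest dated node beneath it that is reachable without
    crossing another dated node (a tip, at age 0, if no internal node is
    dated below).  Branch lengths are recomputed as parent age minus child
    age, so the output is ultrametric.  Input branch lengths are ignored.

    Raises
    ------
    PhyloError
        If the root is unconstrained, a constrained label is absent from the
        tree, or a constrained node is older than a constrained ancestor.
    """
    work = tree.copy()
    dtree = work.dendropy_tree
    root = dtree.seed_node

    internal_by_label: dict[str, dendropy.Node] = {}
    for node in dtree.preorder_internal_node_iter():
        if node.label:
            if node.label in internal_by_label:
                raise PhyloError(f"duplicate internal node label {node.label!r}")
            internal_by_label[node.label] = node

    missing = sorted(set(ages.ages) - set(internal_by_label))
    if missing:
        raise PhyloError(f"age constraints for labels absent from tree: {missing}")

    fixed: dict[dendropy.Node, float] = {}
    for label, age in ages.ages.items():
        fixed[internal_by_label[label]] = age
    for leaf in dtree.leaf_node_iter():
        fixed[leaf] = 0.0

    if root not in fixed:
        raise PhyloError(
            "root age unconstrained: bladj requires a dated root "
            "(add the root label to the ages file)"
        )

    # Dated node younger than none of its dated ancestors.
    for node, age in list(fixed.items()):
        anc = node.parent_node
        while anc is not None:
            if anc in fixed:
                if age > fixed[anc] + 1e-12:
                    raise PhyloError(
                        f"constrained node at age {age} is older than its "
                        f"constrained ancestor at age {fixed[anc]}"
                    )
                break
            anc = anc.parent_node

    def frontier(v: dendropy.Node) -> list[tuple[float, int, str]]:
        """Dated nodes below v reachable without crossing a dated node.

        Returns (age, steps from v, tiebreak label) triples.
        """
        out: list[tuple[float, int, str]] = []
        stack = [(c, 1) for c in v.child_nodes()]
        while stack:
            node, steps = stack.pop()
            if node in fixed:
                name = node.taxon.label if node.taxon else (node.label or "")
                out.append((fixed[node], steps, name))
            else:
                stack.extend((c, steps + 1) for c in node.child_nodes())
        return out

    # Top-down sequential assignment: once a node's age is interpolated it
    # acts as dated for everything beneath it.  Along a dated-to-dated chain
    # this reproduces exact even spacing, and it guarantees child ages never
    # exceed parent ages even when sibling subtrees interpolate against
    # chains of different lengths.
    age_of: dict[dendropy.Node, float] = dict(fixed)
    for v in dtree.preorder_internal_node_iter():
        if v in fixed:
            continue
        # nearest dated ancestor and step count up to it
        anc, k = v.parent_node, 1
        while anc not in fixed:
            anc, k = anc.parent_node, k + 1
        cands = frontier(v)
        # oldest dated descendant; ties to the shortest chain, then by label
        age_d, steps_vd, _ = max(cands, key=lambda c: (c[0], -c[1], c[2]))
        n = k + steps_vd
        age_of[v] = fixed[anc] - k * (fixed[anc] - age_d) / n
        fixed[v] = age_of[v]

    for node in dtree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        length = age_of[node.parent_node] - age_of[node]
        if length < -1e-9:
            raise PhyloError(
                "bladj produced a negative branch length; "
                "age constraints are mutually inconsistent"
            )
        node.edge.length = max(length, 0.0)

    return Phylogeny(dtree)


def _tip_index(tree: Phylogeny) -> tuple[list[str], dict[str, int]]:
    labels = tree.tip_labels
    return labels, {l: i for i, l in enumerate(labels)}


def cophenetic_distances(tree: Phylogeny) -> pd.DataFrame:
    """Species-by-species patristic distance matrix (Myr).

    d(i, j) is the sum of branch lengths on the path between tips i and j,
    computed as depth_i + depth_j − 2 · depth of their MRCA.
    """
    labels, index = _tip_index(tree)
    depths = tree.node_depths()
    n = len(labels)
    D = np.zeros((n, n), dtype=float)

    tipdepth = np.zeros(n)
    for node in tree.dendropy_tree.leaf_node_iter():
        tipdepth[index[node.taxon.label if node.taxon else node.label]] = depths[node]

    # One postorder pass: every tip pair is assigned exactly once, at its MRCA.
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node.taxon.label if node.taxon else node.label]]
            continue
        children = [tipsets[c] for c in node.child_nodes()]
        dn = depths[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        D[i, j] = D[j, i] = tipdepth[i] + tipdepth[j] - 2.0 * dn
        tipsets[node] = [i for ch in children for i in ch]

    return pd.DataFrame(D, index=labels, columns=labels)


def phylo_correlation(tree: Phylogeny) -> pd.DataFrame:
    """Phylogenetic correlation matrix C underlying PSV/PSE.

    c_ij is the root-to-MRCA depth shared by tips i and j divided by the tip
    depth (ultrametric trees); for non-ultrametric trees the generalization
    sharedDepth / sqrt(depth_i · depth_j) is used.  Diagonal is exactly 1.
    """
    labels, index = _tip_index(tree)
    depths = tree.node_depths()
    n = len(labels)
    tipdepth = np.empty(n)
    for node in tree.dendropy_tree.leaf_node_iter():
        tipdepth[index[node.taxon.label if node.taxon else node.label]] = depths[node]
    if np.any(tipdepth <= 0):
        raise PhyloError("zero tip depth: correlation undefined")

    C = np.eye(n)
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node.taxon.label if node.taxon else node.label]]
            continue
        children = [tipsets[c] for c in node.child_nodes()]
        dn = depths[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = dn / math.sqrt(tipdepth[i] * tipdepth[j])
        tipsets[node] = [i for ch in children for i in ch]

    return pd.DataFrame(C, index=labels, columns=labels)
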