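"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a statistic from first principles — path
enumeration on the tree, explicit loops over individual pairs, textbook
sums of squares — sharing no metric code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def tip_paths(tree):
    """label -> list of nodes from root to tip (inclusive)."""
    paths = {}
    for leaf in tree.dendropy_tree.leaf_node_iter():
        chain, node = [], leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        label = leaf.taxon.label if leaf.taxon else leaf.label
        paths[label] = chain[::-1]
    return paths


def brute_cophenetic(tree, a: str, b: str) -> float:
    """d(a,b) = depth_a + depth_b − 2·sharedDepth via root-to-tip paths."""
    paths = tip_paths(tree)

    def depth(path):
        return sum(n.edge.length or 0.0 for n in path[1:])

    pa, pb = paths[a], paths[b]
    shared = 0.0
    for x, y in zip(pa, pb):
        if x is y and x.parent_node is not None:
            shared += x.edge.length or 0.0
        elif x is not y:
            break
    return depth(pa) + depth(pb) - 2.0 * shared


def brute_pd(tree, species: set[str]) -> float:
    """Rooted PD: union of root-to-tip edges over the species set."""
    paths = tip_paths(tree)
    edges = set()
    total = 0.0
    for sp in species:
        for node in paths[sp][1:]:
            if id(node) not in edges:
                edges.add(id(node))
                total += node.edge.length or 0.0
    return total


def brute_correlation(tree, a: str, b: str) -> float:
    paths = tip_paths(tree)

    def depth(path):
        return sum(n.edge.length or 0.0 for n in path[1:])

    pa, pb = paths[a], paths[b]
    if a == b:
        return 1.0
    shared = 0.0
    for x, y in zip(pa, pb):
        if x is y and x.parent_node is not None:
            shared += x.edge.length or 0.0
        elif x is not y:
            break
    return shared / np.sqrt(depth(pa) * depth(pb))


def individual_expansion_pse(tree, abundances: dict[str, int]) -> float:
    """PSE via explicit enumeration of heterospecific individual pairs,
    each individual treated as a tip with conspecific correlation 1."""
    inds = [sp for sp, n in abundances.items() for _ in range(n)]
    num = den = 0.0
    for i, j in itertools.combinations(range(len(inds)), 2):
        if inds[i] == inds[j]:
            continue
        num += brute_correlation(tree, inds[i], inds[j])
        den += 1.0
    return 1.0 - num / den


def brute_mpd(tree, abundances: dict[str, int]) -> float:
    inds = [sp for sp, n in abundances.items() for _ in range(n)]
    num = den = 0.0
    for i, j in itertools.combinations(range(len(inds)), 2):
        if inds[i] == inds[j]:
            continue
        num += brute_cophenetic(tree, inds[i], inds[j])
        den += 1.0
    return num / den


def brute_mntd(tree, abundances: dict[str, int]) -> float:
    species = [sp for sp, n in abundances.items() if n > 0]
    total = weight = 0.0
    for sp in species:
        nn = min(brute_cophenetic(tree, sp, other)
                 for other in species if other != sp)
        total += abundances[sp] * nn
        weight += abundances[sp]
    return total / weight


def brute_unifrac(tree, comm_a: set[str], comm_b: set[str]) -> float:
    """Branch-by-branch enumeration within the union's MRCA subtree."""
    paths = tip_paths(tree)
    union = comm_a | comm_b
    # MRCA = last common node of all union paths
    chains = [paths[sp] for sp in union]
    mrca = chains[0][0]
    for level in zip(*chains):
        if all(n is level[0] for n in level):
            mrca = level[0]
        else:
            break

    def tips_under(node):
        out = set()
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                out.add(nd.taxon.label if nd.taxon else nd.label)
            stack.extend(nd.child_nodes())
        return out

    unique = shared = 0.0
    stack = list(mrca.child_nodes())
    while stack:
        nd = stack.pop()
        tips = tips_under(nd)
        in_a, in_b = bool(tips & comm_a), bool(tips & comm_b)
        if in_a and in_b:
            shared += nd.edge.length or 0.0
        elif in_a or in_b:
            unique += nd.edge.length or 0.0
        stack.extend(nd.child_nodes())
    if unique + shared == 0:
        return 0.0
    return unique / (unique + shared)


def brute_upgma_merges(D: np.ndarray, labels: list[str]):
    """Naive UPGMA: returns the sequence of (merged label set, height)."""
    clusters = {i: {labels[i]} for i in range(len(labels))}
    merges = []
    dist = {frozenset((i, j)): float(D[i, j])
            for i in range(len(labels)) for j in range(i + 1, len(labels))}
    nxt = len(labels)
    while len(clusters) > 1:
        key = min(dist, key=lambda k: (dist[k],
                                       tuple(sorted(min(clusters[i]) for i in k))))
        i, j = sorted(key)
        h = dist[key]
        merged = clusters[i] | clusters[j]
        ni, nj = len(clusters[i]), len(clusters[j])
        merges.append((frozenset(merged), h))
        newd = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            newd[k] = (ni * dik + nj * djk) / (ni + nj)
        del clusters[i], clusters[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k, v in newd.items():
            dist[frozenset((k, nxt))] = v
        clusters[nxt] = merged
        nxt += 1
    return merges


def brute_anova_f(groups: list[np.ndarray]) -> float:
    """F from textbook between/within sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, N = len(groups), len(allv)
    if ssw == 0:
        return 0.0 if ssb == 0 else np.inf
    return (ssb / (k - 1)) / (ssw / (N - k))


def brute_kruskal_h(groups: list[np.ndarray]) -> float:
    """H from rank sums with the tie correction."""
    allv = np.concatenate(groups)
    N = len(allv)
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(N)
    sorted_v = allv[order]
    i = 0
    while i < N:
        j = i
        while j < N and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    # tie correction
    _, counts = np.unique(allv, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    return h / tie
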