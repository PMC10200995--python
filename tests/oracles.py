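"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately takes the dumbest correct route (exhaustive
enumeration, O(n^3) loops) and shares no code with the library paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# monophyly by exhaustive clade enumeration


def all_clade_leafsets(dendropy_tree):
    """Leaf-label set of every node (leaves included) via per-node re-walk."""
    clades = []
    for node in dendropy_tree.preorder_node_iter():
        labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades.append(labels)
    return clades


def brute_monophyly(gft, section_map):
    """Section -> bool by scanning *all* clades for an exact diploid match."""
    leaves_by_section = {}
    diploid_leaves = set()
    for label in gft.leaf_labels():
        sp = section_map.species_of_leaf(label)
        if section_map.is_diploid(sp):
            leaves_by_section.setdefault(section_map.section_of[sp], set()).add(label)
            diploid_leaves.add(label)
    clades = all_clade_leafsets(gft.tree)
    result = {}
    for section, leaves in leaves_by_section.items():
        result[section] = any((clade & diploid_leaves) == leaves for clade in clades)
    return result


# ---------------------------------------------------------------------------
# node census by independent recount


def brute_census(trees, section_map):
    """Recount every internal node independently: combo -> (raw, weight)."""
    table = {}
    for gft in trees:
        for node in gft.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            labels = []
            for lf in node.leaf_iter():
                sp = section_map.species_of_leaf(lf.taxon.label)
                if section_map.is_polyploid(sp):
                    labels.append(sp)
                else:
                    labels.append(section_map.section_of[sp])
            combo = frozenset(labels)
            if len(combo) < 2:
                continue
            raw, weight = table.get(combo, (0, 0.0))
            table[combo] = (raw + 1, weight + 1.0 / len(labels))
    return table


# ---------------------------------------------------------------------------
# UPGMA by explicit O(n^3) average linkage


def brute_upgma_cophenetic(d):
    """Cophenetic (2 * node height) matrix from naive average linkage."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))

    def avg_dist(a, b):
        return float(
            np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
        )

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            dist = avg_dist(a, b)
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = dist
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


# ---------------------------------------------------------------------------
# two-character compatibility by exhaustive tree search (<= 6 taxa)


def _rooted_trees(leaves):
    """All rooted binary tree shapes over the given leaves (nested tuples)."""
    if len(leaves) == 1:
        return [leaves[0]]
    trees = []
    first, rest = leaves[0], leaves[1:]
    for sub in _rooted_trees(rest):
        for placed in _insert_everywhere(sub, first):
            trees.append(placed)
    return trees


def _insert_everywhere(tree, leaf):
    """Insert ``leaf`` on every edge of a rooted tree, plus above the root."""
    out = [(tree, leaf)]
    if isinstance(tree, tuple):
        left, right = tree
        out.extend((new, right) for new in _insert_everywhere(left, leaf))
        out.extend((left, new) for new in _insert_everywhere(right, leaf))
    return out


def all_unrooted_trees(n_taxa):
    """All unrooted binary trees on taxa 0..n-1, rooted at taxon 0's edge."""
    assert n_taxa >= 3
    return [(sub, 0) for sub in _rooted_trees(list(range(1, n_taxa)))]


def fitch_length(tree, states):
    """Fitch parsimony length of one character on a rooted nested-tuple tree."""
    changes = 0

    def walk(node):
        nonlocal changes
        if not isinstance(node, tuple):
            return {states[node]}
        left, right = map(walk, node)
        inter = left & right
        if inter:
            return inter
        changes += 1
        return left | right

    walk(tree)
    return changes


def brute_pair_compatibility(states_i, states_j, trees=None):
    """1 iff NO tree lets both characters evolve without homoplasy, else 0."""
    n = len(states_i)
    if trees is None:
        trees = all_unrooted_trees(n)
    min_i = len(set(states_i)) - 1
    min_j = len(set(states_j)) - 1
    for tree in trees:
        if fitch_length(tree, states_i) == min_i and fitch_length(tree, states_j) == min_j:
            return 0
    return 1
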