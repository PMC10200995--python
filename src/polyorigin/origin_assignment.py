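"""Homeolog origin tagging and ancestral-node census.

This is the analytical core of the pipeline.  For every gene-family tree
(rooted on the outgroup) each polyploid leaf is tagged with its *closest
diploid section*: walk from the leaf toward the root and stop at the first
ancestor with at least one diploid leaf among its descendants; the tag is
the set of sections of all diploid leaves under that ancestor.  A single
section yields an unambiguous origin; several sections yield a multi-origin
tag (e.g. the leaf joins above the common ancestor of two sister sections).
A leaf whose first diploid-bearing ancestor is the root, or whose tag spans
a non-monophyletic section, is tagged ``unresolved``.

Across many trees, the *node census* summarizes which section combinations
repeatedly share an ancestral node: every internal node contributes its
combination of section labels (polyploid leaves count as pseudo-sections
named by species), with weight ``1 / (number of leaves under the node)`` so
that deep, uninformative nodes are penalized.  Both the raw node count and
the normalized weight are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AssignmentError, RootingError
from .sections import SectionMap
from .treeio import GeneFamilyTree

#: Sentinel tag for leaves without a resolvable diploid origin.
UNRESOLVED = ("unresolved",)


def _leafsets(tree) -> dict:
    """Map id(node) -> frozenset of leaf labels under the node (postorder)."""
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset((node.taxon.label,))
        else:
            acc = frozenset()
            for child in node.child_nodes():
                acc |= sets[id(child)]
            sets[id(node)] = acc
    return sets


def root_on_outgroup(gft: GeneFamilyTree, section_map: SectionMap) -> GeneFamilyTree:
    """Return a copy of the tree rooted on the edge subtending the outgroup leaf.

    Idempotent: a tree already rooted with the outgroup as one of the two
    root children is returned unchanged (as a copy).
    """
    rooted = gft.clone()
    out_sp = section_map.outgroup_species
    out_leaves = [
        leaf
        for leaf in rooted.tree.leaf_node_iter()
        if section_map.species_of_leaf(leaf.taxon.label) == out_sp
    ]
    if len(out_leaves) != 1:
        raise RootingError(
            f"tree {gft.id}: expected exactly one outgroup leaf ({out_sp}), "
            f"found {len(out_leaves)}"
        )
    leaf = out_leaves[0]
    seed = rooted.tree.seed_node
    if len(seed.child_nodes()) == 2 and leaf in seed.child_nodes():
        return rooted
    rooted.tree.is_rooted = True
    rooted.tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    return rooted


def check_section_monophyly(gft: GeneFamilyTree, section_map: SectionMap) -> dict:
    """Monophyly flag for every diploid section present in the tree.

    A section is monophyletic iff the MRCA of its diploid leaves subtends no
    diploid leaf of another section.  Polyploid and outgroup leaves nested
    inside the clade do not break monophyly (a nested homeolog is expected
    under allopolyploidy, not evidence against the section).  Sections with
    a single leaf are trivially monophyletic.
    """
    species_of = section_map.resolve_leaves(gft.leaf_labels())
    diploid_leaves_by_section: dict = {}
    for leaf, sp in species_of.items():
        if section_map.is_diploid(sp):
            diploid_leaves_by_section.setdefault(
                section_map.section_of[sp], set()
            ).add(leaf)
    all_diploid_leaves = frozenset(
        leaf for leaves in diploid_leaves_by_section.values() for leaf in leaves
    )
    sets = _leafsets(gft.tree)
    result = {}
    for section, leaves in diploid_leaves_by_section.items():
        if len(leaves) == 1:
            result[section] = True
            continue
        # MRCA = smallest leafset containing all of the section's leaves.
        mrca_set = min(
            (s for s in sets.values() if leaves <= s), key=len
        )
        result[section] = (mrca_set & all_diploid_leaves) <= leaves
    return result


@dataclass
class OriginTagging:
    """Per-tree origin tags for every polyploid leaf."""

    tree_id: str
    tags: dict  # leaf label -> tuple of section names, or UNRESOLVED
    monophyly: dict = field(default_factory=dict)

    def tag_of(self, leaf: str) -> tuple:
        return self.tags[leaf]

    def is_unresolved(self, leaf: str) -> bool:
        return self.tags[leaf] == UNRESOLVED


def assign_leaf_origins(
    gft: GeneFamilyTree, section_map: SectionMap, monophyly: dict | None = None
) -> OriginTagging:
    """Tag every polyploid leaf with its closest diploid section(s).

    ``monophyly`` may be passed to reuse a precomputed check; otherwise it
    is computed here.  Multi-origin tags are sorted alphabetically for a
    canonical representation.
    """
    if monophyly is None:
        monophyly = check_section_monophyly(gft, section_map)
    species_of = section_map.resolve_leaves(gft.leaf_labels())
    sets = _leafsets(gft.tree)

    diploid_leaves = frozenset(
        leaf for leaf, sp in species_of.items() if section_map.is_diploid(sp)
    )
    if not diploid_leaves:
        raise AssignmentError(f"tree {gft.id}: no diploid leaves, cannot assign origins")

    seed = gft.tree.seed_node
    tags = {}
    for leaf_node in gft.tree.leaf_node_iter():
        label = leaf_node.taxon.label
        if not section_map.is_polyploid(species_of[label]):
            continue
        node = leaf_node.parent_node
        tag = UNRESOLVED
        while node is not None:
            under = sets[id(node)] & diploid_leaves
            if under:
                if node is seed:
                    tag = UNRESOLVED
                else:
                    sections = sorted(
                        {
                            section_map.section_of[species_of[leaf]]
                            for leaf in under
                        }
                    )
                    if any(not monophyly.get(s, False) for s in sections):
                        tag = UNRESOLVED
                    else:
                        tag = tuple(sections)
                break
            node = node.parent_node
        tags[label] = tag
    return OriginTagging(tree_id=gft.id, tags=tags, monophyly=dict(monophyly))


def taggings_to_tsv(taggings, path) -> None:
    with open(path, "w") as fh:
        fh.write("tree_id\tleaf\ttag\n")
        for tg in taggings:
            for leaf in sorted(tg.tags):
                fh.write(f"{tg.tree_id}\t{leaf}\t{','.join(tg.tags[leaf])}\n")


@dataclass
class NodeWeightTable:
    """Accumulated census of section combinations across trees."""

    entries: dict = field(default_factory=dict)  # frozenset -> [raw, weight]

    def add(self, combination: frozenset, n_leaves: int) -> None:
        raw_weight = self.entries.setdefault(frozenset(combination), [0, 0.0])
        raw_weight[0] += 1
        raw_weight[1] += 1.0 / n_leaves

    def raw(self, *sections) -> int:
        return self.entries.get(frozenset(sections), [0, 0.0])[0]

    def weight(self, *sections) -> float:
        return self.entries.get(frozenset(sections), [0, 0.0])[1]

    @property
    def total_raw(self) -> int:
        return sum(rw[0] for rw in self.entries.values())

    def sorted_items(self) -> list:
        return sorted(
            self.entries.items(), key=lambda kv: (-kv[1][1], sorted(kv[0]))
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("combination\traw_count\tweight\n")
            for combo, (raw, weight) in self.sorted_items():
                fh.write(f"{'+'.join(sorted(combo))}\t{raw}\t{weight:.6f}\n")


def node_weight_census(trees, section_map: SectionMap) -> NodeWeightTable:
    """Census every internal node's section combination across all trees.

    Diploid and outgroup leaves contribute their section name; polyploid
    leaves contribute a pseudo-section named by species.  Each internal
    node with >= 2 distinct labels contributes raw count 1 and weight
    ``1 / n_leaves_under_node``.
    """
    table = NodeWeightTable()
    for gft in trees:
        species_of = section_map.resolve_leaves(gft.leaf_labels())
        label_of = {
            leaf: (sp if section_map.is_polyploid(sp) else section_map.section_of[sp])
            for leaf, sp in species_of.items()
        }
        sets = _leafsets(gft.tree)
        for node in gft.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            leaves = sets[id(node)]
            combo = frozenset(label_of[leaf] for leaf in leaves)
            if len(combo) >= 2:
                table.add(combo, len(leaves))
    return table
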