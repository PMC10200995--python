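"""Tree-type classification, control-polyploid validation and consensus.

Trees sharing the same multiset of homeolog origin tags per polyploid
species form a *type*.  Types are validated against a control polyploid of
known parentage (trees where the control's tags disagree with the expected
parent sections are discarded), grouped, and — for sufficiently populated
types — summarized by a greedy majority-rule consensus over the member
trees after relabeling gene copies by species + origin (the same
relabeling is exported as an ASTRAL-style mapping file, so an external
quartet-based consensus can be run on the same inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .errors import AssignmentError, MappingError
from .origin_assignment import UNRESOLVED, OriginTagging, _leafsets
from .sections import SectionMap
from .treeio import GeneFamilyTree

logger = logging.getLogger(__name__)


def _fmt_tag(tag: tuple) -> str:
    return "{" + ",".join(tag) + "}"


def classify_tree(tagging: OriginTagging, section_map: SectionMap) -> str:
    """Canonical type signature for one tagged tree.

    Format: ``species:{tagA},{tagB}|species2:{tagC}`` with species sorted,
    and each species' tags sorted as a multiset.  The signature is
    invariant to leaf input order; unresolved tags propagate into it.
    """
    by_species: dict = {}
    for leaf, tag in tagging.tags.items():
        sp = section_map.species_of_leaf(leaf)
        by_species.setdefault(sp, []).append(_fmt_tag(tag))
    parts = []
    for sp in sorted(by_species):
        parts.append(f"{sp}:{','.join(sorted(by_species[sp]))}")
    return "|".join(parts)


@dataclass
class ControlFilterResult:
    kept: list = field(default_factory=list)  # tree ids
    discarded: dict = field(default_factory=dict)  # tree id -> reason
    flagged: list = field(default_factory=list)  # kept only via multi-origin tags


def apply_control_filter(
    taggings, section_map: SectionMap
) -> ControlFilterResult:
    """Discard trees where the control polyploid's tags contradict its known parents.

    A tree is kept iff the control polyploid's singleton tags all belong to
    the expected parent set and every expected parent section is covered by
    some tag.  A multi-origin tag containing an expected section counts as
    covering it but flags the tree.  Unresolved control tags discard the
    tree.  With no control polyploid configured, all trees are kept and a
    warning is logged.
    """
    result = ControlFilterResult()
    control = section_map.control_polyploid
    expected = section_map.expected_parent_sections
    if control is None or not expected:
        logger.warning("no control polyploid configured; control filter is a no-op")
        result.kept = [tg.tree_id for tg in taggings]
        return result

    for tg in taggings:
        control_tags = [
            tag
            for leaf, tag in tg.tags.items()
            if section_map.species_of_leaf(leaf) == control
        ]
        if not control_tags:
            result.discarded[tg.tree_id] = "control_absent"
            continue
        if any(tag == UNRESOLVED for tag in control_tags):
            result.discarded[tg.tree_id] = "control_unresolved"
            continue
        singletons = {tag[0] for tag in control_tags if len(tag) == 1}
        if not singletons <= expected:
            result.discarded[tg.tree_id] = "unexpected_parent"
            continue
        needs_multi = False
        missing = False
        for section in expected:
            if section in singletons:
                continue
            if any(section in tag for tag in control_tags):
                needs_multi = True
            else:
                missing = True
        if missing:
            result.discarded[tg.tree_id] = "missing_expected_parent"
            continue
        result.kept.append(tg.tree_id)
        if needs_multi:
            result.flagged.append(tg.tree_id)
    return result


@dataclass
class TypeGroup:
    """One tree type: identifier, signature and member trees."""

    type_id: str
    signature: str
    members: list
    retained: bool

    def __len__(self) -> int:
        return len(self.members)


def group_by_type(signatures: dict, min_trees: int = 3) -> list:
    """Group trees by signature; assign Type identifiers by descending size.

    ``signatures`` maps tree id -> signature string.  Groups are sorted by
    descending member count, ties broken by signature; groups smaller than
    ``min_trees`` are reported with ``retained=False``.
    """
    by_sig: dict = {}
    for tid, sig in signatures.items():
        by_sig.setdefault(sig, []).append(tid)
    ordered = sorted(by_sig.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    groups = []
    for i, (sig, members) in enumerate(ordered, start=1):
        groups.append(
            TypeGroup(
                type_id=f"Type{i:03d}",
                signature=sig,
                members=sorted(members),
                retained=len(members) >= min_trees,
            )
        )
    return groups


def groups_to_tsv(groups, path) -> None:
    with open(path, "w") as fh:
        fh.write("type_id\tn_trees\tretained\tsignature\tmembers\n")
        for g in groups:
            fh.write(
                f"{g.type_id}\t{len(g)}\t{str(g.retained).lower()}\t"
                f"{g.signature}\t{','.join(g.members)}\n"
            )


def _section_abbreviations(sections) -> dict:
    """Shortest unambiguous per-section suffix: first letter, else full name."""
    sections = sorted(set(sections))
    first = {}
    for s in sections:
        first.setdefault(s[0].upper(), []).append(s)
    out = {}
    for letter, ss in first.items():
        if len(ss) == 1:
            out[ss[0]] = letter
        else:
            for s in ss:
                out[s] = s
    return out


def origin_suffix(tag: tuple, abbreviations: dict) -> str:
    if tag == UNRESOLVED:
        return "U"
    return "".join(abbreviations.get(s, s) for s in tag)


def build_taxon_map(group: TypeGroup, taggings, section_map: SectionMap) -> dict:
    """Composite taxon name -> gene-copy labels, over the group's member trees.

    Diploid and outgroup leaves map identically to their species; polyploid
    leaves map to ``species_<origin suffix>`` (e.g. a Sylvestres-derived
    copy of species ``Nafr`` becomes ``Nafr_S``).
    """
    if not group.members:
        raise AssignmentError(f"{group.type_id}: empty group")
    tagging_of = {tg.tree_id: tg for tg in taggings}
    abbr = _section_abbreviations(section_map.diploid_sections)
    mapping: dict = {}
    for tid in group.members:
        tg = tagging_of[tid]
        for leaf, tag in tg.tags.items():
            sp = section_map.species_of_leaf(leaf)
            name = f"{sp}_{origin_suffix(tag, abbr)}"
            mapping.setdefault(name, set()).add(leaf)
    return {name: sorted(members) for name, members in sorted(mapping.items())}


def complete_taxon_map(group, taggings, trees, section_map: SectionMap) -> dict:
    """Taxon map covering *all* leaves (diploids as identity entries)."""
    mapping = build_taxon_map(group, taggings, section_map)
    tree_of = {gft.id: gft for gft in trees}
    for tid in group.members:
        for leaf in tree_of[tid].leaf_labels():
            sp = section_map.species_of_leaf(leaf)
            if not section_map.is_polyploid(sp):
                mapping.setdefault(sp, [])
                if leaf not in mapping[sp]:
                    mapping[sp].append(leaf)
    return {name: sorted(members) for name, members in sorted(mapping.items())}


def write_astral_map(mapping: dict, path) -> None:
    """ASTRAL mapping-file format: ``name: member,member,...``"""
    with open(path, "w") as fh:
        for name in sorted(mapping):
            fh.write(f"{name}: {','.join(mapping[name])}\n")


def consensus_tree(
    trees, taxon_map: dict, min_freq: float = 0.5
) -> dendropy.Tree:
    """Greedy majority-rule consensus over member trees, relabeled taxa.

    Leaves are first relabeled per ``taxon_map`` (gene copy -> composite
    taxon).  For each tree, every internal node whose leaf set maps onto
    *complete* composite taxa yields a clade (partial clades, where only
    some copies of a taxon fall under the node, are skipped).  Clades with
    frequency >= ``min_freq`` are added greedily in order of decreasing
    frequency if compatible with the clades already accepted.  Internal
    node labels carry the clade frequency.
    """
    if not trees:
        raise AssignmentError("consensus of an empty tree set")
    name_of = {}
    for name, members in taxon_map.items():
        for member in members:
            name_of[member] = name

    universe = set()
    clade_counts: dict = {}
    for gft in trees:
        sets = _leafsets(gft.tree)
        unmapped = [l for l in gft.leaf_labels() if l not in name_of]
        if unmapped:
            raise MappingError(f"tree {gft.id}: unmapped leaves {sorted(unmapped)}")
        copies_of: dict = {}
        for leaf in gft.leaf_labels():
            copies_of.setdefault(name_of[leaf], set()).add(leaf)
        tree_names = set(copies_of)
        universe |= tree_names
        seen = set()
        for node in gft.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            leaves = sets[id(node)]
            names = {name_of[l] for l in leaves}
            # complete-coverage check: all copies of each mapped taxon present
            if any(not copies_of[n] <= leaves for n in names):
                continue
            if len(names) < 2 or names == tree_names:
                continue
            clade = frozenset(names)
            if clade not in seen:  # count once per tree
                seen.add(clade)
                clade_counts[clade] = clade_counts.get(clade, 0) + 1

    n_trees = len(trees)
    candidates = sorted(
        (
            (count / n_trees, clade)
            for clade, count in clade_counts.items()
            if count / n_trees >= min_freq
        ),
        key=lambda fc: (-fc[0], -len(fc[1]), sorted(fc[1])),
    )
    accepted = []
    for freq, clade in candidates:
        if all(
            clade <= other or other <= clade or not (clade & other)
            for _, other in accepted
        ):
            accepted.append((freq, clade))

    return _build_tree_from_clades(universe, accepted)


def _build_tree_from_clades(universe, freq_clades) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(sorted(universe))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    root.clade_set = frozenset(universe)
    root.freq = 1.0
    # insert largest first so parents exist before children
    nodes = [root]
    for freq, clade in sorted(freq_clades, key=lambda fc: -len(fc[1])):
        if clade == frozenset(universe):
            continue
        parent = min(
            (nd for nd in nodes if clade <= nd.clade_set),
            key=lambda nd: len(nd.clade_set),
        )
        node = dendropy.Node()
        node.clade_set = clade
        node.freq = freq
        parent.add_child(node)
        nodes.append(node)
    for name in sorted(universe):
        parent = min(
            (nd for nd in nodes if name in nd.clade_set),
            key=lambda nd: len(nd.clade_set),
        )
        leaf = dendropy.Node(taxon=taxa.get_taxon(name))
        parent.add_child(leaf)
    for nd in nodes:
        if nd is not root:
            nd.label = f"{nd.freq:.4g}"
    return tree


def consensus_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
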