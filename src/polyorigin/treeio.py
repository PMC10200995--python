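"""Reading and writing gene-family trees.

Trees travel as multi-tree Newick, one tree per line, as produced by
high-throughput ML pipelines.  Internal node labels are interpreted as
support values (bootstrap percentages); the ``"alrt/ufboot"`` double-label
dialect is accepted, in which case the *last* component is used.  A missing
label is recorded as *absent* support (``None``), never as zero — the
distinction matters for support-based filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .errors import NewickParseError


def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    token = label.split("/")[-1]
    try:
        return float(token)
    except ValueError:
        return None


@dataclass
class GeneFamilyTree:
    """One gene-family ML tree with per-node supports.

    ``tree`` is a :class:`dendropy.Tree`; every internal non-seed node gets
    a ``support`` attribute (float percentage or ``None``).
    """

    id: str
    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str, tree_id: str) -> "GeneFamilyTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(str(exc)) from exc
        out = cls(id=tree_id, tree=tree)
        out._annotate_supports()
        return out

    def _annotate_supports(self) -> None:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node is self.tree.seed_node:
                node.support = None
            else:
                node.support = _parse_support(node.label)

    # -- views -----------------------------------------------------------

    def leaf_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def internal_nodes(self, exclude_seed: bool = True):
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if exclude_seed and node is self.tree.seed_node:
                continue
            yield node

    def clone(self) -> "GeneFamilyTree":
        return GeneFamilyTree.from_newick(self.as_newick(), self.id)

    # -- serialization ---------------------------------------------------

    def as_newick(self) -> str:
        return _node_to_newick(self.tree.seed_node, is_root=True) + ";"


def _fmt_length(length) -> str:
    if length is None:
        return ""
    return f":{length:.6g}"


def _fmt_support(support) -> str:
    if support is None:
        return ""
    if float(support) == int(support):
        return str(int(support))
    return f"{support:g}"


def _node_to_newick(node, is_root: bool = False) -> str:
    if node.is_leaf():
        return f"{node.taxon.label}{_fmt_length(node.edge.length)}"
    inner = ",".join(_node_to_newick(c) for c in node.child_nodes())
    label = "" if is_root else _fmt_support(getattr(node, "support", None))
    length = "" if is_root else _fmt_length(node.edge.length)
    return f"({inner}){label}{length}"


def read_multitree(path, id_prefix: str = "F") -> list:
    """Read a one-tree-per-line multi-tree Newick file.

    Tree identifiers are positional: ``F0001``, ``F0002``, ... (prefix
    configurable).  A malformed line raises :class:`NewickParseError`
    naming the offending line number.
    """
    trees = []
    with open(path) as fh:
        lines = fh.readlines()
    n = 0
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        if not text.endswith(";"):
            raise NewickParseError(f"{path}: line {lineno}: tree not terminated by ';'")
        n += 1
        try:
            trees.append(GeneFamilyTree.from_newick(text, f"{id_prefix}{n:04d}"))
        except NewickParseError as exc:
            raise NewickParseError(f"{path}: line {lineno}: {exc}") from exc
    return trees


def write_multitree(trees, path) -> None:
    with open(path, "w") as fh:
        for gft in trees:
            fh.write(gft.as_newick() + "\n")
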