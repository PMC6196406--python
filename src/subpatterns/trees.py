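"""Numbered tree topologies and annotated Newick I/O.

PAML's reconstruction output numbers nodes the way this module does: tips
are 1..n (in alignment order), internal nodes n+1..2n-1 with the root at
n+1. A :class:`TreeTopology` is just that numbering plus parent/child maps;
Newick serialization and parsing are delegated to dendropy.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy

from .errors import UnknownBranchError, RstParseError

Branch = tuple[int, int]

_TIP_LABEL = re.compile(r"^(\d+)_(.+)$")


@dataclass(frozen=True)
class TreeTopology:
    """Rooted tree over numbered nodes, PAML-style.

    ``parent`` maps each non-root node to its parent; ``tip_names`` maps
    tip numbers (1..n) to taxon names. Branches are directed parent->child.
    """

    parent: dict[int, int]
    tip_names: dict[int, str]
    root: int

    # derived, filled in __post_init__
    children: dict[int, tuple[int, ...]] = field(default=None, repr=False)

    def __post_init__(self):
        kids: dict[int, list[int]] = {}
        for child, par in self.parent.items():
            kids.setdefault(par, []).append(child)
        object.__setattr__(
            self, "children", {p: tuple(sorted(c)) for p, c in kids.items()}
        )

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.parent) | {self.root}))

    @property
    def branches(self) -> tuple[Branch, ...]:
        """All (parent, child) edges in preorder."""
        out: list[Branch] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in self.children.get(node, ()):
                out.append((node, child))
                stack.append(child)
        return tuple(out)

    def is_tip(self, node: int) -> bool:
        return node in self.tip_names

    def preorder(self) -> list[int]:
        order = [self.root]
        i = 0
        while i < len(order):
            order.extend(self.children.get(order[i], ()))
            i += 1
        return order


def _require_branches(tree: TreeTopology, branches) -> None:
    known = set(tree.branches)
    for b in branches:
        if tuple(b) not in known:
            raise UnknownBranchError(f"branch {b} not in tree")


def _build_dendropy(tree: TreeTopology) -> tuple[dendropy.Tree, dict[int, dendropy.Node]]:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, dendropy.Node] = {tree.root: dtree.seed_node}
    dtree.seed_node.label = str(tree.root)
    for node in tree.preorder():
        for child in tree.children.get(node, ()):
            dnode = dendropy.Node()
            nodes[node].add_child(dnode)
            if tree.is_tip(child):
                dnode.taxon = taxa.new_taxon(f"{child}_{tree.tip_names[child]}")
            else:
                dnode.label = str(child)
            nodes[child] = dnode
    return dtree, nodes


def to_numbered_newick(tree: TreeTopology) -> str:
    """Newick with `k_name` tips and bare internal node numbers as labels."""
    dtree, _ = _build_dendropy(tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_leaf_node_labels=False,
    )
    return text.strip() + "\n"


def from_numbered_newick(text: str) -> TreeTopology:
    """Parse a numbered-node Newick string back into a topology."""
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    number_of: dict[int, int] = {}
    parent: dict[int, int] = {}
    tip_names: dict[int, str] = {}

    def node_number(dnode) -> int:
        if dnode.taxon is not None:
            m = _TIP_LABEL.match(dnode.taxon.label)
            if not m:
                raise RstParseError(
                    f"tip label without numeric prefix: {dnode.taxon.label!r}"
                )
            tip_names[int(m.group(1))] = m.group(2)
            return int(m.group(1))
        if dnode.label is None or not dnode.label.strip().isdigit():
            raise RstParseError(f"internal node without number: {dnode.label!r}")
        return int(dnode.label)

    numbers = {id(nd): node_number(nd) for nd in dtree.preorder_node_iter()}
    root = numbers[id(dtree.seed_node)]
    for nd in dtree.preorder_node_iter():
        for child in nd.child_nodes():
            parent[numbers[id(child)]] = numbers[id(nd)]
    return TreeTopology(parent=parent, tip_names=tip_names, root=root)


def write_annotated_newick(
    tree: TreeTopology,
    labels: dict[Branch, str],
    annotation_name: str = "subs",
) -> str:
    """Serialize a topology with per-branch text annotations.

    Each labeled branch carries its text as a FigTree-style bracket comment
    (``[&subs="..."]``) attached to the branch's child node, so viewers and
    dendropy both recover it on re-parse.
    """
    _require_branches(tree, labels)
    dtree, nodes = _build_dendropy(tree)
    for (par, child), text in labels.items():
        nodes[child].annotations.add_new(annotation_name, f'"{text}"')
    out = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_annotations=False,
    )
    return out.strip() + "\n"


def read_annotated_newick(
    text: str, annotation_name: str = "subs"
) -> tuple[TreeTopology, dict[Branch, str]]:
    """Inverse of :func:`write_annotated_newick` (topology + label map)."""
    tree = from_numbered_newick(text)
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    labels: dict[Branch, str] = {}
    numbers = {}
    for nd in dtree.preorder_node_iter():
        if nd.taxon is not None:
            numbers[id(nd)] = int(_TIP_LABEL.match(nd.taxon.label).group(1))
        else:
            numbers[id(nd)] = int(nd.label)
    for nd in dtree.preorder_node_iter():
        for ann in nd.annotations:
            if ann.name == annotation_name and nd.parent_node is not None:
                branch = (numbers[id(nd.parent_node)], numbers[id(nd)])
                labels[branch] = str(ann.value).strip('"')
    return tree, labels
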