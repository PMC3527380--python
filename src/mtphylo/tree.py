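"""Phylogenetic tree container: multifurcating, optionally rooted, annotatable.

Nodes carry an optional branch length (in years for simulated genealogies)
and the list of variant calls assigned to the branch above them.  Newick
parsing goes through dendropy; serialisation is a direct recursive writer so
mutation annotations can be embedded as comments.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

from .annotate import VariantCall, format_label


class TreeError(ValueError):
    pass


class TreeNode:
    __slots__ = ("name", "children", "parent", "length", "mutations")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        self.length = length
        self.mutations: list[VariantCall] = []

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"<TreeNode {self.name or '·'} deg={len(self.children)}>"


class PhyloTree:
    """A (multi)furcating tree over labelled leaves.

    ``rooted=False`` marks trees whose root placement is an arbitrary
    representation artefact (e.g. output of an unrooted parsimony search).
    """

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # ---- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> TreeNode:
        for n in self.postorder():
            if n.name == name:
                return n
        raise TreeError(f"no node named {name!r}")

    def mrca(self, names: Iterable[str]) -> TreeNode:
        targets = set(names)
        missing = targets - set(self.leaf_names())
        if missing:
            raise TreeError(f"leaves not in tree: {sorted(missing)}")
        found: dict[TreeNode, set] = {}
        for node in self.postorder():
            if node.is_leaf:
                found[node] = {node.name} & targets
            else:
                found[node] = set().union(*(found[c] for c in node.children))
            if targets <= found[node]:
                return node
        raise TreeError("empty clade specification")

    def clade_leaf_names(self, node: TreeNode) -> list[str]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return out

    # ---- copying / editing ----------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(n: TreeNode) -> TreeNode:
            c = TreeNode(n.name, n.length)
            c.mutations = list(n.mutations)
            for ch in n.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def suppress_unifurcations(self) -> None:
        """Splice out internal nodes with a single child (in place)."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                (child,) = node.children
                if node is self.root:
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    if child.length is not None or node.length is not None:
                        child.length = (child.length or 0) + (node.length or 0)
                    child.parent = parent
                    child.mutations = node.mutations + child.mutations
                    parent.children[idx] = child
                changed = True

    # ---- splits ----------------------------------------------------------
    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        if not all_leaves:
            return frozenset()
        anchor = min(all_leaves)
        n = len(all_leaves)
        below: dict[TreeNode, frozenset[str]] = {}
        out = set()
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
                continue
            below[node] = frozenset().union(*(below[c] for c in node.children))
            side = below[node]
            if 1 < len(side) < n - 1:
                out.add(side if anchor not in side else all_leaves - side)
        return frozenset(out)

    # ---- newick ----------------------------------------------------------
    def to_newick(
        self, lengths: bool = False, annotations: bool = False
    ) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if annotations and node.mutations:
                labels = " ".join(str(format_label(m)) for m in node.mutations)
                s += f"[&mutations='{labels}']"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=False)

        def convert(dn) -> TreeNode:
            name = None
            if dn.taxon is not None:
                name = dn.taxon.label
            elif dn.label:
                name = dn.label
            node = TreeNode(name=name, length=dn.edge.length)
            for ch in dn.child_nodes():
                node.add_child(convert(ch))
            return node

        return cls(convert(dt.seed_node), rooted=rooted)

    def __repr__(self):
        return f"<PhyloTree n_leaves={len(self.leaves())} rooted={self.rooted}>"


def reroot_at_node(tree: PhyloTree, target: TreeNode) -> PhyloTree:
    """Return a copy of ``tree`` re-hung so that ``target`` is the root.

    Branch mutation lists are discarded (they are direction-dependent);
    branch lengths are preserved on the re-oriented edges.
    """
    # adjacency with edge lengths
    ids = {}
    nodes = list(tree.postorder())
    for i, n in enumerate(nodes):
        ids[n] = i
    adj: dict[int, list[tuple[int, Optional[float]]]] = {i: [] for i in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            adj[ids[n]].append((ids[c], c.length))
            adj[ids[c]].append((ids[n], c.length))
    root_id = ids[target]
    new_nodes = {i: TreeNode(nodes[i].name) for i in range(len(nodes))}
    seen = {root_id}
    stack = [root_id]
    while stack:
        u = stack.pop()
        for v, ln in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            child = new_nodes[v]
            child.length = ln
            new_nodes[u].add_child(child)
            stack.append(v)
    out = PhyloTree(new_nodes[root_id], rooted=True)
    out.suppress_unifurcations()
    return out
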