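"""Rooted phylogenies with branch lengths and branch-class labels.

A :class:`Phylogeny` is stored as flat arrays (parent pointers, child lists,
edge lengths above each node, a foreground/background class per edge) so the
likelihood engine can traverse it cheaply.  Newick text is parsed with
dendropy; writing is done directly.

Branch classes refer to the edge *above* each node; the root carries no edge.
Class 0 is background, class 1 foreground (the C4 transition branches in the
selection scan).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

BACKGROUND = 0
FOREGROUND = 1


class _Node:
    """Mutable helper node used for tree surgery."""

    __slots__ = ("name", "length", "kids")

    def __init__(self, name=None, length=0.0, kids=None):
        self.name = name
        self.length = length
        self.kids = kids if kids is not None else []


class Phylogeny:
    """Rooted tree over named tips, binary except possibly at the root.

    Parameters
    ----------
    parent : array of int
        Parent index per node; -1 for the root.
    children : list of list of int
        Child indices per node (empty for tips).
    lengths : array of float
        Edge length above each node (ignored for the root).
    tip_labels : sequence of str
        Labels for nodes ``0 .. n_tips-1``; internal nodes are unnamed.
    classes : array of int, optional
        Branch class (0 background / 1 foreground) per edge; defaults to all
        background.
    """

    def __init__(self, parent, children, lengths, tip_labels, classes=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if classes is None:
            self.classes = np.zeros(self.n_nodes, dtype=np.int64)
        else:
            self.classes = np.asarray(classes, dtype=np.int64).copy()
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self._validate()

    def _validate(self):
        if len(set(self.tip_labels)) != self.n_tips:
            raise ValueError("tip names must be unique")
        if not np.all(np.isfinite(self.lengths)):
            raise ValueError("branch lengths must be finite")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        for i in range(self.n_tips):
            if self.children[i]:
                raise ValueError("tips must be leaf nodes")

    # ------------------------------------------------------------------ #
    @property
    def tip_index(self) -> dict:
        return {name: i for i, name in enumerate(self.tip_labels)}

    def postorder(self) -> np.ndarray:
        """All node indices, children before parents."""
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.asarray(order[::-1], dtype=np.int64)

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1].copy()

    def is_binary(self) -> bool:
        return all(len(self.children[v]) in (0, 2)
                   for v in range(self.n_nodes))

    def tips_below(self, node: int) -> frozenset:
        """Labels of all tip descendants of ``node`` (itself if a tip)."""
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(self.tip_labels[v])
            stack.extend(self.children[v])
        return frozenset(out)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent, self.children, self.lengths,
                         self.tip_labels, self.classes)

    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.lengths[mask].sum())

    # ------------------------------------------------------------------ #
    # conversion to/from the mutable helper representation
    def _to_node(self, index: int) -> _Node:
        if index < self.n_tips:
            return _Node(self.tip_labels[index], self.lengths[index])
        return _Node(None, self.lengths[index],
                     [self._to_node(c) for c in self.children[index]])

    @classmethod
    def _from_node(cls, root: _Node) -> "Phylogeny":
        tips, internals = [], []

        def collect(n):
            if n.kids:
                internals.append(n)
                for k in n.kids:
                    collect(k)
            else:
                tips.append(n)

        collect(root)
        index = {id(n): i for i, n in enumerate(tips)}
        for j, n in enumerate(internals):
            index[id(n)] = len(tips) + j
        n_nodes = len(tips) + len(internals)
        parent = [-1] * n_nodes
        children = [[] for _ in range(n_nodes)]
        lengths = [0.0] * n_nodes

        def wire(n):
            i = index[id(n)]
            lengths[i] = float(n.length)
            for k in n.kids:
                parent[index[id(k)]] = i
                children[i].append(index[id(k)])
                wire(k)

        wire(root)
        return cls(parent, children, lengths, [n.name for n in tips])

    # ------------------------------------------------------------------ #
    # construction
    @classmethod
    def from_newick(cls, text: str, default_length: float = 0.0) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(tree, default_length=default_length)

    @classmethod
    def from_dendropy(cls, tree: "dendropy.Tree",
                      default_length: float = 0.0) -> "Phylogeny":
        def convert(dnode):
            if dnode.is_leaf():
                if dnode.taxon is None:
                    raise ValueError("unlabeled tip in newick input")
                node = _Node(dnode.taxon.label)
            else:
                node = _Node(None, 0.0,
                             [convert(c) for c in dnode.child_nodes()])
            el = dnode.edge.length
            node.length = default_length if el is None else float(el)
            return node

        return cls._from_node(convert(tree.seed_node))

    @classmethod
    def from_nested(cls, spec, tip_length: float = 0.0,
                    internal_length: float = 0.0) -> "Phylogeny":
        """Build from nested tuples of tip names, e.g. ``((('Zm','Sb'),...))``."""
        def build(s):
            if isinstance(s, str):
                return _Node(s, tip_length)
            return _Node(None, internal_length, [build(c) for c in s])

        return cls._from_node(build(spec))

    # ------------------------------------------------------------------ #
    # newick output
    def newick(self, lengths: bool = True, digits: int = 10) -> str:
        def fmt(node):
            if node < self.n_tips:
                s = self.tip_labels[node]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            if lengths and node != self.root:
                s += f":{self.lengths[node]:.{digits}g}"
            return s

        return fmt(self.root) + ";"

    def topology_key(self) -> str:
        """Canonical string key for the rooted topology (ignores lengths)."""
        def key(node):
            if node < self.n_tips:
                return self.tip_labels[node]
            return "(" + ",".join(sorted(key(c)
                                         for c in self.children[node])) + ")"

        return key(self.root)

    # ------------------------------------------------------------------ #
    # manipulation
    def restrict(self, keep: Iterable[str]) -> "Phylogeny":
        """Prune to the given tips, suppressing unifurcations.

        Merged edges sum their lengths; branch classes are reset to
        background (foreground labeling is applied after pruning).
        """
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("cannot restrict a tree to fewer than 2 tips")

        def reduce(node: _Node):
            if not node.kids:
                return node if node.name in keep else None
            kids = [reduce(k) for k in node.kids]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            node.kids = kids
            return node

        root = reduce(self._to_node(self.root))
        root.length = 0.0
        return self._from_node(root)

    def with_tip_expanded(self, label: str, new_labels: Sequence[str],
                          cherry_length: float = 0.02) -> "Phylogeny":
        """Replace one tip by a two-tip cherry (maize homeolog expansion)."""
        if label not in self.tip_labels:
            raise ValueError(f"tip {label!r} not in tree")

        def expand(node: _Node):
            if not node.kids:
                if node.name == label:
                    return _Node(None, node.length,
                                 [_Node(nl, cherry_length)
                                  for nl in new_labels])
                return node
            node.kids = [expand(k) for k in node.kids]
            return node

        return self._from_node(expand(self._to_node(self.root)))

    def relabeled(self, mapping: dict) -> "Phylogeny":
        """Return a copy with tip labels renamed via ``mapping``."""
        out = self.copy()
        out.tip_labels = [mapping.get(t, t) for t in out.tip_labels]
        if len(set(out.tip_labels)) != out.n_tips:
            raise ValueError("relabeling produced duplicate tip names")
        return out
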