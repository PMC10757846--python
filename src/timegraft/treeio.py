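"""Rooted trees with absolute node ages, plus Newick I/O and tree queries.

Two tree flavours share one node model:

* :class:`TimeTree` — an ultrametric chronogram. Every node carries an
  *age* in millions of years (myr); tips sit at age 0 and the branch
  length of a node is ``parent.age - node.age``. Because ages (not branch
  lengths) are the stored state, pruning and grafting never accumulate
  floating-point error in divergence times.
* :class:`PhyloTree` — an untimed phylogeny whose branch lengths are in
  substitutions per site; it carries no age semantics.

Newick is the only external format (one tree per file, unquoted labels
with underscores for spaces, no NHX comments). Parsing is delegated to
dendropy; writing is done here so the 6-decimal branch-length format is
stable across versions.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "TimeTree",
    "PhyloTree",
    "TreeError",
    "NotUltrametricError",
    "MissingTaxonError",
    "read_newick",
    "write_newick",
    "pendant_lengths",
    "crown_age",
    "mrca",
    "prune_tips",
    "find_sister",
    "DEFAULT_ULTRAMETRIC_RTOL",
]

#: Accepted relative deviation of root-to-tip depths (fraction of tree
#: height) before a timed tree is rejected as non-ultrametric. Published
#: chronograms digitised from figures carry limited precision, so a small
#: tolerance is required; ages are then rebuilt from mean path lengths.
DEFAULT_ULTRAMETRIC_RTOL = 1e-4


class TreeError(ValueError):
    """Malformed tree, or an operation applied to an unsuitable tree."""


class NotUltrametricError(TreeError):
    """A timed tree whose root-to-tip depths disagree beyond tolerance."""

    def __init__(self, tip_a: str, tip_b: str, depth_a: float, depth_b: float):
        self.tips = (tip_a, tip_b)
        super().__init__(
            f"tree is not ultrametric: tip {tip_a!r} has root-to-tip depth "
            f"{depth_a:.6g} but tip {tip_b!r} has depth {depth_b:.6g}"
        )


class MissingTaxonError(TreeError):
    """A requested taxon label is not present in the tree."""


class Node:
    """A tree node; ``age`` is used by TimeTree, ``length`` by PhyloTree."""

    __slots__ = ("label", "children", "parent", "age", "length")

    def __init__(self, label: str | None = None, age: float = 0.0,
                 length: float = 0.0):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.age = age
        self.length = length

    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def tip_nodes(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_tip()]

    @property
    def tip_label_set(self) -> frozenset[str]:
        return frozenset(n.label for n in self.tip_nodes())

    def copy(self) -> "Node":
        new = Node(self.label, self.age, self.length)
        for c in self.children:
            new.add_child(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip() else f"internal[{len(self.children)}]"
        return f"<Node {self.label or ''} {kind} age={self.age:.4g}>"


def _parse_newick_topology(text: str) -> Node:
    """Parse Newick into our node model; branch lengths land in ``length``."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label:
            label = label.replace(" ", "_")
        node = Node(label=label or None,
                    length=dnode.edge.length if dnode.edge.length else 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    labels = [t.label for t in root.tip_nodes()]
    if any(not lab for lab in labels):
        raise TreeError("every tip must carry a non-empty label")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dup}")
    return root


class _TreeBase:
    """Shared queries over the node model (label lookup, MRCA, clades)."""

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {
            t.label: t for t in root.tip_nodes()
        }

    # -- basic accessors -------------------------------------------------
    def tips(self) -> list[Node]:
        return self.root.tip_nodes()

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self._index)

    @property
    def n_tips(self) -> int:
        return len(self._index)

    def find(self, label: str) -> Node:
        try:
            return self._index[label]
        except KeyError:
            raise MissingTaxonError(f"taxon {label!r} not in tree") from None

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.postorder() if not n.is_tip()]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def _reindex(self) -> None:
        self._index = {t.label: t for t in self.root.tip_nodes()}

    # -- relationships ---------------------------------------------------
    def path_to_root(self, node: Node) -> list[Node]:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def mrca(self, taxa: Iterable[str]) -> Node:
        labels = list(taxa)
        if not labels:
            raise TreeError("mrca of an empty taxon set")
        nodes = [self.find(l) for l in labels]
        ancestors = set(id(n) for n in self.path_to_root(nodes[0]))
        node = nodes[0]
        for other in nodes[1:]:
            for anc in self.path_to_root(other):
                if id(anc) in ancestors:
                    # restrict the running ancestor set to anc's own path
                    node = anc
                    ancestors = set(id(a) for a in self.path_to_root(anc))
                    break
        return node

    def find_sister(self, tip: str) -> Node | list[Node]:
        """Sister clade of a tip: the other child of its parent.

        Returns a single node for binary parents, a list under polytomy.
        """
        node = self.find(tip)
        if node.parent is None:
            raise TreeError(f"{tip!r} is the whole tree; it has no sister")
        sisters = [c for c in node.parent.children if c is not node]
        return sisters[0] if len(sisters) == 1 else sisters


class TimeTree(_TreeBase):
    """A rooted ultrametric chronogram with node ages in myr."""

    def __init__(self, root: Node, validate: bool = True):
        super().__init__(root)
        if validate:
            self.validate()

    # -- construction / serialisation ------------------------------------
    @classmethod
    def from_newick(cls, text: str,
                    rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> "TimeTree":
        root = _parse_newick_topology(text)
        _ages_from_branch_lengths(root, rtol)
        return cls(root)

    def to_newick(self) -> str:
        return _write(self.root, lambda n: n.parent.age - n.age)

    def copy(self) -> "TimeTree":
        return TimeTree(self.root.copy(), validate=False)

    def validate(self) -> None:
        """Check ultrametricity (tips at 0) and age monotonicity."""
        if self.n_tips == 0:
            raise TreeError("empty tree")
        for node in self.postorder():
            if node.is_tip():
                if node.age != 0.0:
                    raise TreeError(
                        f"tip {node.label!r} has age {node.age}; tips must "
                        "sit at age 0 (ultrametric tree)")
            else:
                oldest_child = max(c.age for c in node.children)
                if node.age <= oldest_child:
                    raise TreeError(
                        f"internal node age {node.age:.6g} is not older than "
                        f"its children (max child age {oldest_child:.6g})")

    # -- measures ---------------------------------------------------------
    @property
    def crown_age(self) -> float:
        """Age of the root (myr): the crown age of the sampled clade."""
        return self.root.age

    def pendant_lengths(self) -> dict[str, float]:
        """Terminal branch length (PL) per tip: the age of its parent."""
        out = {}
        for t in self.tips():
            out[t.label] = t.parent.age if t.parent is not None else 0.0
        return out

    def divergence_time(self, a: str, b: str) -> float:
        return self.mrca([a, b]).age

    @property
    def total_branch_length(self) -> float:
        return sum(n.parent.age - n.age for n in self.postorder()
                   if n.parent is not None)

    def clades(self, restrict: Iterable[str] | None = None
               ) -> dict[frozenset[str], float]:
        """Map clade tip-sets to MRCA ages, optionally restricted.

        With ``restrict``, each clade's tip set is intersected with the
        given taxa and only sets of >= 2 taxa are kept; nested nodes that
        collapse to the same restricted set keep the youngest (MRCA) age.
        """
        keep = frozenset(restrict) if restrict is not None else None
        out: dict[frozenset[str], float] = {}
        sets: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip():
                sets[id(node)] = frozenset((node.label,))
                continue
            s = frozenset().union(*(sets[id(c)] for c in node.children))
            sets[id(node)] = s
            key = s if keep is None else s & keep
            if len(key) >= 2 and (key not in out or node.age < out[key]):
                out[key] = node.age
        return out

    def prune(self, tips: Iterable[str]) -> "TimeTree":
        """Remove the given tips, suppressing degree-2 nodes.

        Node ages are carried over verbatim, so all pairwise divergence
        times among surviving tips are exactly unchanged. The crown age
        shrinks if the root is suppressed.
        """
        drop = set(tips)
        unknown = drop - self.tip_labels
        if unknown:
            raise MissingTaxonError(f"cannot prune unknown taxa: {sorted(unknown)}")
        if self.n_tips - len(drop) < 2:
            raise TreeError("pruning would leave fewer than 2 tips")

        def filtered(node: Node) -> Node | None:
            if node.is_tip():
                if node.label in drop:
                    return None
                return Node(node.label, node.age)
            kept = [k for c in node.children if (k := filtered(c)) is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            new = Node(node.label, node.age)
            for k in kept:
                new.add_child(k)
            return new

        new_root = filtered(self.root)
        assert new_root is not None
        return TimeTree(new_root)


class PhyloTree(_TreeBase):
    """A rooted phylogeny with branch lengths in substitutions/site."""

    def __init__(self, root: Node, validate: bool = True):
        super().__init__(root)
        if validate:
            for node in root.postorder():
                if node.parent is not None and node.length < 0:
                    raise TreeError(
                        f"negative branch length {node.length} above "
                        f"{node.label or 'an internal node'}")

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(_parse_newick_topology(text))

    def to_newick(self) -> str:
        return _write(self.root, lambda n: n.length)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), validate=False)

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths keyed by ``id(node)``."""
        out = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[id(node)] = out[id(node.parent)] + node.length
        return out

    @property
    def height(self) -> float:
        d = self.depths()
        return max(d[id(t)] for t in self.tips())


# ---------------------------------------------------------------------------
# helpers

def _ages_from_branch_lengths(root: Node, rtol: float) -> None:
    """Turn parsed branch lengths into node ages, enforcing ultrametricity.

    Root-to-tip depths must agree to ``rtol`` of tree height; ages are then
    rebuilt as mean path lengths from each node to its descendant tips
    (exact when the input is exactly ultrametric), with tips pinned at 0.
    """
    if root.is_tip():
        root.age = 0.0          # degenerate single-taxon tree
        return
    depth = {id(root): 0.0}
    for node in root.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + node.length
    tips = root.tip_nodes()
    deepest = max(tips, key=lambda t: depth[id(t)])
    shallowest = min(tips, key=lambda t: depth[id(t)])
    height = depth[id(deepest)]
    if height <= 0:
        raise TreeError("tree has zero height; cannot assign ages")
    if depth[id(deepest)] - depth[id(shallowest)] > rtol * height:
        raise NotUltrametricError(deepest.label, shallowest.label,
                                  depth[id(deepest)], depth[id(shallowest)])

    # mean path length to descendant tips, then a monotonicity touch-up
    info: dict[int, tuple[int, float]] = {}   # id -> (n tips, mean height)
    for node in root.postorder():
        if node.is_tip():
            info[id(node)] = (1, 0.0)
            node.age = 0.0
        else:
            n = 0
            acc = 0.0
            for c in node.children:
                cn, ch = info[id(c)]
                n += cn
                acc += cn * (ch + c.length)
            h = acc / n
            oldest = max(info[id(c)][1] for c in node.children)
            if h <= oldest:
                h = oldest + 1e-12 * height
            info[id(node)] = (n, h)
            node.age = h


def _write(root: Node, length_of: Callable[[Node], float]) -> str:
    def rec(node: Node) -> str:
        if node.is_tip():
            s = node.label
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
        if node.parent is not None:
            s += f":{length_of(node):.6f}"
        return s

    if root.is_tip():
        # degenerate single-tip tree: written with an explicit zero branch
        return f"{root.label}:0.000000;"
    return rec(root) + ";"


# ---------------------------------------------------------------------------
# module-level convenience functions (thin wrappers over the classes)

def read_newick(text: str, timed: bool = True,
                rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> TimeTree | PhyloTree:
    """Parse one Newick tree; ``timed=True`` yields a TimeTree with ages."""
    if timed:
        return TimeTree.from_newick(text, rtol=rtol)
    return PhyloTree.from_newick(text)


def write_newick(tree: TimeTree | PhyloTree) -> str:
    return tree.to_newick()


def pendant_lengths(tree: TimeTree) -> dict[str, float]:
    return tree.pendant_lengths()


def crown_age(tree: TimeTree) -> float:
    return tree.crown_age


def mrca(tree: _TreeBase, taxa: Iterable[str]) -> Node:
    return tree.mrca(taxa)


def prune_tips(tree: TimeTree, tips: Iterable[str]) -> TimeTree:
    return tree.prune(tips)


def find_sister(tree: _TreeBase, tip: str) -> Node | list[Node]:
    return tree.find_sister(tip)


def trees_equal(a: TimeTree, b: TimeTree, age_tol: float = 1e-9) -> bool:
    """Same tip set, same topology (clade sets), ages within ``age_tol``."""
    if a.tip_labels != b.tip_labels:
        return False
    ca, cb = a.clades(), b.clades()
    if set(ca) != set(cb):
        return False
    return all(abs(ca[k] - cb[k]) <= age_tol for k in ca)
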