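"""Secondary-calibration dating and the sequence-to-tree helpers.

An untimed phylogeny (branch lengths in substitutions/site) is converted
to a chronogram in two steps: node *relative depths* are estimated by
mean path lengths (each node's height is the mean of its root-to-tip
path lengths through that node, normalised by the tree height), and a
global time scale is then fitted from one or more uniform secondary
calibrations — divergence-time ranges lifted from reference timetrees
and summarised by their midpoints. In the strict-clock limit the mean
path length equals the true node height, so dating with the true root
range recovers every node age exactly.

The sequence prong is deliberately minimal: a coverage filter that
removes alignment columns with less than a given fraction of resolved
bases, Jukes-Cantor distances on pairwise-complete sites, and a
neighbor-joining topology (via scikit-bio) rooted at a declared
outgroup. These feed the same calibration machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import Alignment
from .treeio import Node, PhyloTree, TimeTree, TreeError

__all__ = [
    "CalibrationConstraint",
    "relative_depths",
    "calibrate",
    "filter_coverage",
    "jc_distance",
    "nj_tree",
    "load_calibrations",
    "SaturationError",
]


class SaturationError(TreeError):
    """Sequences too diverged for a finite Jukes-Cantor distance."""


@dataclass(frozen=True)
class CalibrationConstraint:
    """A uniform age range (myr) on the MRCA of a taxon pair."""

    taxa: tuple[str, str]
    min_age: float
    max_age: float

    def __post_init__(self):
        if not 0 <= self.min_age < self.max_age:
            raise ValueError("need 0 <= min_age < max_age")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min_age + self.max_age)


def relative_depths(tree: PhyloTree) -> dict[int, float]:
    """Relative node depths in [0, 1], keyed by ``id(node)``.

    A node's height is the mean path length to its descendant tips; the
    root maps to 1 and tips to 0. Heights are made monotone along every
    root-to-tip path by raising each parent to at least its tallest
    child (plus a vanishing offset, so later time-scaling cannot create
    zero-length branches).
    """
    heights: dict[int, float] = {}
    counts: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip():
            heights[id(node)] = 0.0
            counts[id(node)] = 1
        else:
            n = 0
            acc = 0.0
            for c in node.children:
                n += counts[id(c)]
                acc += counts[id(c)] * (heights[id(c)] + c.length)
            counts[id(node)] = n
            heights[id(node)] = acc / n
    total = heights[id(tree.root)]
    if total <= 0:
        raise TreeError("zero-height tree; cannot compute relative depths")
    # parent-max adjustment
    for node in tree.postorder():
        if not node.is_tip():
            tallest = max(heights[id(c)] for c in node.children)
            if heights[id(node)] <= tallest:
                heights[id(node)] = tallest + 1e-12 * total
    total = heights[id(tree.root)]
    return {k: h / total for k, h in heights.items()}


def calibrate(tree: PhyloTree, constraints: list[CalibrationConstraint]
              ) -> TimeTree:
    """Scale relative depths to absolute time using uniform calibrations.

    One constraint: the calibrated node's age is set to the range
    midpoint and all other nodes scale proportionally. Several
    constraints: the scale is the least-squares fit of
    ``depth x scale ~ midpoint`` over the constrained nodes; any
    calibrated node still outside its range is clamped to the nearest
    bound, with its descendants rescaled proportionally (and ancestors
    raised minimally if needed). The output is ultrametric by
    construction.
    """
    if not constraints:
        raise TreeError("at least one calibration constraint is required")
    depths = relative_depths(tree)

    targets: dict[int, tuple[Node, CalibrationConstraint]] = {}
    for con in constraints:
        node = tree.mrca(con.taxa)
        if node.is_tip():
            raise TreeError(f"calibration taxa {con.taxa} resolve to a tip")
        if id(node) in targets:
            prev = targets[id(node)][1]
            if con.min_age > prev.max_age or con.max_age < prev.min_age:
                raise TreeError(
                    f"disjoint calibrations on one node: "
                    f"[{prev.min_age}, {prev.max_age}] vs "
                    f"[{con.min_age}, {con.max_age}]")
            con = CalibrationConstraint(
                con.taxa, max(con.min_age, prev.min_age),
                min(con.max_age, prev.max_age))
        targets[id(node)] = (node, con)

    d = np.array([depths[i] for i in targets])
    m = np.array([con.midpoint for _, con in targets.values()])
    scale = float(np.dot(d, m) / np.dot(d, d))

    ages = {i: depths[i] * scale for i in depths}
    # clamp calibrated nodes into their ranges, rescaling their subtrees
    for i, (node, con) in targets.items():
        clamped = min(max(ages[i], con.min_age), con.max_age)
        if clamped != ages[i]:
            factor = clamped / ages[i]
            for desc in node.preorder():
                ages[id(desc)] *= factor
    # rebuild the chronogram, raising any parent a clamp left too young
    out_root = _build_timed(tree.root, ages)
    tree_height = ages[id(tree.root)]
    for node in out_root.postorder():
        if node.is_tip():
            node.age = 0.0
        else:
            tallest = max(c.age for c in node.children)
            if node.age <= tallest:
                node.age = tallest + 1e-9 * tree_height
    timed = TimeTree(out_root)
    for i, (node, con) in targets.items():
        age = ages[i]
        if not (con.min_age - 1e-9 <= age <= con.max_age + 1e-9):
            raise TreeError(
                f"calibrated node age {age:.6g} escaped its range "
                f"[{con.min_age}, {con.max_age}]; constraints conflict")
    return timed


def _build_timed(src: Node, ages: dict[int, float]) -> Node:
    new = Node(src.label, age=ages[id(src)])
    for c in src.children:
        new.add_child(_build_timed(c, ages))
    return new


def load_calibrations(path_or_buf) -> list[CalibrationConstraint]:
    """Read a tab-delimited table: taxon_a, taxon_b, min_myr, max_myr."""
    df = pd.read_csv(path_or_buf, sep="\t")
    needed = {"taxon_a", "taxon_b", "min_myr", "max_myr"}
    if not needed <= set(df.columns):
        raise ValueError(f"calibration table lacks columns: "
                         f"{sorted(needed - set(df.columns))}")
    return [CalibrationConstraint((r.taxon_a, r.taxon_b),
                                  float(r.min_myr), float(r.max_myr))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# alignment handling

_RESOLVED = frozenset("ACGT")


def filter_coverage(aln: Alignment, threshold: float = 0.5) -> Alignment:
    """Drop columns whose fraction of resolved bases falls below threshold.

    Gaps and Ns do not count as coverage; column order is preserved.
    """
    if aln.n_sites == 0:
        raise TreeError("empty alignment")
    matrix = np.array([list(s) for s in aln.sequences])
    coverage = np.isin(matrix, list(_RESOLVED)).mean(axis=0)
    keep = coverage >= threshold
    if not keep.any():
        raise TreeError(
            f"coverage filter at threshold {threshold} removed every column")
    kept = matrix[:, keep]
    return Alignment(list(aln.taxa), ["".join(row) for row in kept])


def jc_distance(aln: Alignment):
    """Jukes-Cantor distances on pairwise-complete sites.

    d = -(3/4) ln(1 - 4p/3) where p is the mismatch proportion over
    sites where both sequences carry a resolved base. Returns a
    scikit-bio DistanceMatrix.
    """
    from skbio import DistanceMatrix

    matrix = np.array([list(s) for s in aln.sequences])
    resolved = np.isin(matrix, list(_RESOLVED))
    n = len(aln.taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = resolved[i] & resolved[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                raise SaturationError(
                    f"no pairwise-complete sites between {aln.taxa[i]!r} "
                    f"and {aln.taxa[j]!r}")
            p = float((matrix[i, both] != matrix[j, both]).mean())
            if p >= 0.75:
                raise SaturationError(
                    f"proportion of differing sites {p:.3f} between "
                    f"{aln.taxa[i]!r} and {aln.taxa[j]!r} is saturated "
                    "(>= 0.75); Jukes-Cantor distance undefined")
            dist[i, j] = dist[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(dist, ids=list(aln.taxa))


def nj_tree(dist, outgroup: str | None = None) -> PhyloTree:
    """Neighbor-joining topology from a distance matrix.

    Negative NJ branch lengths are clamped to zero with the deficit
    transferred to the adjacent (child) branches, preserving path
    lengths through the node. If ``outgroup`` is given the tree is
    rooted on the outgroup's terminal branch (at its midpoint).
    """
    from skbio.tree import nj as skbio_nj

    sk = skbio_nj(dist, neg_as_zero=False)
    if outgroup is not None:
        if outgroup not in set(dist.ids):
            raise TreeError(f"outgroup {outgroup!r} not in distance matrix")
        out_node = next(t for t in sk.tips() if t.name == outgroup)
        sk = sk.root_at(out_node, above=True, reset=True)

    def convert(sknode) -> Node:
        node = Node(label=sknode.name if sknode.is_tip() else None,
                    length=float(sknode.length or 0.0))
        for c in sknode.children:
            node.add_child(convert(c))
        return node

    root = convert(sk)
    _fix_negative_branches(root)
    return PhyloTree(root)


def _fix_negative_branches(root: Node) -> None:
    for node in root.preorder():
        if node.parent is not None and node.length < 0:
            deficit = -node.length
            node.length = 0.0
            for c in node.children:
                c.length += deficit
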