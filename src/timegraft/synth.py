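"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the kinds of inputs an expanded-timetree build
consumes: ultrametric birth-death chronograms (the backbone), prune/
re-graft scenarios with recorded sister species and pendant lengths (the
grafting evidence one reads off published timetrees), rate-varying
substitution trees whose true chronogram is known (the secondary-
calibration prong), and toy Jukes-Cantor alignments with missing data
(the sequence prong). Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assembly import GraftInstruction, SISTER
from .treeio import Node, PhyloTree, TimeTree, TreeError

__all__ = [
    "BDParams",
    "GraftScenario",
    "simulate_bd_tree",
    "make_graft_scenario",
    "apply_rate_variation",
    "simulate_alignment",
    "Alignment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class BDParams:
    """Constant-rate birth-death settings (rates per lineage per myr)."""

    lam: float
    mu: float
    n_tips: int
    seed: int = 0

    def __post_init__(self):
        if not (self.lam > self.mu >= 0):
            raise ValueError("need lambda > mu >= 0")
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")


@dataclass
class GraftScenario:
    """Ground truth, a pruned backbone, and the instructions to undo it."""

    truth: TimeTree
    backbone: TimeTree
    instructions: list[GraftInstruction] = field(default_factory=list)


def simulate_bd_tree(params: BDParams, max_attempts: int = 10_000) -> TimeTree:
    """Simulate an ultrametric birth-death tree with exactly n extant tips.

    Forward simulation from two crown lineages; a run in which the clade
    dies out is rejected and restarted. The present is placed uniformly
    within the waiting interval after the lineage count first reaches
    ``n_tips``, and extinct lineages are pruned from the returned tree.
    """
    rng = np.random.default_rng(params.seed)
    lam, mu, n = params.lam, params.mu, params.n_tips
    total_rate = lam + mu

    for _ in range(max_attempts):
        root = Node()
        active: list[Node] = [root.add_child(Node()), root.add_child(Node())]
        birth_time = {id(root): 0.0}
        t = 0.0
        failed = False
        while len(active) < n:
            if not active:
                failed = True
                break
            t += rng.exponential(1.0 / (len(active) * total_rate))
            lineage = active[rng.integers(len(active))]
            if rng.random() < lam / total_rate:
                birth_time[id(lineage)] = t
                active.remove(lineage)
                active.append(lineage.add_child(Node()))
                active.append(lineage.add_child(Node()))
            else:
                active.remove(lineage)   # extinction; leaves a dead tip
        if failed:
            continue
        # present: uniform within the interval before the next event
        present = t + rng.random() * rng.exponential(
            1.0 / (len(active) * total_rate))
        survivors = set(id(x) for x in active)

        pruned = _prune_dead(root, survivors)
        if pruned is None or pruned.is_tip():
            continue
        pruned.parent = None
        # assign ages; label extant tips deterministically left-to-right
        idx = 0
        for node in pruned.postorder():
            if node.is_tip():
                node.age = 0.0
                node.label = f"T{idx:04d}"
                idx += 1
            else:
                node.age = present - birth_time[id(node)]
        tree = TimeTree(pruned)
        if tree.n_tips == n:
            return tree
    raise TreeError(
        f"birth-death simulation failed to reach {n} surviving tips "
        f"in {max_attempts} attempts (mu may be too close to lambda)")


def _prune_dead(node: Node, survivors: set[int]) -> Node | None:
    """Drop extinct tips, suppressing unifurcations (identity preserved)."""
    if node.is_tip():
        return node if id(node) in survivors else None
    kept = [k for c in node.children
            if (k := _prune_dead(c, survivors)) is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    for k in kept:
        k.parent = node
    return node


def make_graft_scenario(tree: TimeTree, k: int, conflict_fraction: float = 0.0,
                        seed: int = 0) -> GraftScenario:
    """Prune ``k`` random tips and record how to graft them back.

    Tips are pruned sequentially; each instruction records the species'
    sister tip and pendant length measured in the tree just before its
    removal (the closest relative within its sister clade, preferring
    tips that survive into the backbone), and the instruction list is
    emitted in reverse pruning order. With ``conflict_fraction = 0``
    applying the instructions to the backbone reconstructs the original
    tree exactly. A ``conflict_fraction`` of the instructions instead
    request a pendant length 1.5x the anchor's backbone pendant length,
    guaranteeing the polytomy-avoidance offset rule fires.
    """
    if not 0 <= conflict_fraction <= 1:
        raise ValueError("conflict_fraction must be in [0, 1]")
    if k > tree.n_tips - 3:
        raise TreeError(f"cannot prune {k} of {tree.n_tips} tips; "
                        "at least 3 must remain")
    rng = np.random.default_rng(seed)
    work = tree.copy()
    instructions: list[GraftInstruction] = []
    while len(instructions) < k:
        # only a tip currently in a cherry can be re-grafted exactly:
        # its attachment point is then on the sister's terminal branch
        cherry_tips = sorted(
            t.label for t in work.tips()
            if t.parent is not None and len(t.parent.children) == 2
            and all(c.is_tip() for c in t.parent.children))
        if not cherry_tips:   # pragma: no cover - binary trees have cherries
            raise TreeError("no cherry tips left to prune")
        label = cherry_tips[int(rng.integers(len(cherry_tips)))]
        node = work.find(label)
        anchor = next(c.label for c in node.parent.children if c is not node)
        instructions.append(GraftInstruction(
            species=label, mode=SISTER, anchor=anchor,
            pl=node.parent.age, source="synthetic truth"))
        work = work.prune([label])
    instructions.reverse()

    backbone = work
    if conflict_fraction > 0 and instructions:
        backbone_pl = backbone.pendant_lengths()
        eligible = [i for i, ins in enumerate(instructions)
                    if ins.anchor in backbone_pl]
        n_conflict = math.ceil(conflict_fraction * len(instructions))
        chosen = rng.choice(len(eligible), size=min(n_conflict, len(eligible)),
                            replace=False)
        for j in sorted(int(c) for c in chosen):
            i = eligible[j]
            ins = instructions[i]
            instructions[i] = GraftInstruction(
                species=ins.species, mode=ins.mode, anchor=ins.anchor,
                pl=backbone_pl[ins.anchor] * 1.5,
                source="synthetic conflict")
    return GraftScenario(truth=tree.copy(), backbone=backbone,
                         instructions=instructions)


def apply_rate_variation(tree: TimeTree, sigma: float, seed: int = 0
                         ) -> PhyloTree:
    """Relax the clock: branch length = duration x lognormal rate.

    Per-branch rates are i.i.d. lognormal with mean 1 (``sigma`` is the
    log-scale standard deviation); ``sigma = 0`` gives a strict clock in
    which branch lengths equal branch durations.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    root = tree.root.copy()
    out = PhyloTree(root, validate=False)
    for node in root.preorder():
        if node.parent is None:
            node.length = 0.0
            continue
        duration = node.parent.age - node.age
        rate = 1.0 if sigma == 0 else float(
            rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
        node.length = duration * rate
    return out


# ---------------------------------------------------------------------------
# sequence simulation

@dataclass
class Alignment:
    """A rectangular multiple-sequence alignment over {A,C,G,T,-,N}."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{s}\n"
                       for t, s in zip(self.taxa, self.sequences))

    @classmethod
    def from_fasta(cls, text: str) -> "Alignment":
        from Bio import SeqIO
        import io as _io
        taxa, seqs = [], []
        for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if len(taxa) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        return cls(taxa, seqs)


def simulate_alignment(tree: PhyloTree, length: int,
                       missing_fraction: float = 0.0, seed: int = 0
                       ) -> Alignment:
    """Evolve sites under Jukes-Cantor along the tree.

    Each branch of length ``b`` substitutions/site applies the JC
    transition (stay probability 1/4 + 3/4 e^{-4b/3}); afterwards a
    ``missing_fraction`` of cells is replaced by gap symbols.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    states: dict[int, np.ndarray] = {
        id(tree.root): rng.integers(0, 4, size=length)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = states[id(node.parent)]
        p_change = 0.75 * (1.0 - math.exp(-4.0 * node.length / 3.0))
        flip = rng.random(length) < p_change
        shift = rng.integers(1, 4, size=length)   # move to a different base
        child = parent_state.copy()
        child[flip] = (child[flip] + shift[flip]) % 4
        states[id(node)] = child

    taxa = sorted(tree.tip_labels)
    matrix = np.stack([states[id(tree.find(t))] for t in taxa])
    chars = _BASES[matrix].astype("U1")
    if missing_fraction > 0:
        gaps = rng.random(chars.shape) < missing_fraction
        chars[gaps] = "-"
    return Alignment(taxa, ["".join(row) for row in chars])
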