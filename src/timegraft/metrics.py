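"""Audit statistics for chronograms: evolutionary isolation and congruence.

* :func:`equal_splits` computes the equal-splits statistic of
  evolutionary isolation (EI): each branch's length is apportioned
  equally down both daughter lineages at every split, so a tip's EI is
  the sum over its root path of branch length / 2^(splits passed after
  that branch). Over the tips of a binary tree the statistic exactly
  partitions the total branch length. Dividing by the crown age makes EI
  comparable between trees dated on different time scales.
* :func:`shared_node_ages` and :func:`compare_pendant_lengths` quantify
  congruence between two chronograms by ordinary least squares over
  matched node ages / matched tip pendant lengths, the standard visual
  check when validating a merged timetree against its sources.
* :func:`ei_distribution_summary` contrasts two normalized-EI
  distributions by deciles and, where tip sets overlap, paired
  differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import TimeTree, TreeError

__all__ = [
    "EIReport",
    "RegressionResult",
    "equal_splits",
    "shared_node_ages",
    "compare_pendant_lengths",
    "ei_distribution_summary",
    "summarize_tree",
]


@dataclass
class EIReport:
    """Per-tip equal-splits evolutionary isolation, in myr."""

    ei: dict[str, float]
    crown: float

    @property
    def normalized(self) -> dict[str, float]:
        """EI divided by the tree's crown age (dimensionless)."""
        return {k: v / self.crown for k, v in self.ei.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.ei),
             "ei_myr": list(self.ei.values()),
             "ei_normalized": [v / self.crown for v in self.ei.values()]}
        ).sort_values("ei_myr", ascending=False, ignore_index=True)


@dataclass
class RegressionResult:
    """Matched values from two trees with an OLS fit of y on x.

    Axis order between two chronogram renderings is a convention, so the
    reverse fit (x on y) is also carried.
    """

    pairs: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    slope_reverse: float = field(default=float("nan"))
    intercept_reverse: float = field(default=float("nan"))

    @property
    def n(self) -> int:
        return len(self.pairs)


def _regress(pairs: list[tuple[float, float]]) -> RegressionResult:
    if len(pairs) < 3:
        raise TreeError(f"need at least 3 matched values, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TreeError("matched values are constant; regression undefined")
    fwd = stats.linregress(x, y)
    rev = stats.linregress(y, x)
    return RegressionResult(
        pairs=pairs, slope=float(fwd.slope), intercept=float(fwd.intercept),
        r_squared=float(fwd.rvalue ** 2),
        slope_reverse=float(rev.slope), intercept_reverse=float(rev.intercept))


def equal_splits(tree: TimeTree) -> EIReport:
    """Equal-splits evolutionary isolation for every tip, in myr."""
    for node in tree.internal_nodes():
        if len(node.children) != 2:
            raise TreeError(
                f"equal splits requires a binary tree; node with "
                f"{len(node.children)} children over tips "
                f"{sorted(node.tip_label_set)[:4]}...")
    ei: dict[str, float] = {}

    def descend(node, acc: float) -> None:
        if node.parent is not None:
            acc += node.parent.age - node.age
        if node.is_tip():
            ei[node.label] = acc
        else:
            for c in node.children:
                descend(c, acc / 2.0)

    descend(tree.root, 0.0)
    return EIReport(ei=ei, crown=tree.crown_age)


def shared_node_ages(tree_a: TimeTree, tree_b: TimeTree) -> RegressionResult:
    """OLS over ages of nodes shared by both trees.

    A node is shared when its clade, restricted to the common taxon set,
    occurs in both trees; each side contributes the MRCA age of that
    restricted taxon set.
    """
    common = tree_a.tip_labels & tree_b.tip_labels
    if len(common) < 3:
        raise TreeError(f"trees share only {len(common)} taxa")
    ca = tree_a.clades(restrict=common)
    cb = tree_b.clades(restrict=common)
    keys = sorted(set(ca) & set(cb), key=sorted)
    return _regress([(ca[k], cb[k]) for k in keys])


def compare_pendant_lengths(tree_a: TimeTree, tree_b: TimeTree,
                            scale_by_crown: bool = False) -> RegressionResult:
    """OLS over pendant lengths of shared tips.

    With ``scale_by_crown`` each tree's pendant lengths are divided by
    its own crown age first, removing overall time-scale differences.
    """
    common = sorted(tree_a.tip_labels & tree_b.tip_labels)
    if len(common) < 3:
        raise TreeError(f"trees share only {len(common)} tips")
    pa, pb = tree_a.pendant_lengths(), tree_b.pendant_lengths()
    sa = tree_a.crown_age if scale_by_crown else 1.0
    sb = tree_b.crown_age if scale_by_crown else 1.0
    return _regress([(pa[t] / sa, pb[t] / sb) for t in common])


def ei_distribution_summary(report_a: EIReport, report_b: EIReport
                            ) -> pd.DataFrame:
    """Decile-by-decile contrast of two normalized-EI distributions.

    Returns the deciles of each distribution and their difference
    (b - a); when the reports share tips, per-tip paired differences of
    normalized EI are attached as a DataFrame attribute ``paired``.
    """
    qs = np.arange(0.1, 1.0, 0.1)
    na = np.array(list(report_a.normalized.values()))
    nb = np.array(list(report_b.normalized.values()))
    if na.size == 0 or nb.size == 0:
        raise TreeError("empty EI report")
    da = np.quantile(na, qs)
    db = np.quantile(nb, qs)
    out = pd.DataFrame({"quantile": np.round(qs, 1), "a": da, "b": db,
                        "difference": db - da})
    shared = set(report_a.ei) & set(report_b.ei)
    norm_a, norm_b = report_a.normalized, report_b.normalized
    out.attrs["paired"] = pd.DataFrame(
        {"species": sorted(shared),
         "difference": [norm_b[t] - norm_a[t] for t in sorted(shared)]})
    return out


def summarize_tree(tree: TimeTree, focal_tips: tuple[str, ...] = (),
                   genera: tuple[str, ...] = ()) -> dict:
    """Headline audit numbers for a chronogram.

    Tip count, crown age (myr), EI for named focal tips and mean EI for
    named genera (genus = first underscore-delimited token of the tip
    label) — the quantities one quotes when validating an assembled
    timetree against its publication of record.
    """
    report = equal_splits(tree)
    out: dict = {"n_tips": tree.n_tips, "crown_age_myr": tree.crown_age}
    for tip in focal_tips:
        if tip not in report.ei:
            raise TreeError(f"focal tip {tip!r} not in tree")
        out[f"ei_myr[{tip}]"] = report.ei[tip]
    for genus in genera:
        members = [v for k, v in report.ei.items()
                   if k.split("_", 1)[0] == genus]
        if not members:
            raise TreeError(f"genus {genus!r} not in tree")
        out[f"mean_ei_myr[{genus}]"] = float(np.mean(members))
    return out
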