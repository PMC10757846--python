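"""Equal-splits isolation and chronogram-congruence regressions."""

import shutil
import subprocess

import numpy as np
import pytest

import timegraft as tg
from timegraft import metrics
from timegraft.treeio import TreeError


def brute_force_equal_splits(tree: tg.TimeTree) -> dict[str, float]:
    """Independent oracle: explicit root-path enumeration per tip.

    Each edge on the tip's root path contributes its length divided by
    2^s, where s counts the splits passed between that edge's lower end
    and the tip.
    """
    out = {}
    for tip in tree.tips():
        total = 0.0
        path = tree.path_to_root(tip)            # tip ... root
        for k, node in enumerate(path[:-1]):     # node has the edge above it
            edge = node.parent.age - node.age
            splits_below = k                     # internal nodes passed
            total += edge / (2.0 ** splits_below)
        out[tip.label] = total
    return out


class TestEqualSplits:
    def test_worked_example(self, basic_tree):
        report = tg.equal_splits(basic_tree)
        assert report.ei == {"A": 1.5, "B": 1.5, "C": 2.0}
        assert sum(report.ei.values()) == pytest.approx(
            basic_tree.total_branch_length)

    def test_two_tip_symmetry(self):
        report = tg.equal_splits(tg.read_newick("(A:3,B:3);"))
        assert report.ei == {"A": 3.0, "B": 3.0}

    def test_normalized_by_crown_age(self, basic_tree):
        report = tg.equal_splits(basic_tree)
        assert report.normalized["C"] == pytest.approx(1.0)

    def test_polytomy_rejected(self):
        with pytest.raises(TreeError, match="binary"):
            tg.equal_splits(tg.read_newick("(A:2,B:2,C:2);"))

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_bruteforce_and_conserves_length(self, seed):
        rng = np.random.default_rng(seed)
        tree = tg.simulate_bd_tree(
            tg.BDParams(0.4, 0.1, int(rng.integers(4, 9)), seed=seed))
        report = tg.equal_splits(tree)
        oracle = brute_force_equal_splits(tree)
        for label, value in oracle.items():
            assert report.ei[label] == pytest.approx(value, abs=1e-9)
        assert sum(report.ei.values()) == pytest.approx(
            tree.total_branch_length, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_ei_at_least_pendant_length(self, seed):
        tree = tg.simulate_bd_tree(tg.BDParams(0.3, 0.05, 50, seed=seed))
        report = tg.equal_splits(tree)
        pls = tree.pendant_lengths()
        for label, value in report.ei.items():
            assert value >= pls[label] - 1e-12

    def test_cherry_under_root_attains_equality(self):
        # a cherry tip whose sister is a tip and whose grandparent is the
        # root: EI = PL + half the stem, equality only if the stem is 0
        report = tg.equal_splits(tg.read_newick("(A:3,B:3);"))
        pls = tg.read_newick("(A:3,B:3);").pendant_lengths()
        assert report.ei["A"] == pls["A"]

    def test_matches_picante_reference_implementation(self, tmp_path):
        """Cross-check against R picante's equal-splits ED on one tree."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript not on PATH")
        tree = tg.simulate_bd_tree(tg.BDParams(0.3, 0.1, 25, seed=13))
        newick = tmp_path / "tree.nwk"
        newick.write_text(tree.to_newick() + "\n")
        script = tmp_path / "es.R"
        script.write_text(
            'suppressMessages(library(picante))\n'
            f'tr <- read.tree("{newick}")\n'
            'es <- evol.distinct(tr, type="equal.splits")\n'
            'write.csv(es, stdout(), row.names=FALSE)\n')
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        reference = {}
        for line in res.stdout.strip().splitlines()[1:]:
            name, value = line.replace('"', "").split(",")
            reference[name] = float(value)
        ours = tg.equal_splits(tree).ei
        assert set(reference) == set(ours)
        for label in ours:
            assert ours[label] == pytest.approx(reference[label], abs=1e-6)


class TestSharedNodeAges:
    def test_tree_against_itself(self, yule_tree):
        result = tg.shared_node_ages(yule_tree, yule_tree)
        assert result.slope == pytest.approx(1.0)
        assert result.intercept == pytest.approx(0.0, abs=1e-9)
        assert result.r_squared == pytest.approx(1.0)

    def test_doubled_ages_double_the_slope(self, yule_tree):
        doubled = yule_tree.copy()
        for node in doubled.postorder():
            node.age *= 2.0
        result = tg.shared_node_ages(yule_tree, doubled)
        assert result.slope == pytest.approx(2.0)
        assert result.r_squared == pytest.approx(1.0)
        assert result.slope_reverse == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_age_jitter_keeps_slope_near_one(self, seed):
        tree = tg.simulate_bd_tree(tg.BDParams(0.25, 0.0, 60, seed=seed))
        jittered = tree.copy()
        rng = np.random.default_rng(seed)
        for node in jittered.postorder():
            if not node.is_tip():
                node.age *= float(1 + 0.05 * rng.standard_normal())
        # repair any inversion the jitter introduced
        for node in jittered.postorder():
            if not node.is_tip():
                top = max(c.age for c in node.children)
                if node.age <= top:
                    node.age = top * (1 + 1e-6)
        result = tg.shared_node_ages(tree, jittered)
        assert 0.9 <= result.slope <= 1.1

    def test_too_few_shared_nodes_rejected(self, basic_tree):
        other = tg.read_newick("((A:1,X:1):1,Y:2);")
        with pytest.raises(TreeError):
            tg.shared_node_ages(basic_tree, other)


class TestComparePendantLengths:
    def test_tree_against_itself(self, yule_tree):
        result = tg.compare_pendant_lengths(yule_tree, yule_tree)
        assert result.r_squared == pytest.approx(1.0)

    def test_crown_scaling_removes_global_rescaling(self, yule_tree):
        doubled = yule_tree.copy()
        for node in doubled.postorder():
            node.age *= 2.0
        result = tg.compare_pendant_lengths(yule_tree, doubled,
                                            scale_by_crown=True)
        assert result.slope == pytest.approx(1.0)
        assert result.r_squared == pytest.approx(1.0)
        for x, y in result.pairs:
            assert x == pytest.approx(y, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_pendant_lengths_uncorrelated(self, seed):
        tree = tg.simulate_bd_tree(tg.BDParams(0.25, 0.0, 80, seed=seed))
        rng = np.random.default_rng(1000 + seed)
        shuffled = tree.copy()
        # replace pendant structure with an independent draw by permuting
        # tip labels, decoupling each label's pendant length from tree_a
        labels = [t.label for t in shuffled.tips()]
        permuted = list(rng.permutation(labels))
        for tip, new in zip(shuffled.tips(), permuted):
            tip.label = new
        shuffled._reindex()
        result = tg.compare_pendant_lengths(tree, shuffled)
        assert result.r_squared < 0.3   # single-seed guard; mean tested below

    def test_mean_null_r_squared_below_point_one(self):
        values = []
        for seed in range(10):
            tree = tg.simulate_bd_tree(tg.BDParams(0.25, 0.0, 80, seed=seed))
            rng = np.random.default_rng(2000 + seed)
            shuffled = tree.copy()
            labels = [t.label for t in shuffled.tips()]
            for tip, new in zip(shuffled.tips(), rng.permutation(labels)):
                tip.label = new
            shuffled._reindex()
            values.append(tg.compare_pendant_lengths(tree, shuffled).r_squared)
        assert float(np.mean(values)) < 0.1


class TestEIDistributionSummary:
    def test_report_against_itself_is_zero(self, yule_tree):
        report = tg.equal_splits(yule_tree)
        summary = tg.ei_distribution_summary(report, report)
        assert np.allclose(summary["difference"], 0.0)
        assert np.allclose(summary.attrs["paired"]["difference"], 0.0)

    def test_halved_ei_gives_half_differences(self, yule_tree):
        report = tg.equal_splits(yule_tree)
        halved = metrics.EIReport(
            ei={k: v / 2 for k, v in report.ei.items()}, crown=report.crown)
        summary = tg.ei_distribution_summary(report, halved)
        paired = summary.attrs["paired"]
        normalized = report.normalized
        for species, diff in zip(paired["species"], paired["difference"]):
            assert diff == pytest.approx(-normalized[species] / 2)

    def test_short_pendant_tree_scores_lower(self, yule_tree):
        """An imputation-style tree (shrunken pendants) has lower EI."""
        shrunk = yule_tree.copy()
        for node in shrunk.postorder():
            if not node.is_tip() and node.parent is not None:
                node.age *= 0.5
        for node in shrunk.postorder():   # re-establish monotonicity
            if not node.is_tip():
                top = max(c.age for c in node.children)
                if node.age <= top:
                    node.age = top * (1 + 1e-9)
        summary = tg.ei_distribution_summary(tg.equal_splits(yule_tree),
                                             tg.equal_splits(shrunk))
        assert np.median(summary.attrs["paired"]["difference"]) < 0


class TestSummarizeTree:
    def test_reports_tip_count_crown_and_focal_ei(self):
        """Audit summary on a synthetic stand-in for a published tree."""
        tree = tg.read_newick(
            "(((Homo_sapiens:6,Pan_troglodytes:6):24,"
            "((Macaca_mulatta:5,Macaca_fascicularis:5):3,"
            "Macaca_sylvanus:8):22):12,Ateles_paniscus:42);")
        out = metrics.summarize_tree(tree, focal_tips=("Homo_sapiens",),
                                     genera=("Macaca",))
        assert out["n_tips"] == 6
        assert out["crown_age_myr"] == pytest.approx(42.0)
        report = tg.equal_splits(tree)
        assert out["ei_myr[Homo_sapiens]"] == pytest.approx(
            report.ei["Homo_sapiens"])
        macaca = [v for k, v in report.ei.items() if k.startswith("Macaca")]
        assert out["mean_ei_myr[Macaca]"] == pytest.approx(np.mean(macaca))

    def test_unknown_focal_tip_rejected(self, basic_tree):
        with pytest.raises(TreeError):
            metrics.summarize_tree(basic_tree, focal_tips=("Zz",))
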