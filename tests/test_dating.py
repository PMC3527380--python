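import numpy as np
import pytest

from mtphylo.annotate import VariantCall
from mtphylo.dating import (CalibrationConfig, DatingError, count_path_changes,
                            date_named_clades, estimate_age, estimate_clade_age)
from mtphylo.tree import PhyloTree, TreeError, TreeNode


def syn(pos=5000):
    return VariantCall(pos, "A", "G", "transition", feature_class="protein",
                       coding_effect="synonymous")


def nonsyn(pos=6000):
    return VariantCall(pos, "A", "G", "transition", feature_class="protein",
                       coding_effect="nonsynonymous", aa_change=("thr", "ala"))


def rna(pos=1438):
    return VariantCall(pos, "A", "G", "transition", feature_class="rRNA",
                       coding_effect="rna")


def star_tree(per_leaf_mutations):
    root = TreeNode(name="root")
    for name, muts in per_leaf_mutations.items():
        leaf = root.add_child(TreeNode(name=name))
        leaf.mutations = list(muts)
    return PhyloTree(root, rooted=True)


class TestCalibration:
    def test_rho_of_one_maps_to_6760_years_exactly(self):
        cal = CalibrationConfig.kivisild()
        est = estimate_age({"a": 1, "b": 1, "c": 1}, cal)
        assert est.rho == 1.0
        assert est.age_years == 6760.0

    def test_zero_counts_degenerate_to_zero(self):
        cal = CalibrationConfig.kivisild()
        est = estimate_age([0, 0, 0, 0], cal)
        assert est.age_years == 0.0 and est.se_years == 0.0

    def test_age_linear_in_years_per_change(self):
        counts = [3, 1, 2]
        a = estimate_age(counts, CalibrationConfig("soares_complete", 1000.0))
        b = estimate_age(counts, CalibrationConfig("soares_complete", 2000.0))
        assert b.age_years == 2 * a.age_years
        assert b.se_years == 2 * a.se_years

    def test_invalid_calibrations_rejected(self):
        with pytest.raises(DatingError):
            CalibrationConfig("kivisild_synonymous", 0.0)
        with pytest.raises(DatingError):
            CalibrationConfig("x", 1.0, excluded_positions=frozenset({0}))


class TestCountPathChanges:
    def test_one_synonymous_change_per_leaf(self):
        tree = star_tree({"a": [syn()], "b": [syn(6100)], "c": [syn(7000)]})
        cal = CalibrationConfig.kivisild()
        assert count_path_changes(tree, tree.root, cal) == {"a": 1, "b": 1, "c": 1}

    def test_nonsynonymous_and_rna_do_not_count_for_synonymous_clock(self):
        tree = star_tree({"a": [syn(), nonsyn(), rna()], "b": [nonsyn()]})
        cal = CalibrationConfig.kivisild()
        assert count_path_changes(tree, tree.root, cal) == {"a": 1, "b": 0}

    def test_soares_excludes_hypervariable_positions(self):
        cal = CalibrationConfig.soares(3000.0)
        hyper = VariantCall(16519, "T", "C", "transition",
                            feature_class="control", coding_effect="noncoding")
        tree = star_tree({"a": [syn(), hyper], "b": [rna()]})
        counts = count_path_changes(tree, tree.root, cal)
        assert counts == {"a": 1, "b": 1}
        # removing the excluded change leaves counts identical
        tree2 = star_tree({"a": [syn()], "b": [rna()]})
        assert count_path_changes(tree2, tree2.root, cal) == counts

    def test_deletions_never_count(self):
        d = VariantCall(8281, "A", None, "deletion", feature_class="control",
                        coding_effect="na")
        tree = star_tree({"a": [d], "b": []})
        assert count_path_changes(tree, tree.root,
                                  CalibrationConfig.soares(3000.0)) == {"a": 0,
                                                                        "b": 0}

    def test_matches_independent_path_walk(self):
        # nested clade: counts accumulate along root->leaf paths
        root = TreeNode(name="root")
        inner = root.add_child(TreeNode(name="inner"))
        inner.mutations = [syn(100)]
        a = inner.add_child(TreeNode(name="a"))
        a.mutations = [syn(200), nonsyn()]
        b = inner.add_child(TreeNode(name="b"))
        c = root.add_child(TreeNode(name="c"))
        c.mutations = [syn(300), syn(400)]
        tree = PhyloTree(root, rooted=True)
        cal = CalibrationConfig.kivisild()
        got = count_path_changes(tree, tree.root, cal)

        def walk_to(leaf_name):  # independent: follow parents upward
            node = tree.find(leaf_name)
            total = 0
            while node.parent is not None:
                total += sum(1 for v in node.mutations if
                             v.coding_effect == "synonymous")
                node = node.parent
            return total

        assert got == {n: walk_to(n) for n in ("a", "b", "c")}

    def test_unannotated_mutations_rejected_for_synonymous_clock(self):
        bare = VariantCall(5000, "A", "G", "transition")
        tree = star_tree({"a": [bare], "b": []})
        with pytest.raises(DatingError, match="unannotated"):
            count_path_changes(tree, tree.root, CalibrationConfig.kivisild())


class TestCladeEstimates:
    def test_star_se_reduces_to_sqrt_rho_over_n(self):
        tree = star_tree({"a": [syn()], "b": [syn(), syn(5100)], "c": []})
        cal = CalibrationConfig.kivisild()
        est = estimate_clade_age(tree, tree.root, cal)
        assert est.rho == 1.0
        assert est.se_rho == pytest.approx(np.sqrt(est.rho / 3))

    def test_branch_weighted_se_on_structured_clade(self):
        # one shared mutation above two leaves: Saillard weight (n_below=2)
        root = TreeNode(name="root")
        inner = root.add_child(TreeNode(name="inner"))
        inner.mutations = [syn(100)]
        inner.add_child(TreeNode(name="a"))
        inner.add_child(TreeNode(name="b"))
        root.add_child(TreeNode(name="c"))
        tree = PhyloTree(root, rooted=True)
        est = estimate_clade_age(tree, tree.root, CalibrationConfig.kivisild())
        assert est.rho == pytest.approx(2 / 3)
        assert est.se_rho == pytest.approx(np.sqrt(2 ** 2 * 1) / 3)

    def test_nested_clade_independent_of_changes_above(self):
        root = TreeNode(name="root")
        stem = root.add_child(TreeNode(name="stem"))
        stem.mutations = [syn(100), syn(200)]
        a = stem.add_child(TreeNode(name="a"))
        a.mutations = [syn(300)]
        stem.add_child(TreeNode(name="b"))
        root.add_child(TreeNode(name="out"))
        tree = PhyloTree(root, rooted=True)
        cal = CalibrationConfig.kivisild()
        sub = estimate_clade_age(tree, tree.find("stem"), cal)
        assert sub.per_leaf_counts == {"a": 1, "b": 0}
        # stripping the stem's own mutations changes nothing below it
        tree.find("stem").mutations = []
        sub2 = estimate_clade_age(tree, tree.find("stem"), cal)
        assert sub2.per_leaf_counts == sub.per_leaf_counts

    def test_named_clades_and_monophyly_error(self):
        tree = PhyloTree.from_newick("((a,b),(c,d));", rooted=True)
        for node in tree.postorder():
            node.mutations = []
        tree.find("a").mutations = [syn()]
        cal = CalibrationConfig.kivisild()
        (est,) = date_named_clades(tree, {"AB": ["a", "b"]}, cal)
        assert est.clade == "AB" and est.n_leaves == 2
        with pytest.raises(TreeError, match="monophyletic"):
            date_named_clades(tree, {"bad": ["a", "c"]}, cal)

    def test_single_leaf_clade_uses_pendant_branch(self):
        tree = star_tree({"a": [syn(), syn(5100)], "b": []})
        cal = CalibrationConfig.kivisild()
        (est,) = date_named_clades(tree, {"solo": ["a"]}, cal)
        assert est.age_years == 2 * 6760.0

    def test_empty_clade_rejected(self):
        with pytest.raises(DatingError):
            estimate_age({}, CalibrationConfig.kivisild())


class TestParameterRecovery:
    def test_estimator_recovers_star_tmrca(self):
        """Poisson counts at the clock rate on a known-age star genealogy:
        near-nominal 2-se coverage and small bias (smaller version of the
        acceptance-scale experiment)."""
        rng = np.random.default_rng(20)
        cal = CalibrationConfig.kivisild()
        T = 22430.0
        n = 7
        covered = 0
        ages = []
        reps = 200
        for _ in range(reps):
            counts = rng.poisson(T / cal.years_per_change, size=n)
            est = estimate_age(counts.tolist(), cal)
            ages.append(est.age_years)
            if abs(est.age_years - T) <= 2 * est.se_years or est.se_years == 0:
                covered += 1
        assert covered / reps >= 0.9
        assert abs(np.mean(ages) - T) / T < 0.05
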