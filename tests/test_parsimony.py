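import numpy as np
import pytest

from mtphylo.alignment import Alignment, drop_gapped_columns, informative_sites
from mtphylo.parsimony import (ParsimonyError, SearchConfig, TreeSet,
                               enumerate_mp_trees, exhaustive_min_length,
                               fitch_length, heuristic_search, map_mutations,
                               strict_consensus)
from mtphylo.simulate import SimConfig, evolve_sequences, simulate_genealogy
from mtphylo.tree import PhyloTree, reroot_at_node

from conftest import random_alignment
from oracles import naive_parsimony_score, splits_bruteforce

import dendropy


def aln_from_rows(rows, taxa=None):
    mat = np.array([list(r.encode()) for r in rows], dtype=np.uint8).view("S1")
    return Alignment(
        taxa=taxa or [f"t{i}" for i in range(len(rows))],
        matrix=mat.reshape(len(rows), -1),
        column_positions=np.arange(1, len(rows[0]) + 1),
    )


class TestFitchLength:
    def test_identical_sequences_score_zero(self):
        aln = aln_from_rows(["ACGT"] * 5)
        ts = enumerate_mp_trees(aln)
        assert ts.score == 0
        assert fitch_length(ts.trees[0], aln) == 0

    def test_matches_naive_sankoff_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            aln = random_alignment(rng, 6, 12)
            ts = enumerate_mp_trees(aln)
            seqs = {t: aln.sequence_str(t) for t in aln.taxa}
            for tree in ts.trees[:3]:
                assert fitch_length(tree, aln) == naive_parsimony_score(tree, seqs)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 6, 20)
        ts = enumerate_mp_trees(aln)
        tree = ts.trees[0]
        for node in [n for n in tree.postorder() if not n.is_leaf]:
            assert fitch_length(reroot_at_node(tree, node), aln) == ts.score

    def test_invariant_under_leaf_order_permutation(self):
        rng = np.random.default_rng(4)
        aln = random_alignment(rng, 6, 20)
        ts = enumerate_mp_trees(aln)
        rows = rng.permutation(6)
        shuffled = Alignment(
            taxa=[aln.taxa[i] for i in rows], matrix=aln.matrix[rows],
            column_positions=aln.column_positions,
        )
        assert fitch_length(ts.trees[0], shuffled) == ts.score

    def test_lower_bound_from_state_counts(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            aln = random_alignment(rng, 7, 15)
            ts = enumerate_mp_trees(aln)
            counts = np.stack([(aln.matrix == b).sum(axis=0)
                               for b in np.frombuffer(b"ACGT", dtype="S1")], axis=1)
            bound = int(((counts > 0).sum(axis=1) - 1).sum())
            assert ts.score >= bound

    def test_every_informative_column_contributes(self):
        rng = np.random.default_rng(6)
        aln = random_alignment(rng, 6, 25)
        rep = informative_sites(aln)
        ts = enumerate_mp_trees(aln)
        assert ts.score >= rep.n_informative

    def test_taxon_mismatch_rejected(self):
        aln = aln_from_rows(["ACGT"] * 4)
        other = aln_from_rows(["ACGT"] * 4, taxa=list("wxyz"))
        ts = enumerate_mp_trees(aln)
        with pytest.raises(ParsimonyError):
            fitch_length(ts.trees[0], other)

    def test_multifurcation_never_scores_below_binary_resolution(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, 6, 20)
        ts = enumerate_mp_trees(aln)
        star_cons = strict_consensus(TreeSet(trees=list(ts.trees), score=ts.score))
        assert fitch_length(star_cons, aln) >= ts.score


class TestEnumeration:
    def test_three_taxa_single_topology(self):
        aln = aln_from_rows(["AC", "AG", "CG"])
        ts = enumerate_mp_trees(aln)
        assert len(ts) == 1

    def test_single_split_forces_topology(self):
        # one informative site splitting {t0,t1} | {t2,t3}
        aln = aln_from_rows(["A", "A", "C", "C"])
        ts = enumerate_mp_trees(aln)
        assert ts.score == 1 and len(ts) == 1
        assert frozenset(["t2", "t3"]) in ts.trees[0].splits()

    def test_score_agrees_with_fitch_on_each_winner(self):
        rng = np.random.default_rng(8)
        aln = random_alignment(rng, 7, 18)
        ts = enumerate_mp_trees(aln)
        assert all(fitch_length(t, aln) == ts.score for t in ts.trees)

    def test_refuses_large_taxon_sets(self):
        aln = aln_from_rows(["ACGT"] * 12)
        with pytest.raises(ParsimonyError, match="heuristic_search"):
            enumerate_mp_trees(aln)


class TestHeuristicSearch:
    def test_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(9)
        for i in range(25):
            n = int(rng.integers(5, 8))
            aln = random_alignment(rng, n, 20, n_states=int(rng.integers(2, 5)))
            assert heuristic_search(aln).score == exhaustive_min_length(aln)[0]

    def test_identical_sequences_score_zero(self):
        aln = aln_from_rows(["ACGTACGT"] * 6)
        assert heuristic_search(aln).score == 0

    def test_deterministic_for_fixed_config(self):
        rng = np.random.default_rng(10)
        aln = random_alignment(rng, 8, 25)
        a = heuristic_search(aln)
        b = heuristic_search(aln)
        assert a.score == b.score
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]

    def test_random_restarts_never_worsen(self):
        rng = np.random.default_rng(11)
        aln = random_alignment(rng, 8, 25)
        base = heuristic_search(aln)
        restarted = heuristic_search(aln, SearchConfig(random_restarts=2, seed=1))
        assert restarted.score <= base.score


class TestStrictConsensus:
    def test_single_tree_is_identity(self):
        rng = np.random.default_rng(12)
        aln = random_alignment(rng, 6, 30)
        ts = enumerate_mp_trees(aln)
        one = TreeSet(trees=[ts.trees[0]], score=ts.score)
        assert strict_consensus(one).splits() == ts.trees[0].splits()

    def test_conflicting_edge_collapses(self):
        t1 = PhyloTree.from_newick("((a,b),(c,(d,e)));", rooted=False)
        t2 = PhyloTree.from_newick("((a,b),(d,(c,e)));", rooted=False)
        cons = strict_consensus(TreeSet(trees=[t1, t2], score=0))
        expected = t1.splits() & t2.splits()
        assert cons.splits() == expected
        assert frozenset(["c", "d", "e"]) in cons.splits()

    def test_matches_split_intersection_bruteforce(self):
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, 7, 12, n_states=2)
        ts = enumerate_mp_trees(aln)
        cons = strict_consensus(ts)
        expected = set.intersection(*(splits_bruteforce(t) for t in ts.trees))
        assert set(cons.splits()) == expected

    def test_matches_dendropy_consensus(self):
        rng = np.random.default_rng(14)
        aln = random_alignment(rng, 7, 10, n_states=2)
        ts = enumerate_mp_trees(aln)
        if len(ts) < 2:
            ts = enumerate_mp_trees(random_alignment(rng, 7, 8, n_states=2))
        tns = dendropy.TaxonNamespace()
        dtrees = dendropy.TreeList(
            [dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=tns) for t in ts.trees]
        )
        dcons = dtrees.consensus(min_freq=1.0)
        dcons_splits = splits_bruteforce(
            PhyloTree.from_newick(dcons.as_string(schema="newick")
                                  .replace("[&R] ", ""), rooted=False)
        )
        assert set(strict_consensus(ts).splits()) == dcons_splits

    def test_incompatible_splits_listed_for_conflicting_trees(self):
        from mtphylo.parsimony import incompatible_splits

        t1 = PhyloTree.from_newick("((a,b),(c,(d,e)));", rooted=False)
        t2 = PhyloTree.from_newick("((a,c),(b,(d,e)));", rooted=False)
        conflicts = incompatible_splits(TreeSet(trees=[t1, t2], score=0))
        # ab|cde and ac|bde cross (canonical sides exclude the anchor 'a')
        expected = {frozenset({"c", "d", "e"}), frozenset({"b", "d", "e"})}
        assert any({frozenset(x) for x in pair} == expected for pair in conflicts)
        # the shared cherry de is compatible with everything
        for pair in conflicts:
            assert frozenset({"d", "e"}) not in {frozenset(x) for x in pair}

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((a,b),(c,d));", rooted=False)
        t2 = PhyloTree.from_newick("((a,b),(c,e));", rooted=False)
        with pytest.raises(ParsimonyError):
            strict_consensus(TreeSet(trees=[t1, t2], score=0))


class TestMapMutations:
    def test_change_conservation(self, reference, gene_map):
        rng = np.random.default_rng(15)
        for _ in range(5):
            aln = random_alignment(rng, 6, 30)
            ts = heuristic_search(aln)
            mp = map_mutations(ts.trees[0], aln, reference, gene_map,
                               root="reference")
            assert mp.total_changes == ts.score
            assert sum(len(n.mutations) for n in mp.tree.postorder()) == ts.score

    def test_outgroup_rooting(self, reference, gene_map):
        rng = np.random.default_rng(16)
        aln = random_alignment(rng, 6, 25)
        ts = heuristic_search(aln)
        mp = map_mutations(ts.trees[0], aln, reference, gene_map, root="t3")
        assert mp.total_changes == ts.score
        # outgroup sits directly under the root
        assert any(c.name == "t3" for c in mp.tree.root.children)

    def test_unrooted_without_root_choice_rejected(self, reference, gene_map):
        rng = np.random.default_rng(17)
        aln = random_alignment(rng, 5, 20)
        ts = heuristic_search(aln)
        with pytest.raises(ParsimonyError, match="root"):
            map_mutations(ts.trees[0], aln, reference, gene_map, root=None)

    def test_recovers_simulated_placements_without_homoplasy(
        self, reference, gene_map
    ):
        cfg = SimConfig(n_leaves=6, genealogy="yule", tmrca_years=30000,
                        recurrent_prob=0.0, seed=21)
        tree = simulate_genealogy(cfg)
        aln, truth = evolve_sequences(tree, reference, gene_map, cfg)
        aln = drop_gapped_columns(aln)
        positions_hit = [e.position for e in truth.mutation_events]
        if len(set(positions_hit)) != len(positions_hit):
            pytest.skip("rare multi-hit draw; homoplasy-free premise violated")
        truth_by_branch = {
            n.name: sorted(v.position for v in n.mutations)
            for n in truth.tree.postorder()
        }
        # map on the true topology: placements must match the simulation
        mapped = map_mutations(truth.tree.copy(), aln, reference, gene_map,
                               root=None)
        seen = 0
        for node in mapped.tree.postorder():
            got = sorted(v.position for v in node.mutations)
            want = [p for p in truth_by_branch.get(node.name, [])
                    if _varies(aln, p)]
            assert got == want, node.name
            seen += len(got)
        assert seen == mapped.total_changes
        assert mapped.recurrent_positions == {}

    def test_recurrent_sites_flagged_and_numbered(self, reference, gene_map):
        # two taxa pairs forcing a parallel change at one site
        rows = ["AAAC", "AAAC", "CAAA", "CAAA", "ACCA", "GCCA"]
        aln = aln_from_rows(rows)
        ts = heuristic_search(aln)
        mp = map_mutations(ts.trees[0], aln, reference, gene_map,
                           root="reference")
        for pos, count in mp.recurrent_positions.items():
            hits = [v for n in mp.tree.postorder() for v in n.mutations
                    if v.position == pos]
            assert len(hits) == count >= 2
            assert sorted(h.occurrence_index for h in hits) == list(
                range(1, count + 1))
            assert all(h.is_recurrent for h in hits)


def _varies(aln, position):
    col = np.nonzero(aln.column_positions == position)[0]
    if not col.size:
        return False
    c = aln.matrix[:, col[0]]
    return len(set(c.tolist())) > 1
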