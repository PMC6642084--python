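"""Tree handling, cut levels, per-branch scans and simplification."""

import math

import pandas as pd
import pytest

import skewscan as sk
from conftest import balanced_newick


class TestNewickIO:
    def test_parse_counts_nodes(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        assert sorted(sk.leaf_labels(tree)) == ["A", "B", "C", "D"]
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 3

    def test_polytomy_accepted(self):
        tree = sk.parse_newick("(A,B,C);")
        assert len(tree.seed_node.child_nodes()) == 3

    def test_duplicate_labels_rejected(self):
        with pytest.raises(sk.FormatError, match="[Dd]uplicate"):
            sk.parse_newick("(A,(A,B));")

    def test_malformed_newick_rejected(self):
        with pytest.raises(sk.FormatError):
            sk.parse_newick("((A,B);")

    def test_round_trip(self, tmp_path):
        tree = sk.parse_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        path = tmp_path / "t.nwk"
        sk.write_newick(tree, path)
        again = sk.read_newick(path)
        assert sk.to_newick(again).replace(" ", "") == \
            sk.to_newick(tree).replace(" ", "")


class TestPrune:
    def test_prune_suppresses_degree_two_nodes(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        pruned = sk.prune_to(tree, ["A", "C", "D"])
        assert sk.to_newick(pruned).strip() == "(A,(C,D));"

    def test_prune_sums_branch_lengths(self):
        tree = sk.parse_newick("((A:1,B:1):2,C:3);")
        pruned = sk.prune_to(tree, ["A", "C"])
        lengths = {l.taxon.label: l.edge.length
                   for l in pruned.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(3.0)  # 1 through suppressed + 2

    def test_prune_to_all_is_identity(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        pruned = sk.prune_to(tree, ["A", "B", "C", "D"])
        assert sk.to_newick(pruned).strip() == "((A,B),(C,D));"

    def test_prune_to_empty_or_unknown(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        with pytest.raises(sk.ParameterError):
            sk.prune_to(tree, [])
        with pytest.raises(sk.FormatError, match="Z"):
            sk.prune_to(tree, ["A", "Z"])


class TestReroot:
    def test_reroot_on_clade(self):
        tree = sk.parse_newick("((A,B),(C,(D,E)));")
        rerooted = sk.reroot_on(tree, ["D", "E"])
        sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                 for c in rerooted.seed_node.child_nodes()]
        assert frozenset("DE") in sides
        assert sorted(sk.leaf_labels(rerooted)) == sorted(sk.leaf_labels(tree))

    def test_reroot_on_single_leaf(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        rerooted = sk.reroot_on(tree, ["A"])
        sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                 for c in rerooted.seed_node.child_nodes()]
        assert frozenset("A") in sides

    def test_reroot_on_complement_clade(self):
        """An outgroup monophyletic only in the unrooted sense still works."""
        tree = sk.parse_newick("((A,B),(C,D));")
        rerooted = sk.reroot_on(tree, ["A", "B", "C"])  # complement of {D}... no
        sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                 for c in rerooted.seed_node.child_nodes()]
        assert frozenset("ABC") in sides or frozenset("D") in sides

    def test_reroot_on_everything_rejected(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        with pytest.raises(sk.ParameterError):
            sk.reroot_on(tree, ["A", "B", "C", "D"])

    def test_non_monophyletic_outgroup_rejected(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        with pytest.raises(sk.FormatError):
            sk.reroot_on(tree, ["A", "C"])


class TestCutLevels:
    def test_balanced_four_leaves(self):
        tree = sk.parse_newick("((A,B),(C,D));")
        partitions = sk.cut_levels(tree)
        assert [p.n_clusters for p in partitions] == [2, 3, 4]
        assert partitions[-1].sizes() == (1, 1, 1, 1)

    def test_caterpillar_expansion_order(self):
        tree = sk.parse_newick("(((A,B),C),D);")
        partitions = sk.cut_levels(tree)
        as_sets = [[set(c.samples) for c in p.clusters] for p in partitions]
        assert as_sets == [
            [{"A", "B", "C"}, {"D"}],
            [{"A", "B"}, {"C"}, {"D"}],
            [{"A"}, {"B"}, {"C"}, {"D"}],
        ]

    def test_two_leaf_tree(self):
        tree = sk.parse_newick("(A,B);")
        partitions = sk.cut_levels(tree)
        assert len(partitions) == 1
        assert partitions[0].sizes() == (1, 1)

    def test_partitions_strictly_refine(self, rng):
        newick, _ = balanced_newick(16)
        tree = sk.parse_newick(newick)
        partitions = sk.cut_levels(tree)
        for before, after in zip(partitions, partitions[1:]):
            assert after.n_clusters > before.n_clusters
            assert after.samples == before.samples
            prev = {frozenset(c.samples) for c in before.clusters}
            for cluster in after.clusters:
                assert any(cluster.samples <= block for block in prev)


class TestBranchScan:
    def test_uniform_presence_no_signal(self, balanced32):
        tree, labels = balanced32
        matrix = sk.PresenceMatrix(pd.DataFrame({"g1": [1] * 32}, index=labels))
        results = sk.branch_scan(tree, matrix)
        assert all(r.p_value == 1.0 for r in results)
        assert not any(r.significant for r in results)

    def test_planted_loss_best_split_closed_form(self, planted_loss_matrix):
        """A clean 8-leaf clade loss on 32 leaves is found at the branch
        whose cluster-vs-rest table is the unique extreme one."""
        tree, matrix = planted_loss_matrix
        results = sk.branch_scan(tree, matrix)
        best = sk.best_splits(results)["g1"]
        leaves = {l.taxon.label
                  for n in tree.preorder_node_iter() if n.node_id == best.node_id
                  for l in n.leaf_iter()}
        assert leaves == {f"t{i}" for i in range(1, 9)}
        assert best.p_value == pytest.approx(1 / math.comb(32, 8), rel=1e-12)
        assert best.significant

    def test_exactly_one_best_per_hmm(self, planted_loss_matrix):
        tree, matrix = planted_loss_matrix
        results = sk.branch_scan(tree, matrix)
        assert sum(r.is_best for r in results) == len(matrix.hmms)

    def test_invariant_to_leaf_order_and_rerooting(self, planted_loss_matrix):
        tree, matrix = planted_loss_matrix
        base = {(r.node_id, r.hmm_id): r.p_value
                for r in sk.branch_scan(tree, matrix)}
        shuffled = matrix.restrict(sorted(matrix.samples, reverse=True))
        other = {(r.node_id, r.hmm_id): r.p_value
                 for r in sk.branch_scan(tree, shuffled)}
        assert base == other
        # re-rooting on the same outgroup clade preserves the best p-value
        rerooted = sk.reroot_on(tree, [f"t{i}" for i in range(17, 33)])
        best0 = sk.best_splits(sk.branch_scan(tree, matrix))["g1"]
        best1 = sk.best_splits(sk.branch_scan(rerooted, matrix))["g1"]
        assert best1.p_value == pytest.approx(best0.p_value, rel=1e-12)

    def test_matrix_tree_mismatch_rejected(self, balanced32):
        tree, labels = balanced32
        matrix = sk.PresenceMatrix(
            pd.DataFrame({"g1": [1] * 31}, index=labels[:31]))
        with pytest.raises(sk.FormatError, match="t32"):
            sk.branch_scan(tree, matrix)


class TestSimplifyTree:
    def test_uniform_matrix_single_cluster(self, balanced32):
        tree, labels = balanced32
        matrix = sk.PresenceMatrix(pd.DataFrame({"g1": [1] * 32}, index=labels))
        partition = sk.simplify_tree(tree, matrix)
        assert partition.n_clusters == 1
        assert partition.clusters[0].samples == frozenset(labels)

    def test_planted_loss_two_clusters(self, planted_loss_matrix):
        tree, matrix = planted_loss_matrix
        partition = sk.simplify_tree(tree, matrix)
        sizes = sorted(partition.sizes())
        assert sizes == [8, 24]
        lost = next(c for c in partition.clusters if c.size == 8)
        assert lost.samples == {f"t{i}" for i in range(1, 9)}

    def test_partition_valid_on_random_fixtures(self, rng):
        """Any tree x matrix combination yields a true partition."""
        for rep in range(30):
            n = int(rng.integers(6, 20))
            tree = sk.simulate_tree(n, "yule", seed=int(rng.integers(2**31)))
            labels = sk.leaf_labels(tree)
            calls = pd.DataFrame(
                {f"g{j}": rng.integers(0, 2, size=n) for j in range(3)},
                index=labels)
            partition = sk.simplify_tree(tree, sk.PresenceMatrix(calls))
            assert partition.samples == frozenset(labels)
            assert sum(partition.sizes()) == n

    def test_power_and_type_one_error(self):
        """Across replicated noisy simulations the true loss branch wins the
        scan in a clear majority of cases, while null (uniform) genes almost
        never produce a significant best split at alpha = 1e-3."""
        tree = sk.simulate_tree(32, "balanced", seed=0)
        node = sk.clade_node_of_size(tree, 8)
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            truth = sk.planted_loss_trait(tree, node)
            hits, (obs,) = sk.apply_dropout(
                [truth], detection_prob=0.9,
                bitscore_model=sk.BitscoreModel(spurious_rate=0.0),
                seed=1000 + rep)
            matrix = sk.presence_call(hits, samples=sk.leaf_labels(tree),
                                      hmms=["g1"])
            best = sk.best_splits(sk.branch_scan(tree, matrix))["g1"]
            clade = {l.taxon.label
                     for n_ in tree.preorder_node_iter()
                     if n_.node_id == best.node_id for l in n_.leaf_iter()}
            wins += clade == set(truth.tip_states) - {
                s for s, v in truth.tip_states.items() if v}
        assert wins > n_rep / 2

        false_hits = 0
        for rep in range(n_rep):
            null = sk.SimTruth("g1", 1, {s: 1 for s in sk.leaf_labels(tree)},
                               ())
            hits, _ = sk.apply_dropout(
                [null], detection_prob=0.9,
                bitscore_model=sk.BitscoreModel(spurious_rate=0.0),
                seed=5000 + rep)
            matrix = sk.presence_call(hits, samples=sk.leaf_labels(tree),
                                      hmms=["g1"])
            best = sk.best_splits(sk.branch_scan(tree, matrix))["g1"]
            false_hits += best.significant
        assert false_hits / n_rep <= 0.01
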