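import itertools
import math

import numpy as np
import pytest

from phylonom import phylogeny as ph
from phylonom._aa import AA_INDEX, AMINO_ACIDS


def random_unrooted_tree(ids, rng):
    """Random unrooted binary topology with exponential branch lengths."""
    nodes = [ph.Node(i, float(rng.exponential(0.5)) + 0.05) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = ph.Node(None, float(rng.exponential(0.5)) + 0.05)
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = ph.Node()
    for n in nodes:
        root.add(n)
    return ph.PhyloTree(root, rooted=False)


def path_distance_matrix(tree):
    ids = sorted(tree.leaf_names())
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = tree.patristic_distance(ids[i], ids[j])
    return ph.DistanceMatrix(ids, d)


class TestNewick:
    def test_supports_parsed_from_internal_labels(self):
        t = ph.read_newick("((A:1,B:2)90:1,C:3);")
        assert [n.support for n in t.internal_edges()] == [90.0]

    def test_round_trip(self):
        text = "((A:1.000000,B:2.000000)90:1.000000,C:3.000000);"
        assert ph.write_newick(ph.read_newick(text)) == text

    @pytest.mark.parametrize("bad", ["((A,B);", "(A,B))", "((A,A));", "(A,B)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            ph.read_newick(bad)


class TestPairwiseDistances:
    def test_identical_rows_zero(self, make_alignment):
        aln = make_alignment(["a", "b"], ["HDSHDS", "HDSHDS"])
        assert ph.pairwise_distances(aln).matrix[0, 1] == 0.0

    def test_half_mismatch_poisson(self, make_alignment):
        aln = make_alignment(["a", "b"], ["HDHD", "HSHS"])
        assert ph.pairwise_distances(aln).matrix[0, 1] == \
            pytest.approx(-math.log(0.5))

    def test_pairwise_deletion_ignores_missing(self, make_alignment):
        aln = make_alignment(["a", "b"], ["HD-X", "HDSS"])
        assert ph.pairwise_distances(aln).matrix[0, 1] == 0.0

    def test_saturation_clamped_and_flagged(self, make_alignment):
        aln = make_alignment(["a", "b"], ["H" * 50, "D" * 50])
        dm = ph.pairwise_distances(aln)
        assert dm.matrix[0, 1] == ph.DISTANCE_MAX
        assert ("a", "b") in dm.saturated

    def test_no_comparable_columns_rejected(self, make_alignment):
        aln = make_alignment(["a", "b"], ["H--", "--S"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            ph.pairwise_distances(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = ph.neighbor_joining(ph.DistanceMatrix(["a", "b", "c"], d))
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_recovers_known_additive_tree(self):
        gen = ph.read_newick("((A:1,B:2):1,C:1,D:2);")
        tree = ph.neighbor_joining(path_distance_matrix(gen))
        assert ph.rf_distance(tree, gen) == 0
        for name, expected in [("A", 1.0), ("B", 2.0), ("C", 1.0), ("D", 2.0)]:
            leaf = next(n for n in tree.leaves() if n.name == name)
            assert leaf.length == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(50))
    def test_additive_matrices_reconstructed_exactly(self, seed):
        """NJ is consistent: path-length matrices of random trees (n <= 8)
        are reconstructed with the generating topology."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ids = [f"t{k}" for k in range(n)]
        gen = random_unrooted_tree(ids, rng)
        rec = ph.neighbor_joining(path_distance_matrix(gen))
        assert ph.rf_distance(rec, gen) == 0

    def test_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = ph.DistanceMatrix(list("abcd"), d)
        assert ph.write_newick(ph.neighbor_joining(dm)) == \
            ph.write_newick(ph.neighbor_joining(dm))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            ph.neighbor_joining(ph.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_against_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(11)
        gen = random_unrooted_tree([f"t{k}" for k in range(6)], rng)
        dm = path_distance_matrix(gen)
        ours = ph.neighbor_joining(dm)
        csv = "," + ",".join(dm.ids) + "\n"
        for i, a in enumerate(dm.ids):
            csv += a + "," + ",".join(str(x) for x in dm.matrix[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        theirs = pdm.nj_tree()
        taxa = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ph.write_newick(ours), schema="newick",
                               taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=theirs.as_string(schema="newick"),
                               schema="newick", taxon_namespace=taxa)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


class TestFitchParsimony:
    def test_constant_column_costs_nothing(self, make_alignment):
        t = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        aln = make_alignment(list("ABCD"), ["H", "H", "H", "H"])
        assert ph.fitch_parsimony_score(t, aln) == 0

    def test_matching_split_costs_one(self, make_alignment):
        t = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        aln = make_alignment(list("ABCD"), ["A", "A", "S", "S"])
        assert ph.fitch_parsimony_score(t, aln) == 1

    def test_gaps_are_union_neutral(self, make_alignment):
        t = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        aln = make_alignment(list("ABCD"), ["A", "-", "S", "X"])
        assert ph.fitch_parsimony_score(t, aln) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_assignment(self, seed, make_alignment):
        """Fitch equals the minimum over all internal-state assignments
        (states restricted to those observed in the column)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        ids = [f"t{k}" for k in range(n)]
        tree = random_unrooted_tree(ids, rng)
        rows = ["".join(rng.choice(list("HDSA"), 3)) for _ in ids]
        aln = make_alignment(ids, rows)
        got = ph.fitch_parsimony_score(tree, aln)

        internal = [nd for nd in tree.postorder() if not nd.is_leaf]
        leaves = {nd.name: nd for nd in tree.leaves()}
        total = 0
        for col in range(3):
            states = sorted({rows[ids.index(i)][col] for i in ids})
            best = None
            for combo in itertools.product(states, repeat=len(internal)):
                label = {id(nd): s for nd, s in zip(internal, combo)}
                for i in ids:
                    label[id(leaves[i])] = rows[ids.index(i)][col]
                cost = sum(
                    1
                    for nd in tree.postorder() if nd is not tree.root
                    for _ in [0]
                    if label[id(nd)] != label[id(nd.parent)]
                )
                best = cost if best is None else min(best, cost)
            total += best
        assert got == total

    def test_leaf_mismatch_rejected(self, make_alignment):
        t = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(ValueError):
            ph.fitch_parsimony_score(t, make_alignment(["A", "B"], ["H", "H"]))


class TestLogLikelihood:
    def test_zero_branch_identical_site(self, poisson, make_alignment):
        t = ph.read_newick(f"(A:{ph.BRANCH_MIN},B:{ph.BRANCH_MIN});")
        aln = make_alignment(["A", "B"], ["H", "H"])
        assert ph.log_likelihood(t, aln, poisson) == \
            pytest.approx(math.log(1 / 20), abs=1e-6)

    def test_stationarity_limit(self, poisson, make_alignment):
        t = ph.read_newick("(A:25,B:25);")
        aln = make_alignment(["A", "B"], ["H", "D"])
        assert ph.log_likelihood(t, aln, poisson) == \
            pytest.approx(math.log(1 / 400), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_internal_state_enumeration(self, seed, wag,
                                                make_alignment):
        """Pruning equals brute-force summation over all 20^2 internal-state
        pairs on 4-taxon 2-site instances."""
        rng = np.random.default_rng(seed)
        bl = rng.uniform(0.05, 1.0, size=5)
        t = ph.read_newick(
            f"((A:{bl[0]},B:{bl[1]}):{bl[4]},C:{bl[2]},D:{bl[3]});")
        rows = ["".join(rng.choice(list(AMINO_ACIDS), 2)) for _ in range(4)]
        aln = make_alignment(list("ABCD"), rows)
        got = ph.log_likelihood(t, aln, wag)

        pi = wag.frequencies
        P = [wag.transition_matrix(b) for b in bl]
        expected = 0.0
        for site in range(2):
            codes = [AA_INDEX[rows[k][site]] for k in range(4)]
            tot = 0.0
            for r in range(20):
                for u in range(20):
                    tot += (pi[r] * P[4][r, u] * P[0][u, codes[0]]
                            * P[1][u, codes[1]] * P[2][r, codes[2]]
                            * P[3][r, codes[3]])
            expected += math.log(tot)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_rerooting(self, wag, make_alignment,
                                       tree_simulator):
        t = ph.read_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.2):0.3,E:0.6);")
        seqs = tree_simulator(t, wag, 40, seed=5)
        aln = make_alignment(list("ABCDE"), [seqs[k] for k in "ABCDE"])
        base = ph.log_likelihood(t, aln, wag)
        for node in t.edges():
            rerooted = t.reroot_on_edge(node, 0.3)
            assert ph.log_likelihood(rerooted, aln, wag) == \
                pytest.approx(base, abs=1e-9)

    def test_gap_and_x_marginalized(self, poisson, make_alignment):
        t = ph.read_newick("(A:0.5,B:0.5);")
        gapped = make_alignment(["A", "B"], ["H-", "HX"])
        plain = make_alignment(["A", "B"], ["H", "H"])
        assert ph.log_likelihood(t, gapped, poisson) == \
            pytest.approx(ph.log_likelihood(t, plain, poisson))

    def test_negative_branch_rejected(self, poisson, make_alignment):
        t = ph.read_newick("(A:-0.5,B:0.5);")
        with pytest.raises(ValueError):
            ph.log_likelihood(t, make_alignment(["A", "B"], ["H", "H"]),
                              poisson)


class TestOptimizeBranchLengths:
    def test_identical_sites_drive_to_lower_bound(self, poisson,
                                                  make_alignment):
        t = ph.read_newick("(A:0.5,B:0.5);")
        aln = make_alignment(["A", "B"], ["HDSHDS", "HDSHDS"])
        opt = ph.optimize_branch_lengths(t, aln, poisson)
        assert opt.total_length() < 1e-2

    def test_all_sites_different_drive_to_upper_bound(self, poisson,
                                                      make_alignment):
        # under the equal-rates model the likelihood of an all-mismatch pair
        # is monotone in the branch length, so the MLE is at the bound
        t = ph.read_newick("(A:0.5,B:0.5);")
        aln = make_alignment(["A", "B"], ["HDSHDS", "DSADSA"])
        opt = ph.optimize_branch_lengths(t, aln, poisson)
        assert opt.total_length() > 0.5 * ph.BRANCH_MAX

    def test_likelihood_never_decreases(self, wag, make_alignment,
                                        tree_simulator):
        t = ph.read_newick("((A:0.3,B:0.5):0.2,C:0.4,D:0.7);")
        seqs = tree_simulator(t, wag, 60, seed=3)
        aln = make_alignment(list("ABCD"), [seqs[k] for k in "ABCD"])
        start = t.copy()
        for node in start.edges():
            node.length = 0.4
        opt = ph.optimize_branch_lengths(start, aln, wag)
        assert ph.log_likelihood(opt, aln, wag) >= \
            ph.log_likelihood(start, aln, wag)


class TestNNISearch:
    def test_recovers_generating_split(self, wag, make_alignment,
                                       tree_simulator):
        """Started from the wrong 4-taxon split, NNI restores the
        generating one (500 simulated sites, strong signal)."""
        truth = ph.read_newick("((A:0.3,B:0.3):0.4,C:0.3,D:0.3);")
        seqs = tree_simulator(truth, wag, 500, seed=7)
        aln = make_alignment(list("ABCD"), [seqs[k] for k in "ABCD"])
        wrong = ph.read_newick("((A:0.3,C:0.3):0.2,B:0.3,D:0.3);")
        found = ph.nni_search(wrong, aln, wag)
        assert ph.rf_distance(found, truth) == 0

    def test_three_leaves_returned_unchanged(self, wag, make_alignment):
        t = ph.read_newick("(A:0.2,B:0.2,C:0.2);")
        aln = make_alignment(list("ABC"), ["HDS", "HDA", "HSA"])
        assert ph.rf_distance(ph.nni_search(t, aln, wag), t) == 0

    def test_optimal_tree_is_fixed_point(self, wag, make_alignment,
                                         tree_simulator):
        truth = ph.read_newick("((A:0.3,B:0.3):0.4,C:0.3,D:0.3);")
        seqs = tree_simulator(truth, wag, 500, seed=9)
        aln = make_alignment(list("ABCD"), [seqs[k] for k in "ABCD"])
        best = ph.nni_search(truth, aln, wag)
        assert ph.rf_distance(best, truth) == 0
        # verify directly that no NNI neighbor beats it
        pruner = ph._Pruner(aln, wag)
        best_ll = pruner.loglik(best)
        for cand, local in ph._nni_candidates(best):
            ph._optimize_edges(cand, pruner)
            assert pruner.loglik(cand) <= best_ll + 1e-6


class TestInferMLTree:
    def test_three_rows_nj_topology_ml_lengths(self, wag, make_alignment,
                                               tree_simulator):
        truth = ph.read_newick("(A:0.3,B:0.4,C:0.5);")
        seqs = tree_simulator(truth, wag, 100, seed=2)
        aln = make_alignment(list("ABC"), [seqs[k] for k in "ABC"])
        tree = ph.infer_ml_tree(aln, wag)
        assert sorted(tree.leaf_names()) == ["A", "B", "C"]

    def test_improves_on_optimized_nj_start(self, wag, make_alignment,
                                            tree_simulator):
        truth = ph.read_newick("((A:0.4,B:0.4):0.3,(C:0.4,D:0.4):0.3,E:0.5);")
        seqs = tree_simulator(truth, wag, 150, seed=4)
        aln = make_alignment(list("ABCDE"), [seqs[k] for k in "ABCDE"])
        nj = ph.neighbor_joining(ph.pairwise_distances(aln))
        nj_opt = ph.optimize_branch_lengths(nj, aln, wag)
        ml = ph.infer_ml_tree(aln, wag)
        assert ph.log_likelihood(ml, aln, wag) >= \
            ph.log_likelihood(nj_opt, aln, wag) - 1e-6

    def test_recovers_generating_topology(self, wag, make_alignment,
                                          tree_simulator):
        truth = ph.read_newick(
            "((A:0.3,B:0.3):0.25,(C:0.3,(D:0.3,E:0.3):0.25):0.25,F:0.5);")
        seqs = tree_simulator(truth, wag, 300, seed=1)
        ids = list("ABCDEF")
        aln = make_alignment(ids, [seqs[k] for k in ids])
        ml = ph.infer_ml_tree(aln, wag)
        assert ph.rf_distance(ml, truth) == 0


class TestBootstrap:
    def test_same_seed_reproduces_supports(self, wag, make_alignment,
                                           tree_simulator):
        truth = ph.read_newick("((A:0.3,B:0.3):0.3,C:0.3,D:0.3);")
        seqs = tree_simulator(truth, wag, 120, seed=6)
        aln = make_alignment(list("ABCD"), [seqs[k] for k in "ABCD"])
        cfg = ph.BootstrapConfig(replicates=10, seed=42)
        s1 = ph.bootstrap_supports(aln, wag, cfg)
        s2 = ph.bootstrap_supports(aln, wag, cfg)
        assert ph.write_newick(s1) == ph.write_newick(s2)

    def test_supports_bounded_and_strong_signal_certain(
            self, wag, make_alignment, tree_simulator):
        truth = ph.read_newick("((A:0.3,B:0.3):0.5,C:0.3,D:0.3);")
        seqs = tree_simulator(truth, wag, 400, seed=8)
        aln = make_alignment(list("ABCD"), [seqs[k] for k in "ABCD"])
        out = ph.bootstrap_supports(aln, wag,
                                    ph.BootstrapConfig(replicates=25, seed=1))
        sup = [n.support for n in out.internal_edges()]
        assert all(0 <= s <= 100 for s in sup)
        assert sup == [100.0]

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            ph.BootstrapConfig(replicates=0)

    def test_single_column_degenerate(self, wag, make_alignment):
        aln = make_alignment(list("ABCD"), ["H", "H", "D", "D"])
        out = ph.bootstrap_supports(aln, wag,
                                    ph.BootstrapConfig(replicates=5, seed=0))
        assert all(n.support is not None for n in out.internal_edges())


class TestRFDistance:
    def test_identical_trees(self):
        t = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        assert ph.rf_distance(t, t.copy()) == 0

    def test_conflicting_quartets(self):
        t1 = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = ph.read_newick("((A:1,C:1):1,B:1,D:1);")
        assert ph.rf_distance(t1, t2) == 2
        assert ph.rf_distance(t2, t1) == 2

    def test_leaf_set_mismatch_rejected(self):
        t1 = ph.read_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = ph.read_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError):
            ph.rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(6))
    def test_against_dendropy(self, seed):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(seed)
        ids = [f"t{k}" for k in range(7)]
        a = random_unrooted_tree(ids, rng)
        b = random_unrooted_tree(ids, rng)
        taxa = dendropy.TaxonNamespace()
        da_ = dendropy.Tree.get(data=ph.write_newick(a), schema="newick",
                                taxon_namespace=taxa)
        db_ = dendropy.Tree.get(data=ph.write_newick(b), schema="newick",
                                taxon_namespace=taxa)
        da_.encode_bipartitions()
        db_.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(da_, db_)
        assert ph.rf_distance(a, b) == expected


class TestDiscreteGamma:
    def test_category_rates_average_to_one(self):
        for shape in (0.2, 0.5, 1.0, 5.0):
            rates = ph.discrete_gamma_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0)
            assert (np.diff(rates) > 0).all()

    def test_single_category_equals_plain_likelihood(self, wag,
                                                     make_alignment):
        t = ph.read_newick("((A:0.3,B:0.5):0.2,C:0.4,D:0.7);")
        aln = make_alignment(list("ABCD"), ["HD", "DS", "HS", "SS"])
        plain = ph.log_likelihood(t, aln, wag)
        assert ph.log_likelihood(t, aln, wag, gamma_shape=1.0,
                                 gamma_categories=1) == pytest.approx(plain)

    def test_large_shape_converges_to_single_rate(self, wag, make_alignment):
        t = ph.read_newick("((A:0.3,B:0.5):0.2,C:0.4,D:0.7);")
        aln = make_alignment(list("ABCD"), ["HD", "DS", "HS", "SS"])
        plain = ph.log_likelihood(t, aln, wag)
        hetero = ph.log_likelihood(t, aln, wag, gamma_shape=1e5)
        assert hetero == pytest.approx(plain, abs=1e-4)

    def test_rate_variation_changes_likelihood(self, wag, make_alignment):
        t = ph.read_newick("((A:0.3,B:0.5):0.2,C:0.4,D:0.7);")
        aln = make_alignment(list("ABCD"), ["HDHD", "DSDS", "HSHH", "SSSS"])
        plain = ph.log_likelihood(t, aln, wag)
        hetero = ph.log_likelihood(t, aln, wag, gamma_shape=0.3)
        assert hetero != pytest.approx(plain, abs=1e-6)


def test_wag_model_invariants(wag):
    q = wag.Q
    pi = wag.frequencies
    assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
    assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0)
    assert pi.sum() == pytest.approx(1.0, abs=1e-12)
    # detailed balance (reversibility)
    assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)
    p = wag.transition_matrix(0.7)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
    assert (p >= 0).all()
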