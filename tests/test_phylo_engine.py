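"""Trees, matrix exponentials, pruning likelihoods and marginal
ancestral reconstruction, checked against enumeration oracles."""

import itertools

import numpy as np
import pytest

from phylogrammar import (DNA, ParamSet, ancestral_marginal, chain_params,
                          felsenstein_likelihood, instantiate_matrix,
                          jc_distance_matrix, jukes_cantor,
                          matrix_exponential, neighbor_joining,
                          nielsen_yang, parse_newick, raser_chain,
                          write_newick)
from phylogrammar.chain import HybridChain
from phylogrammar.likelihood import ChainEngine, PhyloEmitter
from phylogrammar.tree import NewickError, PhyloTree

from conftest import brute_force_likelihood, brute_force_root_posterior


class TestNewick:
    def test_two_leaf(self):
        t = parse_newick("(A:1,B:1);")
        assert t.leaf_names == ["A", "B"]
        assert all(l.length == 1.0 for l in t.leaves())

    def test_internal_label(self):
        t = parse_newick("((A:0.1,B:0.2)n1:0.3,C:0.4);")
        assert t.find("n1") is not None
        assert t.find("n1").length == pytest.approx(0.3)

    def test_roundtrip_random_ten_leaf(self, rng):
        def rand_tree(names):
            nodes = [PhyloTree(parse_newick(f"{n}:1;").root).root
                     for n in names]
            for n, name in zip(nodes, names):
                n.label, n.length = name, round(float(rng.uniform(0.05, 1)), 4)
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                parent = parse_newick("x;").root
                parent.label = None
                parent.length = round(float(rng.uniform(0.05, 1)), 4)
                parent.children = []
                parent.add(nodes[i])
                parent.add(nodes[j])
                nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
                nodes.append(parent)
            return PhyloTree(nodes[0])

        t = rand_tree([f"L{i}" for i in range(10)])
        t2 = parse_newick(write_newick(t))
        assert write_newick(t2) == write_newick(t)
        assert sorted(t2.leaf_names) == sorted(t.leaf_names)

    def test_malformed_reports_position(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,B:2;")

    def test_dendropy_agrees_on_structure(self):
        """Cross-check the Newick parser against dendropy."""
        import dendropy

        text = "((A:0.1,B:0.2)n1:0.3,(C:0.15,D:0.25)n2:0.05)root;"
        ours = parse_newick(text)
        theirs = dendropy.Tree.get(data=text, schema="newick",
                                   preserve_underscores=True)
        assert sorted(ours.leaf_names) == sorted(
            l.taxon.label for l in theirs.leaf_node_iter())
        our_len = sum(n.length for n in ours.nodes_preorder())
        their_len = theirs.length()
        assert our_len == pytest.approx(their_len)

    def test_rerooted_preserves_leaves_and_lengths(self):
        t = parse_newick("((A:0.1,B:0.2)n1:0.3,C:0.4)root;")
        r = t.rerooted("n1")
        assert sorted(r.leaf_names) == ["A", "B", "C"]
        total = sum(n.length for n in r.nodes_preorder())
        assert total == pytest.approx(0.1 + 0.2 + 0.3 + 0.4)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        """Distances computed from a known tree are exactly additive, so
        NJ must recover that tree (topology and branch lengths)."""
        true = {"A": 0.1, "B": 0.3, "C": 0.2, "D": 0.4}
        internal = 0.25
        names = ["A", "B", "C", "D"]
        d = np.zeros((4, 4))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i == j:
                    continue
                split = internal if {x, y} not in ({"A", "B"}, {"C", "D"}) \
                    else 0.0
                d[i, j] = true[x] + true[y] + split
        t = neighbor_joining(d, names)
        # AB and CD must be sibling pairs (the root join may trifurcate)
        assert t.find("A").parent is t.find("B").parent
        assert t.find("C").parent is t.find("D").parent
        for name, length in true.items():
            assert t.find(name).length == pytest.approx(length)
        # pairwise path lengths reproduce the additive distances
        def path_len(x, y):
            anc = {}
            n, acc = t.find(x), 0.0
            while n is not None:
                anc[id(n)] = acc
                acc += n.length
                n = n.parent
            n, acc = t.find(y), 0.0
            while id(n) not in anc:
                acc += n.length
                n = n.parent
            return acc + anc[id(n)]
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i < j:
                    assert path_len(x, y) == pytest.approx(d[i, j])

    def test_two_taxa_split_evenly(self):
        t = neighbor_joining(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])
        assert [l.length for l in t.leaves()] == [0.5, 0.5]

    def test_three_taxon_hand_solution(self):
        """For 3 taxa the join is unique: branch a = (dAB+dAC-dBC)/2."""
        d = np.array([[0.0, 0.4, 0.6],
                      [0.4, 0.0, 0.8],
                      [0.6, 0.8, 0.0]])
        t = neighbor_joining(d, ["A", "B", "C"])
        assert t.find("A").length == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert t.find("B").length == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert t.find("C").length == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, ["A", "B"])

    def test_jc_distance_of_identical_rows_is_zero(self):
        d = jc_distance_matrix(["acgt", "acgt"])
        assert d[0, 1] == 0.0


class TestMatrixExponential:
    def test_zero_time_is_identity(self):
        c = raser_chain()
        rm = instantiate_matrix(c, chain_params(c))
        assert np.allclose(matrix_exponential(rm.Q, 0.0), np.eye(8))

    def test_jc_stay_probability_closed_form(self):
        """JC69: P(stay) = 1/4 + (3/4) e^(-4ut), checked at u=1/3, t=1."""
        u, t = 1.0 / 3.0, 1.0
        c = jukes_cantor(u)
        rm = instantiate_matrix(c, chain_params(c))
        P = matrix_exponential(rm.Q, t)
        expected = 0.25 + 0.75 * np.exp(-4 * u * t)
        assert np.allclose(np.diag(P), expected, atol=1e-12)
        assert np.allclose(P[~np.eye(4, dtype=bool)],
                           (1 - expected) / 3, atol=1e-12)

    def test_rows_stochastic(self):
        c = raser_chain()
        rm = instantiate_matrix(c, chain_params(c))
        P = matrix_exponential(rm.Q, 0.73)
        assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-10
        assert P.min() >= 0

    def test_long_time_reaches_stationarity(self):
        """Every row tends to the stationary vector (null space of Q^T)."""
        import scipy.linalg

        c = raser_chain()
        rm = instantiate_matrix(c, chain_params(c))
        ns = scipy.linalg.null_space(rm.Q.T)[:, 0]
        pi = ns / ns.sum()
        # slowest relaxation is the class flip (rate 0.02), so go far out
        P = matrix_exponential(rm.Q, 2500.0)
        assert np.allclose(P, np.tile(pi, (8, 1)), atol=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            matrix_exponential(np.zeros((2, 2)), -0.1)

    def test_eigen_path_matches_scaling_and_squaring(self):
        import scipy.linalg

        c = raser_chain()
        params = chain_params(c)
        eng = ChainEngine(c, params)
        assert eng.eig is not None
        for t in (0.01, 0.4, 2.5):
            assert np.allclose(eng.pmatrix(t),
                               scipy.linalg.expm(eng.Q * t), atol=1e-11)


class TestFelsenstein:
    def test_zero_branches_same_token(self):
        t = parse_newick("(A:0,B:0);")
        c = jukes_cantor()
        lik = felsenstein_likelihood({"A": "a", "B": "a"}, c, t,
                                     chain_params(c))
        assert lik == pytest.approx(0.25)

    def test_infinite_branches_independent(self):
        t = parse_newick("(A:400,B:400);")
        c = jukes_cantor()
        lik = felsenstein_likelihood({"A": "a", "B": "c"}, c, t,
                                     chain_params(c))
        assert lik == pytest.approx(1.0 / 16.0, rel=1e-9)

    def test_three_leaf_matches_enumeration(self, tree3):
        c = jukes_cantor(0.7)
        params = chain_params(c)
        col = {"A": "a", "B": "c", "C": "a"}
        got = felsenstein_likelihood(col, c, tree3, params)
        want = brute_force_likelihood(col, c, tree3, params)
        assert got == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("newick", [
        "(A:0.3,B:0.5);",
        "((A:0.2,B:0.35)x:0.15,C:0.4);",
        "((A:0.3,B:0.4)x:0.2,(C:0.25,D:0.35)y:0.15);",
        "(((A:0.1,B:0.2)x:0.1,C:0.3)y:0.2,D:0.15);",
    ])
    @pytest.mark.parametrize("chain_fn", [jukes_cantor, raser_chain])
    def test_pruning_equals_brute_force(self, newick, chain_fn, rng):
        """Pruning vs full ancestral enumeration on all trees with <= 4
        leaves and chains with <= 8 states."""
        tree = parse_newick(newick)
        chain = chain_fn()
        params = chain_params(chain)
        for _ in range(3):
            col = {l: str(rng.choice(["a", "c", "g", "t", "*"]))
                   for l in tree.leaf_names}
            got = felsenstein_likelihood(col, chain, tree, params)
            want = brute_force_likelihood(col, chain, tree, params)
            assert got == pytest.approx(want, rel=1e-9)

    def test_all_wildcard_column_is_one(self, tree4):
        c = raser_chain()
        lik = felsenstein_likelihood({l: "*" for l in tree4.leaf_names},
                                     c, tree4, chain_params(c))
        assert lik == pytest.approx(1.0, rel=1e-12)

    def test_gaps_are_missing_data(self, tree3):
        c = jukes_cantor()
        params = chain_params(c)
        lik_gap = felsenstein_likelihood({"A": "-", "B": "c", "C": "a"},
                                         c, tree3, params)
        lik_wild = felsenstein_likelihood({"A": "*", "B": "c", "C": "a"},
                                          c, tree3, params)
        assert lik_gap == pytest.approx(lik_wild, rel=1e-12)

    def test_missing_leaf_named_in_error(self, tree3):
        c = jukes_cantor()
        with pytest.raises(KeyError, match="C"):
            felsenstein_likelihood({"A": "a", "B": "c"}, c, tree3,
                                   chain_params(c))

    def test_root_invariance_reversible_chains(self, tree4):
        """Rerooting anywhere leaves the likelihood unchanged for
        reversible chains."""
        col = {"A": "a", "B": "c", "C": "g", "D": "a"}
        for chain in (jukes_cantor(0.4), raser_chain()):
            params = chain_params(chain)
            base = felsenstein_likelihood(col, chain, tree4, params)
            for label in ("n1", "n2"):
                rerooted = tree4.rerooted(label)
                lik = felsenstein_likelihood(col, chain, rerooted, params)
                assert lik == pytest.approx(base, rel=1e-9)

    def test_hybrid_with_identical_components_is_plain(self, tree4):
        c = jukes_cantor(0.5)
        hybrid = HybridChain(c.terminals, {"A": c, "n1": c}, c)
        params = chain_params(c)
        col = {"A": "a", "B": "c", "C": "g", "D": "t"}
        plain = felsenstein_likelihood(col, c, tree4, params)
        hyb = felsenstein_likelihood(col, hybrid, tree4, params)
        assert abs(plain - hyb) < 1e-12

    def test_hybrid_resolution_changes_likelihood(self, tree4):
        fast = jukes_cantor(2.0, rate_name="uf")
        slow = jukes_cantor(0.1, rate_name="us")
        hybrid = HybridChain(slow.terminals, {"A": fast}, slow)
        params = chain_params(fast, slow)
        col = {"A": "a", "B": "c", "C": "g", "D": "t"}
        plain = felsenstein_likelihood(col, slow, tree4, params)
        hyb = felsenstein_likelihood(col, hybrid, tree4, params)
        assert hyb != pytest.approx(plain, rel=1e-6)


class TestAncestralMarginal:
    def test_observed_leaf_is_point_mass(self, tree3):
        c = jukes_cantor()
        post = ancestral_marginal({"A": "a", "B": "c", "C": "g"}, c,
                                  tree3, chain_params(c), "A")
        assert post[(("a",), None)] == pytest.approx(1.0)

    def test_zero_length_star_root_point_mass(self):
        t = parse_newick("(A:0,B:0,C:0)root;")
        c = jukes_cantor()
        post = ancestral_marginal({l: "g" for l in "ABC"}, c, t,
                                  chain_params(c), "root")
        assert post[(("g",), None)] == pytest.approx(1.0)

    def test_root_posterior_matches_bayes_enumeration(self, tree3):
        c = jukes_cantor(0.6)
        params = chain_params(c)
        col = {"A": "a", "B": "a", "C": "g"}
        got = ancestral_marginal(col, c, tree3, params, "root")
        want = brute_force_root_posterior(col, c, tree3, params)
        rm = instantiate_matrix(c, params)
        for s, w in zip(rm.states, want):
            assert got[s] == pytest.approx(w, rel=1e-9)

    def test_posterior_sums_to_one(self, tree4, rng):
        c = raser_chain()
        params = chain_params(c)
        for _ in range(5):
            col = {l: str(rng.choice(list("acgt")))
                   for l in tree4.leaf_names}
            for node in ("root", "n1", "n2"):
                post = ancestral_marginal(col, c, tree4, params, node)
                assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_node_rejected(self, tree3):
        c = jukes_cantor()
        with pytest.raises(KeyError):
            ancestral_marginal({"A": "a", "B": "c", "C": "g"}, c, tree3,
                               chain_params(c), "nosuch")
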