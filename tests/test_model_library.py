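"""Built-in model constructors and their equivalence with the
macro-expanded grammar files."""

import numpy as np
import pytest
from scipy.integrate import quad

from phylogrammar import (DNA, chain_params, discrete_gamma_rates,
                          dless_hmm, genetic_code, instantiate_matrix,
                          jukes_cantor, nielsen_yang, parse_newick,
                          phastcons_hmm, raser_chain, read_grammar,
                          sense_codons, codon_frequencies)
from phylogrammar.chain import HybridChain
from phylogrammar.inference import CompiledGrammar
from phylogrammar.library import codon_pair_type

ALIASES = {"changeProb": "leaveProb"}


class TestJukesCantor:
    def test_unit_rate_entries(self):
        rm = instantiate_matrix(jukes_cantor(1.0), chain_params(jukes_cantor()))
        assert np.allclose(rm.Q[~np.eye(4, dtype=bool)], 1.0)

    def test_one_third_gives_unit_substitution_rate(self):
        """-sum_i pi_i Q_ii = 1 at u = 1/3 (hand oracle: 4 * 1/4 * 3u)."""
        c = jukes_cantor(1.0 / 3.0)
        rm = instantiate_matrix(c, chain_params(c))
        assert rm.expected_rate() == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_rate_approaches_identity_process(self):
        c = jukes_cantor(1e-12)
        rm = instantiate_matrix(c, chain_params(c))
        assert np.max(np.abs(rm.Q)) < 1e-11

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor(0.0)
        with pytest.raises(ValueError):
            jukes_cantor(-1.0)


class TestLatentClassChain:
    def test_printed_seed_rates(self):
        c = raser_chain()
        rm = instantiate_matrix(c, chain_params(c))
        i = rm.index()
        assert rm.Q[i[(("a",), "s")], i[(("g",), "s")]] == pytest.approx(0.1)
        assert rm.Q[i[(("g",), "f")], i[(("g",), "s")]] == pytest.approx(0.01)

    def test_zero_flip_rates_block_diagonal(self):
        c = raser_chain(r_sf=0.0, r_fs=0.0)
        rm = instantiate_matrix(c, chain_params(c))
        i = rm.index()
        for t in DNA.tokens:
            for t2 in DNA.tokens:
                assert rm.Q[i[((t,), "s")], i[((t2,), "f")]] == 0.0
                assert rm.Q[i[((t,), "f")], i[((t2,), "s")]] == 0.0

    def test_equal_class_rates_lump_to_scaled_jc(self):
        """With s = f the token-marginal process is JC69 scaled by s:
        lumping classes gives identical generator blocks."""
        scale = 0.6
        c = raser_chain(s=scale, f=scale)
        rm = instantiate_matrix(c, chain_params(c))
        i = rm.index()
        jc = instantiate_matrix(jukes_cantor(1.0),
                                chain_params(jukes_cantor()))
        for a, t1 in enumerate(DNA.tokens):
            for b, t2 in enumerate(DNA.tokens):
                if t1 == t2:
                    continue
                lumped = sum(rm.Q[i[((t1,), "s")], i[((t2,), cls)]]
                             for cls in ("s", "f"))
                assert lumped == pytest.approx(scale * jc.Q[a, b])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            raser_chain(s=-0.1)


class TestDiscreteGamma:
    def test_single_bin_is_unit(self):
        assert discrete_gamma_rates(0.7, 1) == [pytest.approx(1.0)]

    def test_large_shape_degenerates_to_one(self):
        rates = discrete_gamma_rates(1e6, 5)
        assert np.allclose(rates, 1.0, atol=1e-2)

    def test_exponential_quartiles_match_quadrature(self):
        """shape=1 is the exponential density; bin means from direct
        numerical integration of x e^-x over its quartile bins."""
        edges = [-np.log(1 - q) for q in (0, 0.25, 0.5, 0.75)] + [np.inf]
        oracle = [4 * quad(lambda x: x * np.exp(-x), a, b)[0]
                  for a, b in zip(edges, edges[1:])]
        got = discrete_gamma_rates(1.0, 4)
        assert np.allclose(got, oracle, atol=1e-8)

    def test_mean_is_one(self):
        for shape in (0.2, 1.0, 3.7):
            for K in (2, 4, 7):
                assert np.mean(discrete_gamma_rates(shape, K)) == \
                    pytest.approx(1.0, abs=1e-8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)
        with pytest.raises(ValueError):
            discrete_gamma_rates(1.0, 0)


class TestRateMultiplierHMM:
    def test_three_state_transitions(self, tree3):
        """stayProb .9 leaves .05 for each of the two other states."""
        g = phastcons_hmm(3, jukes_cantor(), [0.5, 1.0, 2.0], 0.9)
        eng = CompiledGrammar(g, tree3).hmm()
        assert len(eng.states) == 3
        assert np.allclose(np.diag(eng.T), 0.9)
        assert np.allclose(eng.T[~np.eye(3, dtype=bool)], 0.05)
        assert np.allclose(eng.init, 1.0 / 3.0)

    def test_emitting_nonterminal_count(self):
        g = phastcons_hmm(3, jukes_cantor(), [1.0] * 3)
        assert len(g.emitting_nonterminals) == 3

    def test_single_state_forces_stay(self):
        with pytest.warns(UserWarning, match="forcing stayProb"):
            g = phastcons_hmm(1, jukes_cantor(), [1.0], 0.8)
        grp = g.params.pgroup_of("stayProb")
        assert grp["stayProb"] == pytest.approx(1.0)

    def test_chain_scaled_by_rate_multiplier(self):
        g = phastcons_hmm(2, jukes_cantor(1.0), [0.25, 2.0])
        q1 = instantiate_matrix(g.chains[0], g.params).Q
        q2 = instantiate_matrix(g.chains[1], g.params).Q
        assert np.allclose(q1 * 8.0, q2)


class TestLineageSpecificHMM:
    def test_balanced_tree_node_nonterminals(self, tree4):
        """4 leaves + 2 internals + root = 7 node nonterminals plus the
        neutral background."""
        g = dless_hmm(tree4, jukes_cantor(), slow_scale=0.3)
        nts = g.emitting_nonterminals
        assert len(nts) == 8 and "bg" in nts

    def test_one_hybrid_per_node(self, tree4):
        g = dless_hmm(tree4, jukes_cantor())
        hybrids = [c for c in g.chains if isinstance(c, HybridChain)]
        assert len(hybrids) == 7

    def test_root_nonterminal_scales_every_branch(self, tree4):
        g = dless_hmm(tree4, jukes_cantor(1.0), slow_scale=0.5)
        hybrids = {c.terminals[0]: c for c in g.chains
                   if isinstance(c, HybridChain)}
        root_h = hybrids["chain_root"]
        labels = [n.label for n in tree4.nodes_preorder()]
        assert all(lbl in root_h.components for lbl in labels)
        comp = root_h.resolve("A")
        q = instantiate_matrix(comp, g.params).Q
        base = instantiate_matrix(root_h.default, g.params).Q
        assert np.allclose(q, 0.5 * base)

    def test_leaf_nonterminal_scales_one_branch(self, tree4):
        g = dless_hmm(tree4, jukes_cantor())
        hybrids = {c.terminals[0]: c for c in g.chains
                   if isinstance(c, HybridChain)}
        leaf_h = hybrids["chain_A"]
        assert set(leaf_h.components) == {"A"}


class TestNielsenYang:
    def test_synonymous_transition_rate(self):
        """AAA->AAG (Lys->Lys, transition at codon position 3) has rate
        kappa * pi_AAG; synonymy checked against biopython translation."""
        from Bio.Seq import Seq

        assert str(Seq("AAA").translate()) == str(Seq("AAG").translate())
        kappa, n = 3.0, 61
        c = nielsen_yang(kappa=kappa, omega=0.5)
        rm = instantiate_matrix(c, chain_params(c))
        i = rm.index()
        rate = rm.Q[i[(("a", "a", "a"), None)], i[(("a", "a", "g"), None)]]
        assert rate == pytest.approx(kappa / n)

    def test_nonsynonymous_transversion_rate(self):
        from Bio.Seq import Seq

        assert str(Seq("AAA").translate()) != str(Seq("AAT").translate())
        c = nielsen_yang(kappa=3.0, omega=0.5)
        rm = instantiate_matrix(c, chain_params(c))
        i = rm.index()
        rate = rm.Q[i[(("a", "a", "a"), None)], i[(("a", "a", "t"), None)]]
        assert rate == pytest.approx(0.5 / 61)

    def test_multi_nucleotide_change_forbidden(self):
        c = nielsen_yang()
        rm = instantiate_matrix(c, chain_params(c))
        i = rm.index()
        assert rm.Q[i[(("a", "a", "a"), None)],
                    i[(("a", "c", "g"), None)]] == 0.0

    def test_parameter_collapse_uniformity(self):
        c = nielsen_yang(kappa=1.0, omega=1.0)
        rm = instantiate_matrix(c, chain_params(c))
        off = rm.Q[~np.eye(61, dtype=bool)]
        vals = np.unique(np.round(off[off > 0], 12))
        assert len(vals) == 1

    def test_reversibility(self):
        """pi_i q_ij = pi_j q_ji for every pair (detailed balance)."""
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(61))
        c = nielsen_yang(kappa=2.5, omega=0.3, pi=pi)
        rm = instantiate_matrix(c, chain_params(c))
        flux = rm.pi[:, None] * rm.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_neighbor_sparsity(self):
        """Each codon has at most 9 single-nucleotide neighbors: at most
        549 nonzero off-diagonal entries over 61 states."""
        c = nielsen_yang()
        rm = instantiate_matrix(c, chain_params(c))
        nnz = np.count_nonzero(rm.Q[~np.eye(61, dtype=bool)])
        assert nnz <= 549
        per_row = (rm.Q > 0).sum(axis=1)
        assert per_row.max() <= 9

    def test_alternate_genetic_code_changes_synonymy(self):
        std = genetic_code("Standard")
        mito = genetic_code("Vertebrate Mitochondrial")
        assert len(sense_codons(std)) == 61
        assert len(sense_codons(mito)) == 60  # AGA/AGG are stops, TGA is Trp
        assert codon_pair_type("aga", "agg", std)["synonymous"]
        assert std["tga"] == "*" and mito["tga"] == "W"

    def test_codon_frequency_helper(self):
        freqs = codon_frequencies(["aaagggaaa", "aaaccctga"],
                                  pseudocount=0.0)
        codons = sense_codons(genetic_code("Standard"))
        assert freqs[codons.index("aaa")] == pytest.approx(3 / 5)
        assert abs(freqs.sum() - 1.0) < 1e-12

    def test_bad_pi_rejected(self):
        with pytest.raises(ValueError):
            nielsen_yang(pi=np.ones(61))


class TestConstructorMacroEquivalence:
    """The native constructors produce the same model the macro listings
    expand to (same matrices, parameters and transition structure)."""

    def test_jc69(self, data_dir):
        g = read_grammar(data_dir / "jc69.eg")
        c = jukes_cantor(1.0)
        rm_macro = instantiate_matrix(g.chains[0], g.params)
        rm_native = instantiate_matrix(c, chain_params(c))
        assert np.array_equal(rm_macro.Q, rm_native.Q)
        assert rm_macro.states == rm_native.states

    def test_raser(self, data_dir):
        g = read_grammar(data_dir / "raser.eg")
        c = raser_chain()
        rm_macro = instantiate_matrix(g.chains[0], g.params)
        rm_native = instantiate_matrix(c, chain_params(c))
        assert np.allclose(rm_macro.Q, rm_native.Q, atol=1e-15)
        assert rm_macro.states == rm_native.states
        assert g.chains[0].hidden_row == c.hidden_row == "CLASS"
        assert g.chains[0].hidden_labels == c.hidden_labels == ("s", "f")

    def test_phastcons_k3(self, data_dir, tree3):
        g_macro = read_grammar(data_dir / "phastcons.eg",
                               param_aliases=ALIASES)
        g_native = phastcons_hmm(3, jukes_cantor(1.0), [0.001] * 3, 0.9)
        assert set(g_macro.params.free_parameters) == \
            set(g_native.params.free_parameters)
        for cm, cn in zip(g_macro.chains, g_native.chains):
            qm = instantiate_matrix(cm, g_macro.params).Q
            qn = instantiate_matrix(cn, g_native.params).Q
            assert np.allclose(qm, qn, atol=1e-18)
        em = CompiledGrammar(g_macro, tree3).hmm()
        en = CompiledGrammar(g_native, tree3).hmm()
        assert em.states == en.states
        assert np.allclose(em.T, en.T) and np.allclose(em.init, en.init)
        assert np.allclose(em.endw, en.endw)
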