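"""Inside/outside, forward/backward, CYK and EM training, checked
against explicit parse-enumeration oracles on small inputs."""

import numpy as np
import pytest

from phylogrammar import (DNA, ParamExpr, chain_params, cyk, em_train,
                          forward_backward, inside, jukes_cantor,
                          phastcons_hmm, raser_chain, read_grammar,
                          simulate_alignment, single_chain_grammar,
                          felsenstein_likelihood, annotate)
from phylogrammar.chain import Chain
from phylogrammar.grammar import Grammar, Rule, RuleKind
from phylogrammar.inference import CompiledGrammar, GrammarStructureError
from phylogrammar.params import ParamSet

from conftest import enumeration_total_likelihood, enumerate_parses


def pair_chain(rate_name="v", seed=1.0):
    """2-column chain: one position mutates at a time, JC-style."""
    c = Chain(("L", "R"), DNA, seeds={rate_name: seed})
    for t1 in DNA.tokens:
        for t2 in DNA.tokens:
            for t3 in DNA.tokens:
                for t4 in DNA.tokens:
                    if (t1, t2) != (t3, t4) and \
                            int(t1 != t3) + int(t2 != t4) == 1:
                        c.mutate[((t1, t2), None), ((t3, t4), None)] = \
                            ParamExpr.of(rate_name)
    return c


def pair_grammar(with_bifurcation=False):
    """Toy nested-structure grammar: S emits pairs (P), single columns
    (U), optionally bifurcates, or ends."""
    pc = pair_chain()
    uc = jukes_cantor(0.8)
    params = chain_params(pc, uc)
    rules = [
        Rule(RuleKind.TRANSITION, "start", rhs=("S",), prob=ParamExpr.of(1)),
        Rule(RuleKind.TRANSITION, "S", rhs=("P",), prob=ParamExpr.of(0.35)),
        Rule(RuleKind.TRANSITION, "S", rhs=("U",), prob=ParamExpr.of(0.35)),
        Rule(RuleKind.END, "S", prob=ParamExpr.of(0.2)),
        Rule(RuleKind.EMISSION, "P", left_terms=("L",), right_terms=("R",),
             inner="P*", prob=ParamExpr.of(1)),
        Rule(RuleKind.RETURN, "P*", rhs=("P",), prob=ParamExpr.of(1)),
        Rule(RuleKind.TRANSITION, "P", rhs=("S",), prob=ParamExpr.of(1)),
        Rule(RuleKind.EMISSION, "U", left_terms=("NUC",), inner="U*",
             prob=ParamExpr.of(1)),
        Rule(RuleKind.RETURN, "U*", rhs=("U",), prob=ParamExpr.of(1)),
        Rule(RuleKind.TRANSITION, "U", rhs=("S",), prob=ParamExpr.of(1)),
    ]
    if with_bifurcation:
        rules.insert(4, Rule(RuleKind.TRANSITION, "S", rhs=("B",),
                             prob=ParamExpr.of(0.1)))
        rules.append(Rule(RuleKind.BIFURCATION, "B", rhs=("P", "U"),
                          prob=ParamExpr.of(1)))
    return Grammar("toypair", DNA, [pc, uc], rules, params)


class TestInside:
    def test_single_parse_grammar_equals_column_likelihood(self, tree3):
        g = single_chain_grammar(jukes_cantor(0.5))
        rows = {"A": "a", "B": "c", "C": "g"}
        _, ll = inside(g, rows, tree3)
        col = {k: (v,) for k, v in rows.items()}
        f = felsenstein_likelihood(col, g.chains[0], tree3, g.params)
        # one derivation: start->E (1), emit, end (1)
        assert ll == pytest.approx(np.log(f), rel=1e-12)

    def test_hmm_matches_path_enumeration(self, tree3):
        """3 columns under a 2-state rate-multiplier HMM: inside equals
        the brute-force sum over the 2^3 hidden-state paths."""
        g = phastcons_hmm(2, jukes_cantor(1.0), [0.3, 2.0], 0.9)
        rows = {"A": "aac", "B": "aat", "C": "atc"}
        _, ll = inside(g, rows, tree3)
        want, _ = enumeration_total_likelihood(g, rows, tree3)
        assert ll == pytest.approx(np.log(want), rel=1e-9)

    @pytest.mark.parametrize("bif", [False, True])
    def test_pair_grammar_matches_parse_enumeration(self, tree3, bif):
        g = pair_grammar(with_bifurcation=bif)
        rows = {"A": "aacgt", "B": "aacgc", "C": "atcga"}
        _, ll = inside(g, rows, tree3)
        want, _ = enumeration_total_likelihood(g, rows, tree3)
        assert ll == pytest.approx(np.log(want), rel=1e-9)

    def test_band_at_alignment_length_is_inactive(self, tree3):
        g = pair_grammar()
        rows = {"A": "aacgt", "B": "aacgc", "C": "atcga"}
        _, unbanded = inside(g, rows, tree3)
        _, banded = inside(g, rows, tree3, band=len(rows["A"]))
        assert banded == pytest.approx(unbanded, rel=1e-12)

    def test_banding_monotone_in_band_width(self, tree3):
        g = pair_grammar()
        rows = {"A": "aacgtg", "B": "aacgcg", "C": "atcgat"}
        lls = [inside(g, rows, tree3, band=N)[1] for N in (2, 3, 4, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))
        _, unbanded = inside(g, rows, tree3)
        assert lls[-1] == pytest.approx(unbanded, rel=1e-12)

    def test_unknown_row_rejected(self, tree3):
        g = single_chain_grammar(jukes_cantor())
        with pytest.raises(KeyError, match="no tree leaf"):
            inside(g, {"A": "a", "B": "c", "C": "g", "Z": "t"}, tree3)


class TestForwardBackward:
    def test_forward_equals_inside(self, tree3, data_dir):
        for g in (phastcons_hmm(2, jukes_cantor(), [0.3, 2.0]),
                  read_grammar(data_dir / "raser.eg")):
            rows = {"A": "aacg", "B": "aacc", "C": "atcg"}
            _, ll_in = inside(g, rows, tree3)
            _, ll_fw, _ = forward_backward(g, rows, tree3)
            assert ll_fw == pytest.approx(ll_in, rel=1e-9)

    def test_rejects_scfg(self, tree3):
        g = pair_grammar()
        with pytest.raises(GrammarStructureError, match="phylo-HMM"):
            forward_backward(g, {"A": "aa", "B": "aa", "C": "aa"}, tree3)

    def test_single_state_posterior_is_one(self, tree3):
        g = phastcons_hmm(1, jukes_cantor(), [1.0], stay_prob=1.0)
        _, _, posts = forward_backward(g, {"A": "aacg", "B": "aacc",
                                           "C": "atcg"}, tree3)
        assert np.allclose(posts["1"], 1.0)

    def test_symmetric_states_posterior_half(self, tree3):
        """Identical chains in both states: posteriors are exactly 1/2."""
        g = phastcons_hmm(2, jukes_cantor(), [1.0, 1.0], 0.9)
        _, _, posts = forward_backward(g, {"A": "aacg", "B": "aacc",
                                           "C": "atcg"}, tree3)
        assert np.allclose(posts["1"], 0.5, atol=1e-12)

    def test_posteriors_match_enumeration(self, tree3):
        """Per-column posteriors from forward/backward equal the
        parse-enumeration posteriors on a short alignment."""
        from phylogrammar import felsenstein_likelihood as fl

        g = phastcons_hmm(2, jukes_cantor(1.0), [0.2, 3.0], 0.8)
        rows = {"A": "aaacgtgt", "B": "aaacctgc", "C": "ataccagc"}
        L = len(rows["A"])
        _, _, posts = forward_backward(g, rows, tree3)
        total = 0.0
        col_mass = {nt: np.zeros(L) for nt in ("1", "2")}
        chain_of = {"1": g.chains[0], "2": g.chains[1]}
        params = g.params.copy()
        params.normalize_pgroups()
        for w, events in enumerate_parses(g, L):
            for nt, cols in events:
                col = {k: (v[cols[0]],) for k, v in rows.items()}
                w *= fl(col, chain_of[nt], tree3, params)
            total += w
            for nt, cols in events:
                col_mass[nt][cols[0]] += w
        for nt in ("1", "2"):
            assert np.allclose(posts[nt], col_mass[nt] / total, rtol=1e-9)

    def test_column_posteriors_sum_to_one(self, tree4):
        g = phastcons_hmm(3, jukes_cantor(), [0.3, 1.0, 2.5], 0.85)
        aln, _ = simulate_alignment(g, tree4, 40, seed=5)
        _, _, posts = forward_backward(g, aln, tree4)
        sums = sum(posts.values())
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestCYK:
    def test_single_parse_score_equals_inside(self, tree3):
        g = single_chain_grammar(jukes_cantor(0.5))
        rows = {"A": "ac", "B": "cc", "C": "gc"}
        _, ll = inside(g, rows, tree3)
        p = cyk(g, rows, tree3)
        assert p.log_score == pytest.approx(ll, rel=1e-12)

    def test_best_parse_matches_exhaustive_enumeration(self, tree3):
        g = pair_grammar()
        rows = {"A": "aacgtt", "B": "aacgtc", "C": "atcgta"}
        p = cyk(g, rows, tree3)
        _, ll = inside(g, rows, tree3)
        assert p.log_score <= ll + 1e-12
        _, (best_ll, best_events) = enumeration_total_likelihood(
            g, rows, tree3)
        assert p.log_score == pytest.approx(best_ll, rel=1e-9)
        assert sorted((e.nt, e.cols) for e in p.events) == \
            sorted((nt, cols) for nt, cols in best_events)

    def test_deterministic_tie_breaking(self, tree3):
        g = phastcons_hmm(2, jukes_cantor(), [1.0, 1.0], 0.9)
        rows = {"A": "aacg", "B": "aacc", "C": "atcg"}
        p1 = cyk(g, rows, tree3)
        p2 = cyk(g, rows, tree3)
        assert p1.labels == p2.labels and p1.log_score == p2.log_score


class TestEM:
    def test_trace_monotone_on_self_simulated_data(self, tree4):
        g = phastcons_hmm(2, jukes_cantor(1.0), [0.3, 2.0], 0.9)
        aln, _ = simulate_alignment(g, tree4, 400, seed=3)
        res = em_train(g, [aln], [tree4], max_iter=8)
        assert all(b >= a - 1e-6 * abs(a)
                   for a, b in zip(res.trace, res.trace[1:]))

    def test_rate_moves_toward_truth(self, tree4):
        true_u = 0.3
        g = single_chain_grammar(jukes_cantor(true_u))
        aln, _ = simulate_alignment(g, tree4, 1500, seed=7)
        g0 = single_chain_grammar(jukes_cantor(1.0))
        res = em_train(g0, [aln], [tree4], max_iter=20)
        got = res.grammar.params.rates["u"]
        assert abs(got - true_u) < abs(1.0 - true_u) / 3

    def test_multiple_alignments_pool_counts(self, tree4):
        g = single_chain_grammar(jukes_cantor(0.4))
        a1, _ = simulate_alignment(g, tree4, 300, seed=1)
        a2, _ = simulate_alignment(g, tree4, 300, seed=2)
        res = em_train(single_chain_grammar(jukes_cantor(1.0)),
                       [a1, a2], [tree4, tree4], max_iter=10)
        assert 0.2 < res.grammar.params.rates["u"] < 0.7

    def test_scfg_em_monotone(self, tree3):
        g = pair_grammar()
        rows = {"A": "aacgtt", "B": "aacgtc", "C": "atcgta"}
        res = em_train(g, [rows], [tree3], max_iter=5)
        assert all(b >= a - 1e-6 * abs(a)
                   for a, b in zip(res.trace, res.trace[1:]))

    def test_no_data_columns_rejected(self, tree3):
        g = single_chain_grammar(jukes_cantor())
        with pytest.raises(ValueError, match="no data columns"):
            em_train(g, [], [], max_iter=2)


class TestAnnotate:
    def test_single_state_single_feature(self, tree3):
        g = phastcons_hmm(1, jukes_cantor(), [1.0], stay_prob=1.0)
        ann = annotate(g, {"A": "aacgt", "B": "aacgc", "C": "atcga"},
                       tree3)
        assert len(ann.gff) == 1
        assert (ann.gff[0].start, ann.gff[0].end) == (1, 5)
        assert ann.gc_label == "11111"

    def test_latent_class_rows_over_class_labels(self, tree3, data_dir):
        g = read_grammar(data_dir / "raser.eg")
        ann = annotate(g, {"A": "aacg", "B": "aacc", "C": "atcg"}, tree3)
        assert set(ann.gr_class) == {"A", "B", "C"}
        for tags in ann.gr_class.values():
            assert set(tags) == {"CLASS"}
            assert set(tags["CLASS"]) <= {"s", "f"}

    def test_ancestral_sequences_produced(self, tree3):
        g = single_chain_grammar(jukes_cantor(0.5))
        ann = annotate(g, {"A": "aacg", "B": "aacc", "C": "atcg"},
                       tree3, ancestral=True)
        assert set(ann.ancestral) == {"root", "n1"}
        assert len(ann.ancestral["n1"]) == 4
        assert set(ann.ancestral["n1"]) <= set("acgt")
        assert np.all(ann.ancestral_pp["n1"] > 0.25)
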