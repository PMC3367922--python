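"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by enumeration or
closed form, independent of the package's dynamic-programming code
paths, so agreement is evidence of correctness rather than tautology.
"""

from pathlib import Path

import itertools

import numpy as np
import pytest
import scipy.linalg

from phylogrammar import (Grammar, ParamSet, PhyloTree, chain_params,
                          instantiate_matrix, parse_newick)
from phylogrammar.chain import Chain
from phylogrammar.grammar import RuleKind

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def tree3() -> PhyloTree:
    return parse_newick("((A:0.2,B:0.35)n1:0.15,C:0.4)root;")


@pytest.fixture
def tree4() -> PhyloTree:
    return parse_newick(
        "((A:0.3,B:0.4)n1:0.2,(C:0.25,D:0.35)n2:0.15)root;")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def leaf_indicator(chain: Chain, tokens, state):
    """Direct observation indicator, independent of the engine code."""
    toks, _cls = state
    for obs, st in zip(tokens, toks):
        if obs in chain.alphabet.tokens and obs != st:
            return 0.0
    return 1.0


def brute_force_likelihood(col, chain, tree, params):
    """Column likelihood by explicit enumeration over every ancestral
    state assignment (exponential; use only on tiny trees)."""
    rm = instantiate_matrix(chain, params)
    n = rm.n
    nodes = tree.nodes_preorder()
    internal = [nd for nd in nodes if not nd.is_leaf]
    leaves = [nd for nd in nodes if nd.is_leaf]
    P = {id(nd): scipy.linalg.expm(rm.Q * nd.length)
         for nd in nodes if nd.parent is not None}
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internal)):
        amap = {id(nd): s for nd, s in zip(internal, assign)}
        w = rm.pi[amap[id(tree.root)]]
        for nd in internal:
            if nd.parent is not None:
                w *= P[id(nd)][amap[id(nd.parent)], amap[id(nd)]]
        for leaf in leaves:
            tok = col[leaf.label]
            tok = tok if isinstance(tok, tuple) else (tok,)
            s = 0.0
            for j in range(n):
                s += P[id(leaf)][amap[id(leaf.parent)], j] * \
                    leaf_indicator(chain, tok, rm.states[j])
            w *= s
        total += w
    return total


def brute_force_root_posterior(col, chain, tree, params):
    """Bayes-rule enumeration of the root-state posterior."""
    rm = instantiate_matrix(chain, params)
    post = np.zeros(rm.n)
    for r in range(rm.n):
        post[r] = rm.pi[r] * _cond_lik_below(col, chain, rm, tree.root, r)
    return post / post.sum()


def _cond_lik_below(col, chain, rm, node, state):
    P_children = {id(c): scipy.linalg.expm(rm.Q * c.length)
                  for c in node.children}
    w = 1.0
    for c in node.children:
        s = 0.0
        for j in range(rm.n):
            if c.is_leaf:
                tok = col[c.label]
                tok = tok if isinstance(tok, tuple) else (tok,)
                down = leaf_indicator(chain, tok, rm.states[j])
            else:
                down = _cond_lik_below(col, chain, rm, c, j)
            s += P_children[id(c)][state, j] * down
        w *= s
    return w


def enumerate_parses(g: Grammar, L: int, max_depth: int = 40):
    """All derivations of L columns: list of (rule-weight product,
    [(nt, cols)...]).  Independent recursive enumeration (no DP)."""
    params = g.params.copy()
    params.normalize_pgroups()
    emits = {}
    returns = {r.lhs: r for r in g.rules if r.kind is RuleKind.RETURN}
    for r in g.rules:
        if r.kind is RuleKind.EMISSION:
            emits[r.lhs] = r

    def post_rules(nt):
        r = emits[nt]
        tgt = returns[r.inner].rhs[0] if r.inner in returns else \
            (r.inner[:-1] if r.inner.endswith("*") else r.inner)
        return [p for p in g.rules if p.lhs == tgt
                and p.kind not in (RuleKind.EMISSION, RuleKind.RETURN)]

    def derive(sym, i, j, depth):
        """Yield (weight, events) for sym spanning columns i..j."""
        if depth > max_depth:
            return
        if sym in emits:
            r = emits[sym]
            wl, wr = len(r.left_terms), len(r.right_terms)
            if j - i < wl + wr:
                return
            cols = tuple(range(i, i + wl)) + tuple(range(j - wr, j))
            for w, evs in derive_rules(post_rules(sym), i + wl, j - wr,
                                       depth + 1):
                yield w, [(sym, cols)] + evs
        else:
            rules = [p for p in g.rules if p.lhs == sym
                     and p.kind is not RuleKind.RETURN]
            yield from derive_rules(rules, i, j, depth)

    def derive_rules(rules, i, j, depth):
        for r in rules:
            w0 = r.prob.value(params)
            if w0 == 0:
                continue
            if r.kind is RuleKind.END:
                if i == j:
                    yield w0, []
            elif r.kind is RuleKind.TRANSITION:
                for w, evs in derive(r.rhs[0], i, j, depth + 1):
                    yield w0 * w, evs
            elif r.kind is RuleKind.BIFURCATION:
                a, b = r.rhs
                for m in range(i, j + 1):
                    for wa, ea in derive(a, i, m, depth + 1):
                        for wb, eb in derive(b, m, j, depth + 1):
                            yield w0 * wa * wb, ea + eb

    return list(derive(g.start, 0, L, 0))


def enumeration_total_likelihood(g, rows, tree):
    """Sum over all parses of rule weights times column likelihoods —
    the enumeration oracle for the inside algorithm."""
    from phylogrammar import felsenstein_likelihood

    L = len(next(iter(rows.values())))
    chain_of = {}
    for r in g.rules:
        if r.kind is RuleKind.EMISSION:
            chain_of[r.lhs] = g.chain_for_terminal(
                (r.left_terms + r.right_terms)[0])
    params = g.params.copy()
    params.normalize_pgroups()
    total = 0.0
    best = (-np.inf, None)
    for w, events in enumerate_parses(g, L):
        for nt, cols in events:
            chain = chain_of[nt]
            col = {name: tuple(row[c].lower() for c in cols)
                   for name, row in rows.items()}
            w *= felsenstein_likelihood(col, chain, tree, params)
        total += w
        if w > 0 and np.log(w) > best[0]:
            best = (np.log(w), events)
    return total, best
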