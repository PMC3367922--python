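"""Grammar-level dynamic programming.

A grammar compiles to one of two engines:

* phylo-HMM: forward/backward/Viterbi over columns, linear in alignment
  length — the workhorse for training and annotation;
* phylo-SCFG: inside/outside/CYK over column spans, with optional
  pairing-distance banding (``band=N`` excludes any pair emission whose
  columns are more than N apart, bounding time and memory).

Emitting nonterminals follow the convention of the grammar dialect:
entering an emitting nonterminal emits its column tuple once, after which
its non-emission rules (reached through the starred symbol's return rule)
decide what happens next.  End-rule weights are unnormalized; the model
is normalized globally by the dynamic programming, so "likelihoods" are
derivation weights and posteriors are ratios of them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .chain import Chain, HybridChain
from .grammar import (Grammar, Rule, RuleKind, classify_grammar, PHYLO_HMM,
                      PHYLO_SCFG)
from .likelihood import PhyloEmitter
from .params import ParamSet
from .tree import PhyloTree

__all__ = ["CompiledGrammar", "HMMEngine", "SCFGEngine", "Parse",
           "EmissionEvent", "inside", "forward_backward", "cyk",
           "alignment_rows"]

_NEG_INF = -np.inf


def alignment_rows(aln) -> Dict[str, str]:
    """Accept either a mapping name->row or a Stockholm alignment."""
    if hasattr(aln, "rows"):
        return dict(aln.rows)
    return dict(aln)


@dataclass
class EmissionEvent:
    nt: str
    cols: Tuple[int, ...]       # 0-based alignment columns, terminal order


@dataclass
class Parse:
    """A single derivation: per-column nonterminal labels plus the list of
    emission events, with its log weight."""

    labels: List[Optional[str]]
    events: List[EmissionEvent]
    log_score: float
    rule_counts: Dict[int, float] = field(default_factory=dict)


class GrammarStructureError(ValueError):
    pass


@dataclass
class _Emit:
    nt: str
    chain: Union[Chain, HybridChain]
    left: Tuple[str, ...]
    right: Tuple[str, ...]
    post: List[Rule]

    @property
    def wl(self) -> int:
        return len(self.left)

    @property
    def wr(self) -> int:
        return len(self.right)

    @property
    def width(self) -> int:
        return self.wl + self.wr


class CompiledGrammar:
    """A grammar bound to a tree and numeric parameters."""

    def __init__(self, grammar: Grammar, tree: PhyloTree,
                 params: Optional[ParamSet] = None,
                 band: Optional[int] = None):
        self.g = grammar
        self.tree = tree
        self.params = (params if params is not None else grammar.params).copy()
        self.params.normalize_pgroups()
        self.band = band
        self.kind = classify_grammar(grammar)
        self._build()

    # ------------------------------------------------------------------
    def _build(self) -> None:
        g = self.g
        self.emits: Dict[str, _Emit] = {}
        returns = {r.lhs: r for r in g.rules if r.kind is RuleKind.RETURN}
        for r in g.rules:
            if r.kind is not RuleKind.EMISSION:
                continue
            if r.lhs in self.emits:
                raise GrammarStructureError(
                    f"nonterminal {r.lhs!r} has two emission rules")
            terms = r.left_terms + r.right_terms
            chain = g.chain_for_terminal(terms[0])
            if tuple(terms) != tuple(chain.terminals):
                raise GrammarStructureError(
                    f"emission from {r.lhs!r} must list the chain's "
                    f"pseudoterminals {chain.terminals} in order")
            # the starred symbol routes onward through its return rule
            if r.inner in returns:
                post_sym = returns[r.inner].rhs[0]
            else:
                post_sym = r.inner[:-1] if r.inner.endswith("*") else r.inner
            post = [p for p in g.rules_from(post_sym)
                    if p.kind not in (RuleKind.EMISSION, RuleKind.RETURN)]
            self.emits[r.lhs] = _Emit(r.lhs, chain, r.left_terms,
                                      r.right_terms, post)
        self.null_rules: Dict[str, List[Rule]] = {}
        for nt in g.nonterminals:
            if nt not in self.emits and not nt.endswith("*"):
                self.null_rules[nt] = [
                    p for p in g.rules_from(nt)
                    if p.kind not in (RuleKind.RETURN,)]
        self.weights: Dict[int, float] = {
            id(r): r.prob.value(self.params) for r in g.rules}

    def weight(self, rule: Rule) -> float:
        return self.weights[id(rule)]

    # ------------------------------------------------------------------
    def hmm(self) -> "HMMEngine":
        if self.kind != PHYLO_HMM:
            raise GrammarStructureError(
                "forward/backward requires a phylo-HMM grammar; this one "
                "classifies as phylo-SCFG")
        return HMMEngine(self)

    def scfg(self) -> "SCFGEngine":
        return SCFGEngine(self)

    # ------------------------------------------------------------------
    def null_paths(self, sym: str):
        """All rule paths from a (possibly null) symbol to an emitting
        nonterminal or to the end, as (target|None, weight, rules)."""
        out = []

        def walk(s: str, w: float, path: Tuple[Rule, ...], seen):
            if s in self.emits:
                out.append((s, w, path))
                return
            if s in seen:
                raise GrammarStructureError(
                    f"cycle of non-emitting transitions through {s!r}")
            rules = self.null_rules.get(s)
            if rules is None:
                raise GrammarStructureError(f"unknown symbol {s!r}")
            for r in rules:
                rw = w * self.weight(r)
                if r.kind is RuleKind.TRANSITION:
                    walk(r.rhs[0], rw, path + (r,), seen | {s})
                elif r.kind is RuleKind.END:
                    out.append((None, rw, path + (r,)))
                else:
                    raise GrammarStructureError(
                        "bifurcation reached in HMM null-closure")

        walk(sym, 1.0, (), frozenset())
        return out

    def check_alignment(self, rows: Dict[str, str]) -> None:
        leaf_names = set(self.tree.leaf_names)
        for name in rows:
            if name not in leaf_names:
                raise KeyError(
                    f"alignment row {name!r} has no tree leaf")


# ---------------------------------------------------------------------------
# phylo-HMM engine
# ---------------------------------------------------------------------------

def _leaf_tuples(rows: Dict[str, str], positions: Sequence[Tuple[int, ...]]):
    """Per-leaf token tuples for a list of column-index tuples."""
    return {leaf: [tuple(row[c].lower() for c in cols) for cols in positions]
            for leaf, row in rows.items()}


class HMMEngine:
    """Forward/backward/Viterbi for phylo-HMM grammars.

    Emission log-likelihoods are computed once per state via vectorized
    pruning; the sequential recursions then run over column positions.
    Right-emitting HMMs are handled by running on reversed columns.
    """

    def __init__(self, cg: CompiledGrammar):
        self.cg = cg
        self.states = list(cg.emits)
        self.K = len(self.states)
        sidx = {s: i for i, s in enumerate(self.states)}
        self.widths = np.array([cg.emits[s].width for s in self.states])
        self.reversed = any(cg.emits[s].right for s in self.states)

        self.init = np.zeros(self.K)
        self.init_paths: Dict[int, list] = {i: [] for i in range(self.K)}
        self.empty_weight = 0.0
        for tgt, w, path in cg.null_paths(cg.g.start):
            if tgt is None:
                self.empty_weight += w
            else:
                self.init[sidx[tgt]] += w
                self.init_paths[sidx[tgt]].append((w, path))

        self.T = np.zeros((self.K, self.K))
        self.endw = np.zeros(self.K)
        self.trans_paths: Dict[Tuple[int, int], list] = {}
        self.end_paths: Dict[int, list] = {i: [] for i in range(self.K)}
        for i, s in enumerate(self.states):
            for r in cg.emits[s].post:
                rw = cg.weight(r)
                if r.kind is RuleKind.END:
                    self.endw[i] += rw
                    self.end_paths[i].append((rw, (r,)))
                elif r.kind is RuleKind.TRANSITION:
                    for tgt, w, path in cg.null_paths(r.rhs[0]):
                        w *= rw
                        if tgt is None:
                            self.endw[i] += w
                            self.end_paths[i].append((w, (r,) + path))
                        else:
                            j = sidx[tgt]
                            self.T[i, j] += w
                            self.trans_paths.setdefault((i, j), []).append(
                                (w, (r,) + path))
                else:
                    raise GrammarStructureError(
                        "bifurcation in a phylo-HMM post-rule set")
        self._emitters: Dict[str, PhyloEmitter] = {}
        self._fb = None

    # ------------------------------------------------------------------
    def _emission_logliks(self, rows: Dict[str, str]) -> List[np.ndarray]:
        self.cg.check_alignment(rows)
        L = len(next(iter(rows.values()))) if rows else 0
        if self.reversed:
            rows = {k: v[::-1] for k, v in rows.items()}
        self.L = L
        self.rows = rows
        out = []
        for s in self.states:
            em = self.cg.emits[s]
            w = em.width
            positions = [tuple(range(p, p + w)) for p in range(0, L - w + 1)]
            emitter = PhyloEmitter(em.chain, self.cg.tree, self.cg.params)
            self._emitters[s] = emitter
            if positions:
                ll = emitter.fit(_leaf_tuples(rows, positions))
            else:
                ll = np.zeros(0)
            out.append(ll)
        self.elog = out
        return out

    # ------------------------------------------------------------------
    def forward(self, rows: Dict[str, str]) -> float:
        """Total log derivation weight over alignments of this length."""
        self._emission_logliks(rows)
        L, K = self.L, self.K
        with np.errstate(divide="ignore"):
            linit = np.log(self.init)
            lT = np.log(self.T)
            lend = np.log(self.endw)
        en = np.full((L + 1, K), _NEG_INF)
        en[0] = linit
        total = _NEG_INF
        if L == 0:
            return float(np.log(self.empty_weight)) \
                if self.empty_weight > 0 else _NEG_INF
        for pos in range(L):
            emitted = np.full(K, _NEG_INF)
            for k in range(K):
                w = self.widths[k]
                if pos + w <= L and np.isfinite(en[pos, k]):
                    emitted[k] = en[pos, k] + self.elog[k][pos]
            if not np.any(np.isfinite(emitted)):
                continue
            for w in np.unique(self.widths):
                src = np.where((self.widths == w)
                               & np.isfinite(emitted))[0]
                if not len(src):
                    continue
                if pos + w == L:
                    fin = emitted[src] + lend[src]
                    total = np.logaddexp(total, _logsumexp(fin))
                if pos + w < L:
                    contrib = _logsumexp_mat(emitted[src, None] + lT[src, :])
                    en[pos + w] = np.logaddexp(en[pos + w], contrib)
        self._forward = en
        self._total = float(total)
        return float(total)

    def backward(self) -> np.ndarray:
        L, K = self.L, self.K
        with np.errstate(divide="ignore"):
            lT = np.log(self.T)
            lend = np.log(self.endw)
        bw = np.full((L + 1, K), _NEG_INF)
        for pos in range(L, -1, -1):
            for k in range(K):
                w = self.widths[k]
                if pos + w > L:
                    continue
                cont = lend[k] if pos + w == L else _NEG_INF
                nxt = bw[pos + w]
                fin = np.isfinite(nxt)
                if np.any(fin):
                    cont = np.logaddexp(
                        cont, _logsumexp(lT[k, fin] + nxt[fin]))
                bw[pos, k] = self.elog[k][pos] + cont
        self._backward = bw
        return bw

    # ------------------------------------------------------------------
    def forward_backward(self, rows: Dict[str, str]):
        """Returns (total log-likelihood, per-column posteriors (L, K),
        per-emission-start posteriors gamma (L+1, K))."""
        total = self.forward(rows)
        self.backward()
        L, K = self.L, self.K
        gamma = np.zeros((L + 1, K))
        fin = np.isfinite(self._forward) & np.isfinite(self._backward)
        gamma[fin] = np.exp(self._forward[fin] + self._backward[fin] - total)
        col_post = np.zeros((L, K))
        for k in range(K):
            w = self.widths[k]
            for d in range(w):
                col_post[d:L - w + 1 + d, k] += gamma[:L - w + 1, k]
        if self.reversed:
            col_post = col_post[::-1]
        self._fb = (total, col_post, gamma)
        return total, col_post, gamma

    def expected_counts(self):
        """E-step sufficient statistics given a completed
        forward_backward: rule usages and per-chain emission weights."""
        total, col_post, gamma = self._fb
        L, K = self.L, self.K
        rule_usage: Dict[int, float] = {}

        def add_paths(paths, mass_of_weight):
            for w, path in paths:
                m = mass_of_weight(w)
                for r in path:
                    rule_usage[id(r)] = rule_usage.get(id(r), 0.0) + m

        for k in range(K):
            if np.isfinite(self._backward[0, k]) and self.init[k] > 0:
                mass = np.exp(np.log(self.init[k]) + self._backward[0, k]
                              - total)
                add_paths(self.init_paths[k],
                          lambda w, mk=mass, ik=self.init[k]: mk * w / ik)
        # transitions and ends
        with np.errstate(divide="ignore"):
            lT = np.log(self.T)
        xi = np.zeros((K, K))
        endu = np.zeros(K)
        for k in range(K):
            w = self.widths[k]
            for pos in range(L - w + 1):
                a = self._forward[pos, k]
                if not np.isfinite(a):
                    continue
                emitted = a + self.elog[k][pos]
                if pos + w == L and self.endw[k] > 0:
                    endu[k] += np.exp(emitted + np.log(self.endw[k]) - total)
                nxt = self._backward[pos + w]
                fin = np.where(np.isfinite(nxt) & (self.T[k] > 0))[0]
                for j in fin:
                    xi[k, j] += np.exp(emitted + lT[k, j] + nxt[j] - total)
        for k in range(K):
            if self.endw[k] > 0:
                add_paths(self.end_paths[k],
                          lambda w, mk=endu[k], ek=self.endw[k]: mk * w / ek)
            for j in range(K):
                if self.T[k, j] > 0:
                    add_paths(self.trans_paths.get((k, j), []),
                              lambda w, m=xi[k, j], t=self.T[k, j]: m * w / t)
        # chain emission weights: gamma over emission starts
        chain_weights = {s: gamma[:L - self.widths[i] + 1, i]
                         if L - self.widths[i] + 1 > 0 else np.zeros(0)
                         for i, s in enumerate(self.states)}
        # emission/return rules fire once per emission
        for r in self.cg.g.rules:
            if r.kind in (RuleKind.EMISSION, RuleKind.RETURN):
                base = r.lhs[:-1] if r.kind is RuleKind.RETURN else r.lhs
                if base in chain_weights:
                    rule_usage[id(r)] = rule_usage.get(id(r), 0.0) + \
                        float(chain_weights[base].sum())
        return rule_usage, chain_weights

    # ------------------------------------------------------------------
    def viterbi(self, rows: Dict[str, str]) -> Parse:
        self._emission_logliks(rows)
        L, K = self.L, self.K
        with np.errstate(divide="ignore"):
            linit = np.log(self.init)
            lT = np.log(self.T)
            lend = np.log(self.endw)
        en = np.full((L + 1, K), _NEG_INF)
        bp: Dict[Tuple[int, int], Tuple[int, int]] = {}
        en[0] = linit
        best_end, best_score = None, _NEG_INF
        for pos in range(L):
            for k in range(K):
                w = self.widths[k]
                if pos + w > L or not np.isfinite(en[pos, k]):
                    continue
                emitted = en[pos, k] + self.elog[k][pos]
                if pos + w == L:
                    sc = emitted + lend[k]
                    if sc > best_score:
                        best_score, best_end = sc, (pos, k)
                else:
                    for j in range(K):
                        sc = emitted + lT[k, j]
                        if sc > en[pos + w, j]:
                            en[pos + w, j] = sc
                            bp[(pos + w, j)] = (pos, k)
        if best_end is None:
            raise ValueError("no complete derivation for this alignment "
                             "(zero-probability continuation everywhere)")
        path = [best_end]
        while path[-1][0] > 0:
            path.append(bp[path[-1]])
        path.reverse()
        labels: List[Optional[str]] = [None] * L
        events = []
        for pos, k in path:
            s = self.states[k]
            w = self.widths[k]
            cols = tuple(range(pos, pos + w))
            if self.reversed:
                cols = tuple(L - 1 - c for c in cols)
            for c in cols:
                labels[c] = s
            events.append(EmissionEvent(s, cols))
        return Parse(labels, events, float(best_score))


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    if not np.isfinite(m):
        return _NEG_INF
    return float(m + np.log(np.exp(v - m).sum()))


def _logsumexp_mat(m: np.ndarray) -> np.ndarray:
    mx = m.max(axis=0)
    out = np.full(m.shape[1], _NEG_INF)
    fin = np.isfinite(mx)
    out[fin] = mx[fin] + np.log(
        np.exp(m[:, fin] - mx[fin]).sum(axis=0))
    return out


# ---------------------------------------------------------------------------
# phylo-SCFG engine
# ---------------------------------------------------------------------------

class SCFGEngine:
    """Inside/outside/CYK over column spans for general phylo-grammars.

    Quadratic (cubic with bifurcations) in alignment length: intended for
    the span-structured grammars and modest alignment lengths; phylo-HMM
    grammars should use :class:`HMMEngine`.  Values are derivation
    weights in linear space.
    """

    def __init__(self, cg: CompiledGrammar):
        self.cg = cg
        self._order = self._topo_order()

    def _topo_order(self):
        """Evaluation order for same-span dependencies: 'post:<nt>' and
        null '<nt>' nodes, following transition edges."""
        nodes = [f"post:{nt}" for nt in self.cg.emits] + \
            list(self.cg.null_rules)
        edges: Dict[str, List[str]] = {n: [] for n in nodes}

        def dep_of(rules, node):
            for r in rules:
                if r.kind is RuleKind.TRANSITION:
                    tgt = r.rhs[0]
                    if tgt in self.cg.null_rules:
                        edges[node].append(tgt)

        for nt, em in self.cg.emits.items():
            dep_of(em.post, f"post:{nt}")
        for nt, rules in self.cg.null_rules.items():
            dep_of(rules, nt)
        # Kahn
        order, indeg = [], {n: 0 for n in nodes}
        for n, ds in edges.items():
            for d in ds:
                indeg[d] += 1
        ready = [n for n in nodes if indeg[n] == 0]
        while ready:
            n = ready.pop()
            order.append(n)
            for d in edges[n]:
                indeg[d] -= 1
                if indeg[d] == 0:
                    ready.append(d)
        if len(order) != len(nodes):
            raise GrammarStructureError(
                "cycle of non-consuming transitions in grammar")
        return list(reversed(order))  # dependencies first

    # ------------------------------------------------------------------
    def _emission_tables(self, rows: Dict[str, str]):
        """Per emitting nt: arrays of emission likelihoods indexed by
        (i, j) span corners, and the emitters used (for EM/ancestors)."""
        self.cg.check_alignment(rows)
        L = len(next(iter(rows.values()))) if rows else 0
        self.L = L
        self.rows = rows
        self.E: Dict[str, np.ndarray] = {}
        self.emitters: Dict[str, PhyloEmitter] = {}
        self.cells: Dict[str, List[Tuple[int, int]]] = {}
        band = self.cg.band
        for nt, em in self.cg.emits.items():
            l, r = em.wl, em.wr
            cells = []
            for i in range(L + 1):
                for j in range(i + l + r, L + 1):
                    if l and r and band is not None and j - i > band:
                        continue
                    cells.append((i, j))
            # distinct column tuples (one-sided emissions repeat across j)
            tup_cols = {}
            for (i, j) in cells:
                cols = tuple(range(i, i + l)) + tuple(range(j - r, j))
                tup_cols.setdefault(cols, []).append((i, j))
            col_list = list(tup_cols)
            emitter = PhyloEmitter(em.chain, self.cg.tree, self.cg.params)
            self.emitters[nt] = emitter
            if col_list:
                ll = emitter.fit(_leaf_tuples(rows, col_list))
            else:
                ll = np.zeros(0)
            table = np.zeros((L + 1, L + 1))
            for cols, cs in tup_cols.items():
                v = np.exp(ll[col_list.index(cols)])
                for (i, j) in cs:
                    table[i, j] = v
            self.E[nt] = table
            self.cells[nt] = col_list

    # ------------------------------------------------------------------
    def inside(self, rows: Dict[str, str]) -> float:
        self._emission_tables(rows)
        L = self.L
        cg = self.cg
        V = {nt: np.zeros((L + 1, L + 1))
             for nt in list(cg.emits) + list(cg.null_rules)}
        PostV = {nt: np.zeros((L + 1, L + 1)) for nt in cg.emits}
        band = cg.band

        def rule_sum(rules, i, j):
            total = 0.0
            for r in rules:
                w = cg.weight(r)
                if w == 0:
                    continue
                if r.kind is RuleKind.TRANSITION:
                    total += w * V[r.rhs[0]][i, j]
                elif r.kind is RuleKind.END:
                    if i == j:
                        total += w
                elif r.kind is RuleKind.BIFURCATION:
                    a, b = r.rhs
                    total += w * float(V[a][i, i:j + 1] @ V[b][i:j + 1, j])
            return total

        for span in range(L + 1):
            for i in range(L - span + 1):
                j = i + span
                for node in self._order:
                    if node.startswith("post:"):
                        nt = node[5:]
                        PostV[nt][i, j] = rule_sum(cg.emits[nt].post, i, j)
                        em = cg.emits[nt]
                        l, r = em.wl, em.wr
                        # fill the enclosing emission cell (span+l+r)
                        ii, jj = i - l, j + r
                        if 0 <= ii and jj <= L:
                            if not (l and r and band is not None
                                    and jj - ii > band):
                                V[nt][ii, jj] = self.E[nt][ii, jj] * \
                                    PostV[nt][i, j]
                    else:
                        V[node][i, j] = rule_sum(cg.null_rules[node], i, j)
        self.V, self.PostV = V, PostV
        total = V[cg.g.start][0, L]
        self.total = total
        return float(np.log(total)) if total > 0 else _NEG_INF

    # ------------------------------------------------------------------
    def outside(self):
        """Outside weights; requires :meth:`inside` first."""
        L = self.L
        cg = self.cg
        V, PostV = self.V, self.PostV
        OV = {nt: np.zeros((L + 1, L + 1)) for nt in V}
        OPost = {nt: np.zeros((L + 1, L + 1)) for nt in PostV}
        OV[cg.g.start][0, L] = 1.0
        band = cg.band

        def push(rules, i, j, o):
            if o == 0:
                return
            for r in rules:
                w = cg.weight(r)
                if w == 0:
                    continue
                if r.kind is RuleKind.TRANSITION:
                    OV[r.rhs[0]][i, j] += o * w
                elif r.kind is RuleKind.BIFURCATION:
                    a, b = r.rhs
                    for m in range(i, j + 1):
                        if V[b][m, j]:
                            OV[a][i, m] += o * w * V[b][m, j]
                        if V[a][i, m]:
                            OV[b][m, j] += o * w * V[a][i, m]

        for span in range(L, -1, -1):
            for i in range(L - span + 1):
                j = i + span
                # emissions: distribute from V-cell into the Post cell
                for nt, em in cg.emits.items():
                    l, r = em.wl, em.wr
                    if span >= l + r and OV[nt][i, j]:
                        if l and r and band is not None and span > band:
                            continue
                        OPost[nt][i + l, j - r] += OV[nt][i, j] * \
                            self.E[nt][i, j]
                for node in reversed(self._order):
                    if node.startswith("post:"):
                        nt = node[5:]
                        push(cg.emits[nt].post, i, j, OPost[nt][i, j])
                    else:
                        push(cg.null_rules[node], i, j, OV[node][i, j])
        self.OV, self.OPost = OV, OPost
        return OV, OPost

    # ------------------------------------------------------------------
    def posteriors_and_counts(self):
        """Rule usages, per-column nonterminal posteriors and per-chain
        emission-cell weights, from completed inside+outside."""
        L, cg = self.L, self.cg
        V, PostV, OV, OPost = self.V, self.PostV, self.OV, self.OPost
        total = self.total
        if total <= 0:
            raise ValueError("zero total inside weight")
        usage: Dict[int, float] = {}
        col_post: Dict[str, np.ndarray] = {nt: np.zeros(L)
                                           for nt in cg.emits}
        cell_weights: Dict[str, np.ndarray] = {}

        def count(rules, O):
            for r in rules:
                w = cg.weight(r)
                if w == 0:
                    continue
                if r.kind is RuleKind.TRANSITION:
                    u = float((O * w * V[r.rhs[0]]).sum()) / total
                elif r.kind is RuleKind.END:
                    u = float(np.trace(O) * w) / total
                else:
                    a, b = r.rhs
                    u = 0.0
                    for i in range(L + 1):
                        for j in range(i, L + 1):
                            if O[i, j]:
                                u += O[i, j] * w * float(
                                    V[a][i, i:j + 1] @ V[b][i:j + 1, j])
                    u /= total
                if u:
                    usage[id(r)] = usage.get(id(r), 0.0) + u

        for nt, em in cg.emits.items():
            count(em.post, OPost[nt])
            cw = np.zeros(len(self.cells[nt]))
            for ci, cols in enumerate(self.cells[nt]):
                l, r = em.wl, em.wr
                # all cells sharing this column tuple
                i = cols[0] if l else None
                weightsum = 0.0
                for (a, b) in self._cells_for(nt, cols):
                    p = OV[nt][a, b] * self.E[nt][a, b] * \
                        PostV[nt][a + l, b - r] / total
                    weightsum += p
                    for c in cols:
                        col_post[nt][c] += p
                cw[ci] = weightsum
            cell_weights[nt] = cw
            eru = float(cw.sum())
            for r in cg.g.rules:
                if r.kind is RuleKind.EMISSION and r.lhs == nt:
                    usage[id(r)] = usage.get(id(r), 0.0) + eru
                if r.kind is RuleKind.RETURN and r.lhs == f"{nt}*":
                    usage[id(r)] = usage.get(id(r), 0.0) + eru
        for nt, rules in cg.null_rules.items():
            count(rules, OV[nt])
        return usage, col_post, cell_weights

    def _cells_for(self, nt, cols):
        em = self.cg.emits[nt]
        l, r = em.wl, em.wr
        L = self.L
        out = []
        if l and r:
            out.append((cols[0], cols[-1] + 1))
        elif l:
            i = cols[0]
            for j in range(i + l, L + 1):
                out.append((i, j))
        else:
            j = cols[-1] + 1
            for i in range(0, j - r + 1):
                out.append((i, j))
        return out

    # ------------------------------------------------------------------
    def cyk(self, rows: Dict[str, str]) -> Parse:
        """Single maximum-weight parse (ties broken toward the
        lowest-index rule, deterministically)."""
        self._emission_tables(rows)
        L, cg = self.L, self.cg
        V = {nt: np.zeros((L + 1, L + 1))
             for nt in list(cg.emits) + list(cg.null_rules)}
        PostV = {nt: np.zeros((L + 1, L + 1)) for nt in cg.emits}
        bp: Dict[Tuple[str, int, int], tuple] = {}
        band = cg.band
        rule_index = {id(r): i for i, r in enumerate(cg.g.rules)}

        def rule_max(rules, i, j, key):
            best, choice = 0.0, None
            for r in rules:
                w = cg.weight(r)
                if w == 0:
                    continue
                if r.kind is RuleKind.TRANSITION:
                    v = w * V[r.rhs[0]][i, j]
                    cand = ("t", r, None)
                elif r.kind is RuleKind.END:
                    v = w if i == j else 0.0
                    cand = ("e", r, None)
                else:
                    a, b = r.rhs
                    v, cand = 0.0, None
                    for m in range(i, j + 1):
                        vv = w * V[a][i, m] * V[b][m, j]
                        if vv > v:
                            v, cand = vv, ("b", r, m)
                if v > best:
                    best, choice = v, cand
            if choice is not None:
                bp[key] = choice
            return best

        for span in range(L + 1):
            for i in range(L - span + 1):
                j = i + span
                for node in self._order:
                    if node.startswith("post:"):
                        nt = node[5:]
                        em = cg.emits[nt]
                        PostV[nt][i, j] = rule_max(em.post, i, j,
                                                   ("post:" + nt, i, j))
                        l, r = em.wl, em.wr
                        ii, jj = i - l, j + r
                        if 0 <= ii and jj <= L and not (
                                l and r and band is not None
                                and jj - ii > band):
                            V[nt][ii, jj] = self.E[nt][ii, jj] * \
                                PostV[nt][i, j]
                    else:
                        V[node][i, j] = rule_max(cg.null_rules[node], i, j,
                                                 (node, i, j))
        total = V[cg.g.start][0, L]
        if total <= 0:
            raise ValueError("no parse with positive weight")

        labels: List[Optional[str]] = [None] * L
        events: List[EmissionEvent] = []

        def trace(sym: str, i: int, j: int):
            if sym in cg.emits:
                em = cg.emits[sym]
                l, r = em.wl, em.wr
                cols = tuple(range(i, i + l)) + tuple(range(j - r, j))
                for c in cols:
                    labels[c] = sym
                events.append(EmissionEvent(sym, cols))
                trace_rules("post:" + sym, i + l, j - r)
            else:
                trace_rules(sym, i, j)

        def trace_rules(key_sym: str, i: int, j: int):
            kind, r, m = bp[(key_sym, i, j)]
            if kind == "t":
                trace(r.rhs[0], i, j)
            elif kind == "b":
                trace(r.rhs[0], i, m)
                trace(r.rhs[1], m, j)

        trace(cg.g.start, 0, L)
        events.sort(key=lambda e: e.cols)
        return Parse(labels, events, float(np.log(total)))


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------

def inside(g: Grammar, aln, tree: PhyloTree,
           band: Optional[int] = None) -> Tuple[SCFGEngine, float]:
    """Total log likelihood (sum over all parses) by the inside
    recursion; returns the engine (holding the DP tables) and the log
    likelihood."""
    rows = alignment_rows(aln)
    eng = CompiledGrammar(g, tree, band=band).scfg()
    ll = eng.inside(rows)
    return eng, ll


def forward_backward(g: Grammar, aln, tree: PhyloTree):
    """Forward/backward for a phylo-HMM grammar; returns (engine, total
    log-likelihood, per-column nonterminal posteriors as {nt: (L,)})."""
    rows = alignment_rows(aln)
    eng = CompiledGrammar(g, tree).hmm()
    total, col_post, _ = eng.forward_backward(rows)
    posts = {s: col_post[:, i] for i, s in enumerate(eng.states)}
    return eng, total, posts


def cyk(g: Grammar, aln, tree: PhyloTree,
        band: Optional[int] = None) -> Parse:
    """Single most probable parse and its log score (<= inside total)."""
    rows = alignment_rows(aln)
    cg = CompiledGrammar(g, tree, band=band)
    if cg.kind == PHYLO_HMM:
        return cg.hmm().viterbi(rows)
    return cg.scfg().cyk(rows)
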