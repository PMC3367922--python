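"""Generative sampling from a phylo-grammar (the simulator role).

The two-step generative process: transformation rules are applied from
START until only pseudoterminals remain (a sampled parse); then for each
emission a token tuple is drawn from the chain's initial distribution and
evolved down the tree, each branch sampling the child state from the
exp(Qt) row of its (hybrid-resolved) component.  Leaves become alignment
rows; the truth parse becomes #=GC labels and sampled hidden classes
become #=GR rows — so simulated alignments carry their ground truth.

Alignment length is controlled by conditioning: for phylo-HMMs exactly
the required number of non-end transition steps is sampled (exact when
end weights are uniform across states, as in the built-in models); for
phylo-SCFGs unconstrained samples are drawn with rejection on length.
Branch evolution samples endpoint states directly from exp(Qt); an
event-by-event (Gillespie) path sampler is provided separately for
substitution counting.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .chain import Chain, HybridChain
from .grammar import Grammar, Rule, RuleKind, classify_grammar, PHYLO_HMM
from .inference import CompiledGrammar, EmissionEvent, Parse
from .likelihood import ChainEngine
from .params import ParamSet
from .stockholm import StockholmAlignment
from .tree import PhyloTree

__all__ = ["sample_parse", "evolve_columns", "simulate_alignment",
           "sample_branch_events"]


def _pick(rng, weights: np.ndarray) -> int:
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero-probability continuation everywhere")
    return int(rng.choice(len(weights), p=weights / total))


def sample_parse(g: Grammar, seed: Union[int, np.random.Generator],
                 length: Optional[int] = None,
                 max_tries: int = 1000) -> Parse:
    """Sample a parse under the grammar's rule probabilities.

    ``length`` conditions on the number of emitted columns (see module
    docstring); ``None`` samples unconstrained, treating end weights as
    part of each local decision.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cg = CompiledGrammar(g, tree=None)
    if length is not None and cg.kind == PHYLO_HMM:
        return _sample_hmm_parse(cg, rng, length)
    for _ in range(max_tries):
        parse = _sample_free_parse(cg, rng)
        if length is None or len(parse.labels) == length:
            return parse
    raise RuntimeError(
        f"could not sample a parse of length {length} in {max_tries} tries")


def _sample_hmm_parse(cg: CompiledGrammar, rng, length: int) -> Parse:
    eng = cg.hmm()
    widths = eng.widths
    if len(set(widths)) != 1:
        raise ValueError("fixed-length conditioning requires all emissions "
                         "to have equal width")
    w = int(widths[0])
    if length % w:
        raise ValueError(f"length {length} is not a multiple of the "
                         f"emission width {w}")
    n_steps = length // w
    labels: List[Optional[str]] = []
    events: List[EmissionEvent] = []
    if n_steps == 0:
        return Parse([], [], 0.0)
    k = _pick(rng, eng.init)
    pos = 0
    for step in range(n_steps):
        s = eng.states[k]
        cols = tuple(range(pos, pos + w))
        events.append(EmissionEvent(s, cols))
        labels.extend([s] * w)
        pos += w
        if step < n_steps - 1:
            k = _pick(rng, eng.T[k])
    return Parse(labels, events, 0.0)


def _sample_free_parse(cg: CompiledGrammar, rng,
                       max_expansions: int = 100000) -> Parse:
    budget = [max_expansions]

    def expand(sym: str) -> List:
        """Returns a nested column plan: list of EmissionEvent templates
        (nt, wl, wr) and sublists."""
        budget[0] -= 1
        if budget[0] < 0:
            raise RuntimeError("parse expansion budget exceeded "
                               "(non-terminating grammar?)")
        if sym in cg.emits:
            em = cg.emits[sym]
            inner = expand_rules(em.post)
            return [("emit", sym, em.wl, em.wr, inner)]
        return expand_rules(cg.null_rules[sym])

    def expand_rules(rules: List[Rule]) -> List:
        weights = np.array([cg.weight(r) for r in rules])
        r = rules[_pick(rng, weights)]
        if r.kind is RuleKind.END:
            return []
        if r.kind is RuleKind.TRANSITION:
            return expand(r.rhs[0])
        if r.kind is RuleKind.BIFURCATION:
            return expand(r.rhs[0]) + expand(r.rhs[1])
        raise ValueError(f"unexpected rule kind {r.kind}")

    plan = expand(cg.g.start)
    labels: List[str] = []
    events: List[EmissionEvent] = []

    def layout(plan, offset: int) -> int:
        """Assign column indices; returns total width."""
        width = 0
        for item in plan:
            _, nt, wl, wr, inner = item
            inner_w = layout_width(inner)
            cols = tuple(range(offset + width, offset + width + wl)) + \
                tuple(range(offset + width + wl + inner_w,
                            offset + width + wl + inner_w + wr))
            events.append(EmissionEvent(nt, cols))
            layout(inner, offset + width + wl)
            width += wl + inner_w + wr
        return width

    def layout_width(plan) -> int:
        return sum(it[2] + it[3] + layout_width(it[4]) for it in plan)

    total = layout(plan, 0)
    labels = [None] * total
    for ev in events:
        for c in ev.cols:
            labels[c] = ev.nt
    events.sort(key=lambda e: e.cols)
    return Parse(labels, events, 0.0)


# ---------------------------------------------------------------------------
# Token evolution
# ---------------------------------------------------------------------------

def evolve_columns(parse: Parse, g: Grammar, tree: PhyloTree,
                   seed: Union[int, np.random.Generator],
                   params: Optional[ParamSet] = None
                   ) -> StockholmAlignment:
    """Evolve every emission of a parse down the tree and assemble the
    annotated Stockholm alignment (rows + #=GF NH tree + truth #=GC +
    hidden-class #=GR rows)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = (params if params is not None else g.params).copy()
    params.normalize_pgroups()
    L = len(parse.labels)
    leaves = tree.leaves()
    rows = {n.label: ["-"] * L for n in leaves}
    gr: Dict[str, Dict[str, List[str]]] = {}

    engines: Dict[int, ChainEngine] = {}
    pmats: Dict[Tuple[int, int], np.ndarray] = {}

    def engine_for(chain: Chain) -> ChainEngine:
        e = engines.get(id(chain))
        if e is None:
            e = ChainEngine(chain, params)
            engines[id(chain)] = e
        return e

    nt_chain = {}
    for r in g.rules:
        if r.kind is RuleKind.EMISSION:
            nt_chain[r.lhs] = g.chain_for_terminal(
                (r.left_terms + r.right_terms)[0])

    for ev in parse.events:
        chain = nt_chain[ev.nt]
        root_engine = engine_for(chain.default if isinstance(chain, HybridChain)
                                 else chain)
        state = {id(tree.root): _pick(rng, root_engine.pi)}
        for node in tree.nodes_preorder():
            if node.parent is None:
                continue
            comp = (chain.resolve(node.label)
                    if isinstance(chain, HybridChain) else chain)
            eng = engine_for(comp)
            key = (id(comp), id(node))
            P = pmats.get(key)
            if P is None:
                P = eng.pmatrix(node.length)
                pmats[key] = P
            state[id(node)] = _pick(rng, P[state[id(node.parent)]])
        for leaf in leaves:
            toks, cls = root_engine.rm.states[state[id(leaf)]]
            for p, c in enumerate(ev.cols):
                rows[leaf.label][c] = toks[p]
            if cls is not None:
                tag = chain.hidden_row or "CLASS"
                row = gr.setdefault(leaf.label, {}).setdefault(
                    tag, ["."] * L)
                for c in ev.cols:
                    row[c] = cls[0]

    aln = StockholmAlignment()
    for leaf in leaves:
        aln.rows[leaf.label] = "".join(rows[leaf.label])
    aln.embed_tree(tree)
    aln.gc[g.gc_tag] = "".join(
        g.label_for(lbl) if lbl else "." for lbl in parse.labels)
    for name, tags in gr.items():
        aln.gr[name] = {tag: "".join(chars) for tag, chars in tags.items()}
    return aln


def simulate_alignment(g: Grammar, tree: PhyloTree, length: int,
                       seed: Union[int, np.random.Generator],
                       params: Optional[ParamSet] = None
                       ) -> Tuple[StockholmAlignment, Parse]:
    """Sample a parse of the given length and evolve it down the tree."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    parse = sample_parse(g, rng, length=length)
    return evolve_columns(parse, g, tree, rng, params=params), parse


def sample_branch_events(Q: np.ndarray, state: int, t: float,
                         rng: np.random.Generator) -> Tuple[int, int]:
    """Gillespie path sample along one branch: returns (end state,
    number of substitution events)."""
    s, n, time = state, 0, 0.0
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            return s, n
        time += rng.exponential(1.0 / rate)
        if time >= t:
            return s, n
        probs = np.clip(Q[s], 0.0, None)
        probs[s] = 0.0
        s = int(rng.choice(len(probs), p=probs / probs.sum()))
        n += 1
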