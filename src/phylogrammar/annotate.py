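"""Alignment annotation: best parse, posterior tracks, GFF features,
marginal ancestral sequences and hidden-class rows.

Ancestral reconstruction is *marginal*: per node and column the posterior
over states is computed and maximized independently, conditioned on the
single best parse (each column uses the chain of the nonterminal that
emits it in the CYK/Viterbi parse).  The most-probable character is by
construction the argmax of the returned posterior distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .grammar import Grammar, PHYLO_HMM
from .inference import (CompiledGrammar, Parse, _leaf_tuples,
                        alignment_rows)
from .likelihood import PhyloEmitter
from .tracks import GFFFeature, WigTrack
from .tree import PhyloTree

__all__ = ["ParseAnnotation", "annotate"]


@dataclass
class ParseAnnotation:
    """Everything the annotation pass produces for one alignment."""

    parse: Parse
    gc_label: str
    posteriors: Dict[str, np.ndarray]
    gff: List[GFFFeature] = field(default_factory=list)
    wig: Optional[WigTrack] = None
    ancestral: Dict[str, str] = field(default_factory=dict)
    ancestral_pp: Dict[str, np.ndarray] = field(default_factory=dict)
    gr_class: Dict[str, Dict[str, str]] = field(default_factory=dict)
    log_likelihood: float = 0.0


def annotate(g: Grammar, aln, tree: PhyloTree, band: Optional[int] = None,
             ancestral: bool = False, wig_nonterminal: Optional[str] = None,
             seqid: str = "alignment", source: str = "phylogrammar"
             ) -> ParseAnnotation:
    """Annotate an alignment under a grammar.

    Produces the best-parse per-column labels (#=GC), per-column label
    posteriors (WIG), GFF features for maximal runs of each nonterminal,
    hidden-class #=GR rows for latent-class chains, and (optionally)
    marginal ancestral sequences at every labeled internal node.
    """
    rows = alignment_rows(aln)
    L = len(next(iter(rows.values()))) if rows else 0
    cg = CompiledGrammar(g, tree, band=band)

    if cg.kind == PHYLO_HMM:
        eng = cg.hmm()
        total, col_post, _ = eng.forward_backward(rows)
        posts = {s: col_post[:, i].copy() for i, s in enumerate(eng.states)}
        parse = eng.viterbi(rows)
    else:
        eng = cg.scfg()
        total = eng.inside(rows)
        eng.outside()
        _, col_posts, _ = eng.posteriors_and_counts()
        posts = col_posts
        parse = eng.cyk(rows)

    gc = "".join(g.label_for(lbl) if lbl else "." for lbl in parse.labels)

    # GFF: maximal runs of the same best-parse nonterminal
    gff: List[GFFFeature] = []
    c = 0
    while c < L:
        lbl = parse.labels[c]
        start = c
        while c < L and parse.labels[c] == lbl:
            c += 1
        if lbl is None:
            continue
        mean_post = float(np.mean(posts[lbl][start:c]))
        gff.append(GFFFeature(seqid, source, lbl, start + 1, c,
                              score=mean_post,
                              attributes={"Nonterminal": lbl}))

    if wig_nonterminal is not None:
        if wig_nonterminal not in posts:
            raise KeyError(f"no emitting nonterminal {wig_nonterminal!r}")
        wig_vals = posts[wig_nonterminal]
        wig_name = f"posterior {wig_nonterminal}"
    else:
        # confidence track: posterior of the best-parse label per column
        wig_vals = np.array(
            [posts[lbl][i] if lbl else 0.0
             for i, lbl in enumerate(parse.labels)])
        wig_name = "best-parse posterior"
    wig = WigTrack(wig_name, list(wig_vals), chrom=seqid)

    out = ParseAnnotation(parse, gc, posts, gff, wig,
                          log_likelihood=float(total))

    _reconstruct(out, cg, rows, parse, ancestral)
    return out


def _reconstruct(out: ParseAnnotation, cg: CompiledGrammar,
                 rows: Dict[str, str], parse: Parse,
                 want_ancestral: bool) -> None:
    """Fill ancestral sequences (#=GF-requested) and hidden-class #=GR
    rows, conditioning each column on the best parse's nonterminal."""
    tree = cg.tree
    internal = [n.label for n in tree.nodes_preorder()
                if not n.is_leaf and n.label]
    leaves = [n.label for n in tree.leaves()]
    L = len(parse.labels)

    anc_chars = {n: ["-"] * L for n in internal}
    anc_pp = {n: np.zeros(L) for n in internal}
    gr: Dict[str, Dict[str, List[str]]] = {}

    by_nt: Dict[str, List] = {}
    for ev in parse.events:
        by_nt.setdefault(ev.nt, []).append(ev)

    for nt, events in by_nt.items():
        em = cg.emits[nt]
        chain = em.chain
        emitter = PhyloEmitter(chain, tree, cg.params)
        positions = [ev.cols for ev in events]
        emitter.fit(_leaf_tuples(rows, positions))
        arity = chain.arity
        if want_ancestral:
            for node in internal:
                post = emitter.posterior(node)          # (n_events, S)
                best = np.argmax(post, axis=1)
                pp = post[np.arange(len(events)), best]
                for e_i, ev in enumerate(events):
                    toks, _cls = emitter.states[best[e_i]]
                    for p, c in enumerate(ev.cols):
                        anc_chars[node][c] = toks[p]
                        anc_pp[node][c] = pp[e_i]
        if chain.hidden_labels:
            tag = chain.hidden_row or "CLASS"
            n_cls = len(chain.hidden_labels)
            for leaf in leaves:
                post = emitter.posterior(leaf)          # (n_events, S)
                # marginalize to class: states are token-major, class-minor
                cls_post = post.reshape(len(events), -1, n_cls).sum(axis=1)
                best = np.argmax(cls_post, axis=1)
                row = gr.setdefault(leaf, {}).setdefault(tag, ["."] * L)
                for e_i, ev in enumerate(events):
                    lbl = chain.hidden_labels[best[e_i]]
                    for c in ev.cols:
                        row[c] = lbl[0]

    if want_ancestral:
        out.ancestral = {n: "".join(ch) for n, ch in anc_chars.items()}
        out.ancestral_pp = anc_pp
    out.gr_class = {leaf: {tag: "".join(chars)
                           for tag, chars in tags.items()}
                    for leaf, tags in gr.items()}
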