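"""EM estimation of grammar parameters.

E-step: expected rule usages come from forward/backward (phylo-HMMs) or
inside/outside (phylo-SCFGs); expected substitution counts c(i->j) and
state wait times w(i) come from per-branch joint endpoint posteriors
integrated along each branch (closed-form eigendecomposition integrals,
with quadrature for defective generators).

M-step: each probability group is renormalized from the usage counts of
the rules its members appear in; each rate parameter r is updated to

    r_new = sum of counts over matrix entries whose rate expression
            contains r  /  sum of wait times weighted by the entry's
            remaining factors,

with parameters updated in one coordinate-ascent sweep (later updates see
earlier ones) when entries tie several parameters together.  The
log-likelihood trace is non-decreasing; a step that would decrease it
(possible only through the approximate M-step for tied products) is
rejected and training stops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chain import Chain, HybridChain
from .grammar import Grammar, RuleKind, PHYLO_HMM
from .inference import CompiledGrammar, alignment_rows
from .params import ParamSet
from .tree import PhyloTree

__all__ = ["em_train", "TrainResult"]


@dataclass
class TrainResult:
    grammar: Grammar
    trace: List[float]
    converged: bool
    n_iter: int


def _grammar_components(g: Grammar) -> List[Chain]:
    out, seen = [], set()
    for c in g.chains:
        comps = c.component_set() if isinstance(c, HybridChain) else [c]
        for comp in comps:
            if id(comp) not in seen:
                seen.add(id(comp))
                out.append(comp)
    return out


def em_train(g: Grammar, alignments: Sequence, trees: Sequence[PhyloTree],
             max_iter: int = 30, tol: float = 1e-4,
             band: Optional[int] = None, floor: float = 1e-6) -> TrainResult:
    """Train rates and probability groups by EM on one or more alignments.

    ``tol`` is the relative log-likelihood improvement below which
    training stops; the returned trace holds the log-likelihood at each
    parameter vector visited.
    """
    if len(alignments) != len(trees):
        raise ValueError("need one tree per alignment")
    data = [alignment_rows(a) for a in alignments]
    if not data or all(len(next(iter(r.values()), "")) == 0 for r in data):
        raise ValueError("no data columns to train on")

    g = g.copy()
    params = g.params
    params.normalize_pgroups()

    trainable_rates = _trainable_rates(g)
    trace: List[float] = []
    converged = False
    prev_params = params.copy()

    for it in range(max_iter):
        total_ll, usage, stats = _e_step(g, data, trees, params, band)
        if trace and total_ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            # approximate M-step decreased the likelihood: reject the step
            params = prev_params
            converged = True
            break
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] <= tol * abs(trace[-2]):
            converged = True
            break
        prev_params = params.copy()
        _m_step(g, params, usage, stats, trainable_rates, floor)

    g.params = params
    return TrainResult(g, trace, converged, len(trace))


def _trainable_rates(g: Grammar) -> List[str]:
    """Free rate parameters that actually appear in some mutate entry."""
    used = set()
    for comp in _grammar_components(g):
        for expr in comp.mutate.values():
            used.update(expr.names)
    resolved = set()
    for name in used:
        resolved.update(_resolve_free(g.params, name))
    return sorted(n for n in resolved if n in g.params.rates)


def _resolve_free(params: ParamSet, name: str, depth: int = 0) -> set:
    if depth > 10:
        return set()
    if name in params.aliases:
        out = set()
        for n in params.aliases[name].names:
            out |= _resolve_free(params, n, depth + 1)
        return out
    return {name}


def _e_step(g: Grammar, data, trees, params: ParamSet, band):
    total_ll = 0.0
    usage: Dict[int, float] = {}
    # per-component counts/waits, indexed in the component's state order
    stats: Dict[int, Tuple[Chain, np.ndarray, np.ndarray]] = {}

    def merge_stats(part):
        for key, (comp, c, w) in part.items():
            if key in stats:
                stats[key][1][...] += c
                stats[key][2][...] += w
            else:
                stats[key] = (comp, c.copy(), w.copy())

    for rows, tree in zip(data, trees):
        cg = CompiledGrammar(g, tree, params=params, band=band)
        if cg.kind == PHYLO_HMM:
            eng = cg.hmm()
            ll, _, _ = eng.forward_backward(rows)
            total_ll += ll
            use, cweights = eng.expected_counts()
            for s, wts in cweights.items():
                if wts.size:
                    merge_stats(eng._emitters[s].branch_statistics(wts))
        else:
            eng = cg.scfg()
            ll = eng.inside(rows)
            total_ll += ll
            eng.outside()
            use, _, cell_weights = eng.posteriors_and_counts()
            for nt, wts in cell_weights.items():
                if wts.size:
                    merge_stats(eng.emitters[nt].branch_statistics(wts))
        for k, v in use.items():
            usage[k] = usage.get(k, 0.0) + v
    return total_ll, usage, stats


def _m_step(g: Grammar, params: ParamSet, usage: Dict[int, float],
            stats, trainable_rates: List[str], floor: float) -> None:
    # --- probability groups: renormalize from usage counts -------------
    rule_by_id = {id(r): r for r in g.rules}
    for grp in params.pgroups:
        counts = {m: 0.0 for m in grp}
        for rid, u in usage.items():
            for name in rule_by_id[rid].prob.names:
                if name in counts:
                    counts[name] += u
        total = sum(counts.values())
        if total > 0:
            for m in grp:
                grp[m] = max(counts[m] / total, floor)
            s = sum(grp.values())
            for m in grp:
                grp[m] /= s

    # --- rates: tied count / weighted-wait ratio, one sweep ------------
    for name in trainable_rates:
        num = den = 0.0
        for comp, cmat, wvec in stats.values():
            idx = comp.state_index()
            for (src, dst), expr in comp.mutate.items():
                if name not in expr.names or src not in idx or dst not in idx:
                    continue
                i, j = idx[src], idx[dst]
                num += cmat[i, j]
                den += wvec[i] * expr.value_excluding(params, name)
        if den <= 0:
            continue
        new = num / den
        if new < floor:
            warnings.warn(f"rate parameter {name!r} driven to {new:g}; "
                          f"flooring at {floor}")
            new = floor
        params.rates[name] = new
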