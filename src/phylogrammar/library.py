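"""Native constructors for the built-in models.

Each constructor builds the same structure the macro-expanded grammar
file for that model would produce: the Jukes-Cantor chain, the latent
slow/fast rate-class chain (RASER-style), the rate-multiplier phylo-HMM
(PhastCons-style), the lineage-specific per-node phylo-HMM (DLESS-style,
in its simplified one-scale form), and the Nielsen-Yang codon model with
a pluggable genetic code.
"""

from __future__ import annotations

import itertools
import warnings
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alphabet import DNA, Alphabet
from .chain import Chain, HybridChain
from .grammar import Grammar, Rule, RuleKind
from .params import ParamExpr, ParamSet
from .tree import PhyloTree

__all__ = ["jukes_cantor", "raser_chain", "discrete_gamma_rates",
           "phastcons_hmm", "dless_hmm", "nielsen_yang", "genetic_code",
           "codon_pair_type", "sense_codons", "codon_frequencies",
           "single_chain_grammar", "chain_params"]


def chain_params(*chains: Union[Chain, HybridChain]) -> ParamSet:
    """ParamSet seeded from the constructors' suggested seed values."""
    ps = ParamSet()
    for c in chains:
        comps = c.component_set() if isinstance(c, HybridChain) else [c]
        for comp in comps:
            ps.rates.update(comp.seeds)
    return ps


def single_chain_grammar(chain: Union[Chain, HybridChain],
                         name: str = "onechain",
                         extra_params: Optional[ParamSet] = None) -> Grammar:
    """The trivial grammar: START -> EMIT, with EMIT emitting the chain's
    pseudoterminals left-to-right until the alignment ends."""
    params = extra_params.copy() if extra_params else chain_params(chain)
    inner = "E*"
    rules = [
        Rule(RuleKind.TRANSITION, "start", rhs=("E",), prob=ParamExpr.of(1)),
        Rule(RuleKind.EMISSION, "E", left_terms=tuple(chain.terminals),
             inner=inner, prob=ParamExpr.of(1)),
        Rule(RuleKind.RETURN, inner, rhs=("E",), prob=ParamExpr.of(1)),
        Rule(RuleKind.TRANSITION, "E", rhs=("E",), prob=ParamExpr.of(1)),
        Rule(RuleKind.END, "E", prob=ParamExpr.of(1)),
    ]
    return Grammar(name, chain.alphabet, [chain], rules, params)


# ---------------------------------------------------------------------------
# Nucleotide chains
# ---------------------------------------------------------------------------

def jukes_cantor(u: float = 1.0, alphabet: Alphabet = DNA,
                 rate_name: str = "u", terminal: str = "NUC") -> Chain:
    """The Jukes-Cantor chain: every off-diagonal substitution has rate u.

    With ``u = 1/3`` (4 tokens) the chain performs on average one
    substitution per unit time at stationarity.
    """
    if u <= 0:
        raise ValueError(f"rate u must be positive, got {u}")
    chain = Chain((terminal,), alphabet, seeds={rate_name: float(u)})
    for t1 in alphabet.tokens:
        for t2 in alphabet.tokens:
            if t1 != t2:
                chain.mutate[((t1,), None), ((t2,), None)] = \
                    ParamExpr.of(rate_name)
    return chain


def raser_chain(s: float = 0.1, f: float = 2.0, r_sf: float = 0.01,
                r_fs: float = 0.01, u: float = 1.0,
                alphabet: Alphabet = DNA, terminal: str = "RASER") -> Chain:
    """Latent rate-class chain: tokens evolve under Jukes-Cantor scaled by
    a hidden slow/fast class (``s``/``f``), with class flips at rates
    ``r_sf`` and ``r_fs``.  Five free parameters in total.

    The hidden class is annotated through the Stockholm ``#=GR CLASS``
    row.  No mutate entry changes token and class simultaneously.
    """
    for name, v in [("s", s), ("f", f), ("r_sf", r_sf), ("r_fs", r_fs),
                    ("u", u)]:
        if v < 0:
            raise ValueError(f"rate {name} must be >= 0, got {v}")
    chain = Chain((terminal,), alphabet, hidden_row="CLASS",
                  hidden_labels=("s", "f"),
                  seeds={"s": s, "f": f, "r_sf": r_sf, "r_fs": r_fs, "u": u})
    for c1 in ("s", "f"):
        for c2 in ("s", "f"):
            for t1 in alphabet.tokens:
                for t2 in alphabet.tokens:
                    if c1 == c2 and t1 != t2:
                        chain.mutate[((t1,), c1), ((t2,), c2)] = \
                            ParamExpr.of("u", c1)
                    elif c1 != c2 and t1 == t2:
                        chain.mutate[((t1,), c1), ((t2,), c2)] = \
                            ParamExpr.of(f"r_{c1}{c2}")
    return chain


# ---------------------------------------------------------------------------
# Discrete-Gamma rate classes
# ---------------------------------------------------------------------------

def discrete_gamma_rates(shape: float, K: int) -> List[float]:
    """K rate multipliers from a mean-one Gamma distribution.

    Each rate is the mean of Gamma(shape, scale=1/shape) within its
    equal-probability K-quantile bin, so the rates average exactly one —
    the property the rate-multiplier role requires.
    """
    if shape <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, K + 1), a=shape,
                           scale=1.0 / shape)
    # E[X; a<X<b] for Gamma(shape, 1/shape) equals F_{shape+1}(b)-F_{shape+1}(a)
    upper = gamma_dist.cdf(edges, a=shape + 1.0, scale=1.0 / shape)
    rates = K * np.diff(upper)
    rates = rates / rates.mean()  # remove residual quadrature error
    return [float(r) for r in rates]


# ---------------------------------------------------------------------------
# Phylo-HMM constructors
# ---------------------------------------------------------------------------

def _hmm_transitions(nts: Sequence[str], stay_name: str, leave_name: str,
                     rules: List[Rule]) -> None:
    K = len(nts)
    for nt in nts:
        rules.append(Rule(RuleKind.TRANSITION, "start", rhs=(nt,),
                          prob=ParamExpr.of(Fraction(1, K))))
        rules.append(Rule(RuleKind.END, nt, prob=ParamExpr.of(1)))
        for nt2 in nts:
            if nt == nt2:
                rules.append(Rule(RuleKind.TRANSITION, nt, rhs=(nt2,),
                                  prob=ParamExpr.of(stay_name)))
            else:
                rules.append(Rule(
                    RuleKind.TRANSITION, nt, rhs=(nt2,),
                    prob=ParamExpr.of(leave_name, Fraction(1, K - 1))))


def phastcons_hmm(K: int, base_chain: Chain, rates: Sequence[float],
                  stay_prob: float = 0.9) -> Grammar:
    """Rate-multiplier phylo-HMM: K emitting nonterminals sharing one
    substitution model up to per-nonterminal rate multipliers r_1..r_K.

    Transitions: start picks a nonterminal uniformly (1/K); a nonterminal
    self-transitions with probability stayProb and moves to each other
    nonterminal with probability leaveProb/(K-1); every nonterminal may
    end with weight one (the alignment length decides when).
    """
    if K < 1 or len(rates) != K:
        raise ValueError("need K >= 1 and exactly K rates")
    if not 0.0 <= stay_prob <= 1.0:
        raise ValueError(f"stayProb must be a probability, got {stay_prob}")
    if K == 1 and stay_prob < 1.0:
        warnings.warn("K=1: the leave probability has no destination; "
                      "forcing stayProb to 1")
        stay_prob = 1.0

    params = chain_params(base_chain)
    chains: List[Chain] = []
    rules: List[Rule] = []
    nts = [str(k) for k in range(1, K + 1)]
    for k, nt in enumerate(nts, start=1):
        ck = base_chain.scaled(f"r_{k}").renamed((f"chain_{k}",))
        chains.append(ck)
        params.rates[f"r_{k}"] = float(rates[k - 1])
        rules.append(Rule(RuleKind.EMISSION, nt, left_terms=(f"chain_{k}",),
                          inner=f"{nt}*", prob=ParamExpr.of(1)))
        rules.append(Rule(RuleKind.RETURN, f"{nt}*", rhs=(nt,),
                          prob=ParamExpr.of(1)))
    if K == 1:
        rules.append(Rule(RuleKind.TRANSITION, "start", rhs=(nts[0],),
                          prob=ParamExpr.of(1)))
        rules.append(Rule(RuleKind.TRANSITION, nts[0], rhs=(nts[0],),
                          prob=ParamExpr.of("stayProb")))
        rules.append(Rule(RuleKind.END, nts[0], prob=ParamExpr.of(1)))
    else:
        _hmm_transitions(nts, "stayProb", "leaveProb", rules)
    params.pgroups.append({"stayProb": float(stay_prob),
                           "leaveProb": float(1.0 - stay_prob)})
    g = Grammar("phastcons", base_chain.alphabet, chains, rules, params)
    g.nt_labels = {nt: nt[-1] for nt in nts}
    return g


def dless_hmm(tree: PhyloTree, base_chain: Chain, slow_scale: float = 0.3,
              stay_prob: float = 0.9) -> Grammar:
    """Lineage-specific phylo-HMM: one nonterminal per tree node.

    Node v's chain is a hybrid chain that scales the substitution rate by
    ``slowScale`` on every branch in the subtree rooted at v (detecting
    gain or loss of constraint on that lineage) and leaves the rest of
    the tree at the base rate, plus a neutral background nonterminal.
    Unlabeled nodes are auto-labeled deterministically in preorder.
    """
    if slow_scale <= 0:
        raise ValueError(f"slow_scale must be positive, got {slow_scale}")
    tree = tree.copy()
    tree.auto_label()
    params = chain_params(base_chain)
    params.rates["slowScale"] = float(slow_scale)

    slow = base_chain.scaled("slowScale")
    chains: List[Union[Chain, HybridChain]] = []
    rules: List[Rule] = []

    nts = ["bg"] + [n.label for n in tree.nodes_preorder()]
    chains.append(base_chain.renamed(("chain_bg",)))
    rules.append(Rule(RuleKind.EMISSION, "bg", left_terms=("chain_bg",),
                      inner="bg*", prob=ParamExpr.of(1)))
    rules.append(Rule(RuleKind.RETURN, "bg*", rhs=("bg",),
                      prob=ParamExpr.of(1)))
    for node in tree.nodes_preorder():
        v = node.label
        comp_labels = tree.subtree_labels(node)
        hc = HybridChain((f"chain_{v}",),
                         {lbl: slow for lbl in comp_labels}, base_chain)
        chains.append(hc)
        rules.append(Rule(RuleKind.EMISSION, v, left_terms=(f"chain_{v}",),
                          inner=f"{v}*", prob=ParamExpr.of(1)))
        rules.append(Rule(RuleKind.RETURN, f"{v}*", rhs=(v,),
                          prob=ParamExpr.of(1)))
    _hmm_transitions(nts, "stayProb", "leaveProb", rules)
    params.pgroups.append({"stayProb": float(stay_prob),
                           "leaveProb": float(1.0 - stay_prob)})
    g = Grammar("dless", base_chain.alphabet, chains, rules, params)
    return g


# ---------------------------------------------------------------------------
# Codon model
# ---------------------------------------------------------------------------

_PURINES = {"a", "g"}


def genetic_code(name: str = "Standard") -> Dict[str, str]:
    """Genetic code as {codon: amino acid or '*'}, covering all 64 codons.

    Codes come from the NCBI tables (e.g. ``"Standard"``, ``"Vertebrate
    Mitochondrial"``); alternate codes simply change which substitutions
    count as synonymous and which codons are sense.
    """
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_name[name]
    code = {c.lower(): aa for c, aa in table.forward_table.items()}
    for c in table.stop_codons:
        code[c.lower()] = "*"
    if len(code) != 64:
        raise ValueError(f"genetic code {name!r} does not cover all 64 codons")
    return code


def sense_codons(code: Dict[str, str]) -> Tuple[str, ...]:
    """Sense (non-stop) codons in lexicographic a<c<g<t order."""
    return tuple("".join(c) for c in itertools.product("acgt", repeat=3)
                 if code["".join(c)] != "*")


def codon_pair_type(c1: str, c2: str, code: Dict[str, str]) -> Dict[str, object]:
    """Classify the difference between two codons.

    Returns ``{"ndiff", "position", "transition", "synonymous"}``:
    the number of differing nucleotide positions, the (0-based) position
    when exactly one differs, whether that change is a transition, and
    whether the amino-acid translation is preserved.
    """
    c1, c2 = c1.lower(), c2.lower()
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    info: Dict[str, object] = {"ndiff": len(diffs), "position": None,
                               "transition": None, "synonymous": None}
    if len(diffs) == 1:
        i = diffs[0]
        info["position"] = i
        info["transition"] = (c1[i] in _PURINES) == (c2[i] in _PURINES)
        info["synonymous"] = code[c1] == code[c2]
    return info


def nielsen_yang(code: Optional[Dict[str, str]] = None, kappa: float = 2.0,
                 omega: float = 0.5, pi: Optional[Sequence[float]] = None,
                 normalize: bool = False) -> Chain:
    """The Nielsen-Yang codon chain over the sense codons of a genetic code.

    rate(i -> j) = 0 when the codons differ at more than one nucleotide
    position; otherwise pi_j x kappa^[transition] x omega^[nonsynonymous],
    with synonymy judged by the supplied code (61 states and 3721 matrix
    entries under the standard code).  ``pi`` defaults to uniform over
    sense codons; ``normalize=True`` rescales rates so the expected
    substitution rate at the initial distribution is one.
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be >= 0")
    if code is None:
        code = genetic_code("Standard")
    if len(code) != 64:
        raise ValueError("genetic code must cover all 64 codons")
    codons = sense_codons(code)
    n = len(codons)
    if pi is None:
        pi = np.full(n, 1.0 / n)
    else:
        pi = np.asarray(pi, dtype=float)
        if len(pi) != n or abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError("pi must be a distribution over the sense codons")
        pi = pi / pi.sum()

    allowed = tuple(tuple(c) for c in codons)
    chain = Chain(("COD1", "COD2", "COD3"), DNA, allowed=allowed,
                  seeds={"kappa": float(kappa), "omega": float(omega)})
    scale = 1.0
    if normalize:
        scale = 1.0 / _ny_expected_rate(codons, code, kappa, omega, pi)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            info = codon_pair_type(ci, cj, code)
            if info["ndiff"] != 1:
                continue
            factors: List[object] = [float(pi[j]) * scale]
            if info["transition"]:
                factors.append("kappa")
            if not info["synonymous"]:
                factors.append("omega")
            chain.mutate[((tuple(ci), None), (tuple(cj), None))] = \
                ParamExpr.of(*factors)
        chain.initial[(tuple(ci), None)] = ParamExpr.of(float(pi[i]))
    return chain


def _ny_expected_rate(codons, code, kappa, omega, pi) -> float:
    total = 0.0
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            info = codon_pair_type(ci, cj, code)
            if info["ndiff"] != 1:
                continue
            r = pi[j]
            if info["transition"]:
                r *= kappa
            if not info["synonymous"]:
                r *= omega
            total += pi[i] * r
    return total


def codon_frequencies(rows: Sequence[str],
                      code: Optional[Dict[str, str]] = None,
                      pseudocount: float = 1.0) -> np.ndarray:
    """Empirical codon frequencies from in-frame alignment rows (gapped or
    ambiguous codons are skipped), with a pseudocount for unseen codons."""
    if code is None:
        code = genetic_code("Standard")
    codons = sense_codons(code)
    idx = {c: i for i, c in enumerate(codons)}
    counts = np.full(len(codons), float(pseudocount))
    for row in rows:
        row = row.lower()
        for k in range(0, len(row) - 2, 3):
            cod = row[k:k + 3]
            if cod in idx:
                counts[idx[cod]] += 1
    return counts / counts.sum()
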