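"""The grammar data model: production rules over nonterminals coupled to
substitution chains, plus the S-expression reader/writer, validation and
the phylo-HMM / phylo-SCFG classification.

A phylo-grammar generates an alignment in two steps: nonterminal
transformations (the "grammar" part) and token evolution down the
phylogeny (the "phylo" part).  If the transformation rules contain no
bifurcations and all emissions fall on one fixed side of the nonterminal,
the grammar is a phylo-HMM; otherwise it is a phylo-SCFG.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .alphabet import Alphabet
from .chain import Chain, HybridChain, State, instantiate_matrix
from .macro import MacroEnv, expand_macros, format_rational, parse_rational
from .params import ParamError, ParamExpr, ParamSet
from .sexpr import SExpr, parse_sexpr, write_sexpr

__all__ = ["RuleKind", "Rule", "Grammar", "Diagnostic", "validate_grammar",
           "classify_grammar", "grammar_from_forest", "read_grammar",
           "write_grammar", "PHYLO_HMM", "PHYLO_SCFG"]

PHYLO_HMM = "phylo-HMM"
PHYLO_SCFG = "phylo-SCFG"


class RuleKind(enum.Enum):
    TRANSITION = "transition"
    EMISSION = "emission"
    RETURN = "return"
    BIFURCATION = "bifurcation"
    END = "end"


@dataclass
class Rule:
    """One production rule.

    * transition:   lhs -> rhs[0]
    * emission:     lhs -> (left terms..., inner*, right terms...)
    * return:       lhs* -> rhs[0]
    * bifurcation:  lhs -> (rhs[0], rhs[1])
    * end:          lhs -> epsilon

    ``prob`` is an unnormalized weight expression; end-rule weights in
    particular are conventionally left at 1 and the model is normalized
    globally by the dynamic programming.
    """

    kind: RuleKind
    lhs: str
    rhs: Tuple[str, ...] = ()
    left_terms: Tuple[str, ...] = ()
    right_terms: Tuple[str, ...] = ()
    inner: Optional[str] = None
    prob: ParamExpr = ParamExpr((ParamExpr.of(1).factors[0],))

    def __post_init__(self):
        if not self.prob.factors:
            self.prob = ParamExpr.of(1)


@dataclass
class Diagnostic:
    level: str            # "error" | "warning"
    where: str            # chain/rule/pgroup location
    message: str

    def __str__(self):
        return f"{self.level}: {self.where}: {self.message}"


@dataclass
class Grammar:
    """A complete phylo-grammar: alphabet, chains, rules and parameters."""

    name: str
    alphabet: Alphabet
    chains: List[Union[Chain, HybridChain]]
    rules: List[Rule]
    params: ParamSet
    start: str = "start"
    gc_tag: str = "STATE"
    nt_labels: Dict[str, str] = field(default_factory=dict)

    # Lookup ---------------------------------------------------------------
    def chain_for_terminal(self, term: str) -> Union[Chain, HybridChain]:
        for c in self.chains:
            if term in c.terminals:
                return c
        raise KeyError(f"no chain declares pseudoterminal {term!r}")

    @property
    def pseudoterminals(self) -> Tuple[str, ...]:
        return tuple(t for c in self.chains for t in c.terminals)

    @property
    def nonterminals(self) -> Tuple[str, ...]:
        seen: Dict[str, None] = {}
        terms = set(self.pseudoterminals)
        for r in self.rules:
            for sym in (r.lhs,) + r.rhs + ((r.inner,) if r.inner else ()):
                base = sym[:-1] if sym.endswith("*") else sym
                if base and base not in terms:
                    seen.setdefault(base, None)
        return tuple(seen)

    def rules_from(self, lhs: str) -> List[Rule]:
        return [r for r in self.rules if r.lhs == lhs]

    def emission_rule(self, nt: str) -> Optional[Rule]:
        for r in self.rules:
            if r.kind is RuleKind.EMISSION and r.lhs == nt:
                return r
        return None

    @property
    def emitting_nonterminals(self) -> Tuple[str, ...]:
        return tuple(r.lhs for r in self.rules if r.kind is RuleKind.EMISSION)

    def copy(self) -> "Grammar":
        return replace(self, params=self.params.copy(),
                       rules=list(self.rules), chains=list(self.chains),
                       nt_labels=dict(self.nt_labels))

    def label_for(self, nt: str) -> str:
        """Single-character #=GC annotation label for a nonterminal."""
        if nt in self.nt_labels:
            return self.nt_labels[nt]
        return nt[-1] if nt else "."


# ---------------------------------------------------------------------------
# Classification and validation
# ---------------------------------------------------------------------------

def classify_grammar(g: Grammar) -> str:
    """Return ``"phylo-HMM"`` iff there are no bifurcations and every
    emission places all pseudoterminals on one fixed side of the
    nonterminal; otherwise ``"phylo-SCFG"``."""
    sides = set()
    for r in g.rules:
        if r.kind is RuleKind.BIFURCATION:
            return PHYLO_SCFG
        if r.kind is RuleKind.EMISSION:
            if r.left_terms and r.right_terms:
                return PHYLO_SCFG
            sides.add("left" if r.left_terms else "right")
    return PHYLO_HMM if len(sides) <= 1 else PHYLO_SCFG


def validate_grammar(g: Grammar, tree=None) -> List[Diagnostic]:
    """Check every structural invariant; an empty list means the grammar is
    well-formed.  Diagnostics carry their location."""
    out: List[Diagnostic] = []

    tokens = g.alphabet.tokens
    if len(set(tokens)) != len(tokens):
        out.append(Diagnostic("error", "alphabet", "duplicate tokens"))

    for gi, grp in enumerate(g.params.pgroups):
        total = sum(grp.values())
        if abs(total - 1.0) > 1e-9:
            lvl = "error" if total <= 0 else "warning"
            out.append(Diagnostic(lvl, f"pgroup {tuple(grp)}",
                                  f"pgroup not normalizable: sums to {total:g}"))
    for name, v in g.params.rates.items():
        if v < 0:
            out.append(Diagnostic("error", f"rate {name}",
                                  f"negative seed {v}"))

    terms = set(g.pseudoterminals)
    for c in g.chains:
        comps = c.component_set() if isinstance(c, HybridChain) else [c]
        for comp in comps:
            loc = f"chain {c.name}"
            for (src, dst), expr in comp.mutate.items():
                if src == dst:
                    out.append(Diagnostic("error", loc,
                                          f"mutate entry with from == to: {src}"))
                for st in (src, dst):
                    toks, cls = st
                    if len(toks) != comp.arity:
                        out.append(Diagnostic(
                            "error", loc,
                            f"state {st} arity != chain arity {comp.arity}"))
                    if any(t not in tokens for t in toks):
                        out.append(Diagnostic("error", loc,
                                              f"state {st} uses unknown token"))
                    if comp.hidden_labels and cls not in comp.hidden_labels:
                        out.append(Diagnostic("error", loc,
                                              f"state {st} uses unknown class"))
                if comp.hidden_labels and src[0] != dst[0] and src[1] != dst[1]:
                    out.append(Diagnostic(
                        "warning", loc,
                        f"simultaneous token and class change {src}->{dst}"))
                for name in expr.names:
                    if not g.params.has(name):
                        out.append(Diagnostic("error", loc,
                                              f"unbound parameter {name!r}"))

    nts = set(g.nonterminals)
    for i, r in enumerate(g.rules):
        loc = f"rule {i} ({r.kind.value} from {r.lhs})"
        for name in r.prob.names:
            if not g.params.has(name):
                out.append(Diagnostic("error", loc,
                                      f"unbound parameter {name!r}"))
        for t in r.left_terms + r.right_terms:
            if t not in terms:
                out.append(Diagnostic("error", loc,
                                      f"undeclared pseudoterminal {t!r}"))
        for sym in r.rhs:
            base = sym[:-1] if sym.endswith("*") else sym
            if base not in nts:
                out.append(Diagnostic("error", loc,
                                      f"undeclared nonterminal {sym!r}"))

    if tree is not None:
        labels = {n.label for n in tree.nodes_preorder()}
        for c in g.chains:
            if isinstance(c, HybridChain):
                pass  # every branch resolves by construction (default exists)
    return out


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

def _parse_state(form: SExpr, arity: int, hidden: bool) -> State:
    atoms = [a.atom for a in form.items]
    if hidden:
        if len(atoms) != arity + 1:
            raise ValueError(f"state {atoms} should have {arity} tokens "
                             "plus a class label")
        return tuple(atoms[:arity]), atoms[arity]
    if len(atoms) != arity:
        raise ValueError(f"state {atoms} should have {arity} tokens")
    return tuple(atoms), None


def _chain_from_sexpr(form: SExpr, alphabet: Alphabet) -> Chain:
    terminals: Optional[Tuple[str, ...]] = None
    hidden_row = hidden_labels = None
    body: List[SExpr] = []
    for sub in form.items[1:]:
        if not sub.is_list or not sub.items:
            continue
        tag = sub[0].atom
        if tag == "terminal":
            t = sub[1]
            terminals = ((t.atom,) if t.is_atom
                         else tuple(a.atom for a in t.items))
        elif tag == "hidden-class":
            for h in sub.items[1:]:
                if h[0].atom == "row":
                    hidden_row = h[1].atom
                elif h[0].atom == "label":
                    hidden_labels = tuple(a.atom for a in h[1].items)
        elif tag in ("initial", "mutate"):
            body.append(sub)
        elif tag in ("update-policy",):
            continue
        else:
            raise ValueError(f"unknown chain sub-block {tag!r}")
    if terminals is None:
        raise ValueError("chain lacks a (terminal ...) declaration")
    chain = Chain(terminals, alphabet, hidden_row, hidden_labels)
    arity, hidden = chain.arity, hidden_labels is not None
    for sub in body:
        parts = {p[0].atom: p for p in sub.items[1:] if p.is_list and p.items}
        if sub[0].atom == "initial":
            st = _parse_state(parts["state"][1], arity, hidden)
            chain.initial[st] = ParamExpr.parse(parts["prob"].items[1:])
        else:
            src = _parse_state(parts["from"][1], arity, hidden)
            dst = _parse_state(parts["to"][1], arity, hidden)
            expr = (ParamExpr.parse(parts["rate"].items[1:])
                    if "rate" in parts else ParamExpr.of(1))
            chain.mutate[(src, dst)] = expr
    return chain


def _rule_from_transform(form: SExpr, terms: set) -> Rule:
    parts = {p[0].atom: p for p in form.items[1:] if p.is_list and p.items}
    if "from" not in parts or "to" not in parts:
        raise ValueError("transform needs (from ...) and (to ...)")
    frm = parts["from"][1]
    lhs = frm.atom if frm.is_atom else frm[0].atom
    to = parts["to"]
    to_syms = []
    if len(to.items) > 1:
        t = to[1]
        to_syms = ([t.atom] if t.is_atom else
                   [a.atom for a in t.items if a.is_atom])
    prob = (ParamExpr.parse(parts["prob"].items[1:])
            if "prob" in parts else ParamExpr.of(1))

    if not to_syms:
        if lhs.endswith("*"):
            raise ValueError(f"return rule {lhs} cannot be an end rule")
        return Rule(RuleKind.END, lhs, prob=prob)
    if lhs.endswith("*"):
        if len(to_syms) != 1:
            raise ValueError(f"return rule {lhs} must go to one nonterminal")
        return Rule(RuleKind.RETURN, lhs, rhs=(to_syms[0],), prob=prob)
    if any(s in terms for s in to_syms):
        inner = [s for s in to_syms if s.endswith("*")]
        if len(inner) != 1:
            raise ValueError(
                f"emission from {lhs} must contain exactly one starred "
                f"nonterminal, got {to_syms}")
        pos = to_syms.index(inner[0])
        left = tuple(to_syms[:pos])
        right = tuple(to_syms[pos + 1:])
        bad = [s for s in left + right if s not in terms]
        if bad:
            raise ValueError(f"emission from {lhs} mixes nonterminals "
                             f"{bad} with pseudoterminals")
        return Rule(RuleKind.EMISSION, lhs, left_terms=left,
                    right_terms=right, inner=inner[0], prob=prob)
    if len(to_syms) == 1:
        return Rule(RuleKind.TRANSITION, lhs, rhs=(to_syms[0],), prob=prob)
    if len(to_syms) == 2:
        return Rule(RuleKind.BIFURCATION, lhs, rhs=tuple(to_syms), prob=prob)
    raise ValueError(f"cannot classify transform {lhs} -> {to_syms}")


def grammar_from_forest(forest: SExpr, alphabet: Optional[Alphabet] = None,
                        param_aliases: Optional[Dict[str, str]] = None,
                        name: str = "grammar") -> Grammar:
    """Build a :class:`Grammar` from a macro-free parse forest.

    Blocks may appear bare at top level or wrapped in a ``(grammar ...)``
    form; an ``(alphabet ...)`` block overrides the ``alphabet`` argument.
    ``param_aliases`` maps alternative parameter spellings onto declared
    ones (used e.g. to identify ``changeProb`` with ``leaveProb``).
    """
    blocks: List[SExpr] = []

    def collect(node: SExpr):
        for form in node.items:
            if not form.is_list or not form.items or not form[0].is_atom:
                continue
            if form[0].atom == "grammar":
                collect(form)
            else:
                blocks.append(form)

    collect(forest)

    params = ParamSet()
    chains: List[Union[Chain, HybridChain]] = []
    hybrid_specs: List[SExpr] = []
    transforms: List[SExpr] = []

    for form in blocks:
        tag = form[0].atom
        if tag == "alphabet":
            alphabet = Alphabet.from_sexpr(form)
        elif tag == "name":
            name = form[1].atom
        elif tag == "rate":
            decls = form.items[1:]
            if decls and decls[0].is_atom:
                # flat form: (rate name expr...) declares a single entry
                decls = [SExpr(items=list(decls))]
            for decl in decls:
                if not decl.is_list or not decl.items:
                    continue
                pname = decl[0].atom
                exprs = decl.items[1:]
                num = (parse_rational(exprs[0].atom)
                       if len(exprs) == 1 and exprs[0].is_atom else None)
                if num is not None:
                    params.rates[pname] = float(num)
                else:
                    params.aliases[pname] = ParamExpr.parse(exprs)
        elif tag == "pgroup":
            grp = {}
            for decl in form.items[1:]:
                if decl.is_list and decl.items:
                    grp[decl[0].atom] = float(parse_rational(decl[1].atom))
            params.pgroups.append(grp)
        elif tag == "const":
            for decl in form.items[1:]:
                if decl.is_list and decl.items:
                    params.consts[decl[0].atom] = float(
                        parse_rational(decl[1].atom))
        elif tag == "chain":
            pass  # second pass, needs the alphabet
        elif tag == "hybrid-chain":
            hybrid_specs.append(form)
        elif tag == "transform":
            transforms.append(form)
        elif tag == "annotate":
            pass
        else:
            raise ValueError(f"unknown grammar block {tag!r}")

    if alphabet is None:
        raise ValueError("no alphabet declared or supplied")

    for form in blocks:
        if form[0].atom == "chain":
            chains.append(_chain_from_sexpr(form, alphabet))

    by_terminal = {t: c for c in chains for t in c.terminals}
    for form in hybrid_specs:
        terminals = default = None
        comps: Dict[str, Chain] = {}
        for sub in form.items[1:]:
            tag = sub[0].atom
            if tag == "terminal":
                t = sub[1]
                terminals = ((t.atom,) if t.is_atom
                             else tuple(a.atom for a in t.items))
            elif tag == "default":
                default = by_terminal[sub[1].atom]
            elif tag == "components":
                for decl in sub.items[1:]:
                    comps[decl[0].atom] = by_terminal[decl[1].atom]
        if terminals is None or default is None:
            raise ValueError("hybrid-chain needs (terminal ...) and (default ...)")
        chains.append(HybridChain(terminals, comps, default))

    if param_aliases:
        for alias, target in param_aliases.items():
            if not params.has(alias):
                params.aliases[alias] = ParamExpr.of(target)

    g = Grammar(name, alphabet, chains, [], params)
    terms = set(g.pseudoterminals)
    for form in transforms:
        g.rules.append(_rule_from_transform(form, terms))
    if "start" not in g.nonterminals and g.rules:
        g.start = g.rules[0].lhs
    return g


def read_grammar(source: Union[str, Path], tree=None,
                 n_columns: Optional[int] = None,
                 include_dirs: Sequence[Union[str, Path]] = (),
                 param_aliases: Optional[Dict[str, str]] = None) -> Grammar:
    """Parse a grammar file or text: read S-expressions, find the alphabet
    (macros may depend on it), expand macros, and build the grammar."""
    path: Optional[Path] = None
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and Path(source).is_file()):
        path = Path(source)
        text = path.read_text()
    else:
        text = str(source)
    forest = parse_sexpr(text)

    alphabet = None
    for form in forest.items:
        if form.is_list and form.items and form[0] == SExpr.a("alphabet"):
            alphabet = Alphabet.from_sexpr(form)
        elif form.is_list and form.items and form[0] == SExpr.a("grammar"):
            for sub in form.items:
                if sub.is_list and sub.items and sub[0] == SExpr.a("alphabet"):
                    alphabet = Alphabet.from_sexpr(sub)

    env = MacroEnv(tokens=alphabet.tokens if alphabet else None, tree=tree,
                   n_columns=n_columns,
                   include_dirs=[Path(d) for d in include_dirs],
                   current_dir=path.parent if path else None)
    expanded = expand_macros(forest, env)
    return grammar_from_forest(expanded, alphabet=alphabet,
                               param_aliases=param_aliases)


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def _state_sexpr(st: State) -> SExpr:
    toks, cls = st
    atoms = [SExpr.a(t) for t in toks]
    if cls is not None:
        atoms.append(SExpr.a(cls))
    return SExpr.l(*atoms)


def _chain_sexpr(c: Chain) -> SExpr:
    forms: List[SExpr] = []
    if c.hidden_labels:
        forms.append(SExpr.l(SExpr.a("hidden-class"),
                             SExpr.l(SExpr.a("row"), SExpr.a(c.hidden_row)),
                             SExpr.l(SExpr.a("label"),
                                     SExpr.l(*[SExpr.a(l)
                                               for l in c.hidden_labels]))))
    term = (SExpr.a(c.terminals[0]) if c.arity == 1
            else SExpr.l(*[SExpr.a(t) for t in c.terminals]))
    forms.append(SExpr.l(SExpr.a("terminal"), term))
    idx = c.state_index()
    for st in sorted(c.initial, key=idx.get):
        forms.append(SExpr.l(SExpr.a("initial"),
                             SExpr.l(SExpr.a("state"), _state_sexpr(st)),
                             SExpr.l(SExpr.a("prob"),
                                     *c.initial[st].to_sexprs())))
    for (src, dst) in sorted(c.mutate, key=lambda p: (idx.get(p[0], -1),
                                                      idx.get(p[1], -1))):
        forms.append(SExpr.l(
            SExpr.a("mutate"),
            SExpr.l(SExpr.a("from"), _state_sexpr(src)),
            SExpr.l(SExpr.a("to"), _state_sexpr(dst)),
            SExpr.l(SExpr.a("rate"), *c.mutate[(src, dst)].to_sexprs())))
    return SExpr.l(SExpr.a("chain"), *forms)


def _rule_sexpr(r: Rule) -> SExpr:
    if r.kind is RuleKind.EMISSION:
        to = list(r.left_terms) + [r.inner] + list(r.right_terms)
    elif r.kind is RuleKind.END:
        to = []
    else:
        to = list(r.rhs)
    return SExpr.l(SExpr.a("transform"),
                   SExpr.l(SExpr.a("from"), SExpr.l(SExpr.a(r.lhs))),
                   SExpr.l(SExpr.a("to"), SExpr.l(*[SExpr.a(s) for s in to])),
                   SExpr.l(SExpr.a("prob"), *r.prob.to_sexprs()))


def write_grammar(g: Grammar) -> str:
    """Re-emit a grammar in the macro-free S-expression dialect.

    Byte-stable for identical inputs; used for trained-grammar output."""
    body: List[SExpr] = [SExpr.l(SExpr.a("name"), SExpr.a(g.name))]
    if g.params.rates or g.params.aliases:
        decls = [SExpr.l(SExpr.a(k), SExpr.a(f"{v:.10g}"))
                 for k, v in g.params.rates.items()]
        decls += [SExpr.l(SExpr.a(k), *e.to_sexprs())
                  for k, e in g.params.aliases.items()]
        body.append(SExpr.l(SExpr.a("rate"), *decls))
    for grp in g.params.pgroups:
        body.append(SExpr.l(SExpr.a("pgroup"),
                            *[SExpr.l(SExpr.a(k), SExpr.a(f"{v:.10g}"))
                              for k, v in grp.items()]))
    if g.params.consts:
        body.append(SExpr.l(SExpr.a("const"),
                            *[SExpr.l(SExpr.a(k), SExpr.a(f"{v:.10g}"))
                              for k, v in g.params.consts.items()]))

    hybrid_forms: List[SExpr] = []
    for c in g.chains:
        if isinstance(c, HybridChain):
            names: Dict[int, str] = {}
            comp_forms = []
            for label, comp in sorted(c.components.items()):
                cname = f"{c.terminals[0]}__{label}"
                names[id(comp)] = cname
                body.append(_chain_sexpr(comp.renamed((cname,) if comp.arity == 1
                                                     else tuple(f"{cname}.{i}"
                                                                for i in range(comp.arity)))))
                comp_forms.append(SExpr.l(SExpr.a(label), SExpr.a(cname)))
            dname = names.get(id(c.default))
            if dname is None:
                dname = f"{c.terminals[0]}__default"
                body.append(_chain_sexpr(c.default.renamed(
                    (dname,) if c.default.arity == 1
                    else tuple(f"{dname}.{i}" for i in range(c.default.arity)))))
            term = (SExpr.a(c.terminals[0]) if c.arity == 1
                    else SExpr.l(*[SExpr.a(t) for t in c.terminals]))
            hybrid_forms.append(SExpr.l(
                SExpr.a("hybrid-chain"),
                SExpr.l(SExpr.a("terminal"), term),
                SExpr.l(SExpr.a("components"), *comp_forms),
                SExpr.l(SExpr.a("default"), SExpr.a(dname))))
        else:
            body.append(_chain_sexpr(c))
    body.extend(hybrid_forms)
    body.extend(_rule_sexpr(r) for r in g.rules)

    out = write_sexpr(g.alphabet.to_sexpr()) + "\n"
    out += write_sexpr(SExpr.l(SExpr.a("grammar"), *body)) + "\n"
    return out
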