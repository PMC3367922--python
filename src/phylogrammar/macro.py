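"""Macro expansion for the grammar dialect.

The macro vocabulary lets repetitively-structured grammars be written
compactly: iterators over alphabet tokens (``&foreach-token``), integer
ranges (``&foreach-integer``), explicit lists (``&foreach``) and tree nodes
(``&foreach-node`` / ``&foreach-leaf`` / ``&foreach-branch``); a conditional
``&if`` with the string-equality test ``&eq``; token pasting ``&cat``;
arithmetic ``&+ &- &* &/``; bindings ``&define``; and file inclusion
``&include``.  Expansion is deterministic and the result contains no
``&``-prefixed atoms.

Arithmetic is exact: when every operand is a rational number the result is
a rational atom (``(&/ 1 3)`` -> ``1/3``), which keeps downstream
probability-group normalization exact.  When an operand is a symbolic
parameter name, the macro rewrites itself to a macro-free arithmetic form
(e.g. ``(/ leaveProb 2)``) that the probability-expression parser accepts.
Fused spellings such as ``&/1`` or ``&/changeProb`` are accepted as
tokenizer aliases for ``(&/ 1 ...)`` / ``(&/ changeProb ...)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .sexpr import SExpr, SExprError, parse_sexpr

__all__ = ["MacroEnv", "MacroError", "expand_macros"]


class MacroError(ValueError):
    def __init__(self, message: str, node: Optional[SExpr] = None):
        if node is not None:
            message = f"{message} (line {node.line}, column {node.col})"
        super().__init__(message)


@dataclass
class MacroEnv:
    """Expansion context: bindings, alphabet tokens, tree and alignment.

    ``tree`` may be any object exposing ``nodes_preorder()`` yielding nodes
    with ``label``/``children``/``parent`` attributes (see
    :class:`~phylogrammar.tree.PhyloTree`).
    """

    defines: Dict[str, SExpr] = field(default_factory=dict)
    tokens: Optional[Sequence[str]] = None
    tree: object = None
    n_columns: Optional[int] = None
    include_dirs: List[Path] = field(default_factory=list)
    current_dir: Optional[Path] = None

    def child(self) -> "MacroEnv":
        env = MacroEnv(dict(self.defines), self.tokens, self.tree,
                       self.n_columns, list(self.include_dirs),
                       self.current_dir)
        return env


_NUM_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
_FRAC_RE = re.compile(r"^[+-]?\d+/\d+$")
_FUSED_RE = re.compile(r"^&([+\-*/])(.+)$")

_TREE_ITERS = {"&foreach-node": "nodes", "&foreach-leaf": "leaves",
               "&foreach-branch": "branches"}
_LIST_ATOMS = {"&NODES": "nodes", "&LEAVES": "leaves",
               "&BRANCHES": "branches", "&COLUMNS": "columns"}


def parse_rational(text: str) -> Optional[Fraction]:
    """Exact rational value of an atom spelling, or None if non-numeric."""
    if _FRAC_RE.match(text):
        num, den = text.split("/")
        return Fraction(int(num), int(den))
    if _NUM_RE.match(text):
        if re.search(r"[.eE]", text):
            return Fraction(text)
        return Fraction(int(text))
    return None


def format_rational(x: Fraction) -> str:
    if x.denominator == 1:
        return str(x.numerator)
    return f"{x.numerator}/{x.denominator}"


def expand_macros(expr: SExpr, env: MacroEnv) -> SExpr:
    """Expand every macro in ``expr``; the result contains no ``&``-atoms.

    Macro-free input is a fixed point.  Iterator macros splice one copy per
    element into the enclosing list; a macro expanding to nothing (e.g. the
    empty-list branch of an ``&if``) is spliced out entirely.
    """
    out = _expand(expr, env)
    if len(out) == 1:
        return out[0]
    return SExpr(items=out, line=expr.line, col=expr.col)


def _tree_labels(env: MacroEnv, kind: str, node: SExpr) -> List[str]:
    if env.tree is None:
        raise MacroError(f"no tree in context for tree iterator ({kind})", node)
    if kind == "nodes":
        return [n.label for n in env.tree.nodes_preorder()]
    if kind == "leaves":
        return [n.label for n in env.tree.leaves()]
    # branches are named by their child node
    return [n.label for n in env.tree.nodes_preorder() if n.parent is not None]


def _atom_value(nodes: List[SExpr], ctx: SExpr) -> str:
    if len(nodes) != 1 or not nodes[0].is_atom:
        raise MacroError("expected a single atom here", ctx)
    return nodes[0].atom


def _expand(node: SExpr, env: MacroEnv) -> List[SExpr]:
    if node.is_atom:
        a = node.atom
        if a in env.defines:
            binding = env.defines[a]
            if binding.is_atom and binding.atom == a:
                # a binding to its own spelling (e.g. an iterator variable
                # named after a token) is already fully expanded
                return [SExpr(atom=a, line=node.line, col=node.col)]
            return _expand(binding, env)
        if a in _LIST_ATOMS:
            kind = _LIST_ATOMS[a]
            if kind == "columns":
                if env.n_columns is None:
                    raise MacroError("no alignment in context for &COLUMNS", node)
                return [SExpr.a(str(i + 1)) for i in range(env.n_columns)]
            return [SExpr.a(lbl) for lbl in _tree_labels(env, kind, node)]
        if a.startswith("&"):
            raise MacroError(f"unknown macro {a!r}", node)
        return [SExpr(atom=a, line=node.line, col=node.col)]

    if not node.items:
        return [SExpr(items=[], line=node.line, col=node.col)]

    head = node.items[0]
    if head.is_atom and head.atom.startswith("&"):
        return _expand_macro_call(node, env)

    out: List[SExpr] = []
    for child in node.items:
        out.extend(_expand(child, env))
    return [SExpr(items=out, line=node.line, col=node.col)]


def _splice_body(node: SExpr, env: MacroEnv, var: str, values, body) -> List[SExpr]:
    out: List[SExpr] = []
    for v in values:
        sub = env.child()
        sub.defines[var] = SExpr.a(str(v))
        for b in body:
            for e in _expand(b, sub):
                if e.is_list and not e.items:
                    continue  # iteration arm expanded to (): ignored
                out.append(e)
    return out


def _expand_macro_call(node: SExpr, env: MacroEnv) -> List[SExpr]:
    items = node.items
    name = items[0].atom
    m = _FUSED_RE.match(name)
    if m and name not in _KNOWN:
        # tokenizer alias: (&/1 x) == (&/ 1 x), (&/changeProb y) == (&/ changeProb y)
        items = [SExpr.a("&" + m.group(1), node.line, node.col),
                 SExpr.a(m.group(2), node.line, node.col)] + items[1:]
        name = items[0].atom
        node = SExpr(items=items, line=node.line, col=node.col)

    args = items[1:]

    if name == "&define":
        if len(args) < 2 or not args[0].is_atom:
            raise MacroError("&define expects a name and a value", node)
        if len(args) == 2:
            value = expand_macros(args[1], env)
        else:
            value = SExpr(items=[x for a in args[1:] for x in _expand(a, env)])
        env.defines[args[0].atom] = value
        return []

    if name == "&include":
        if len(args) != 1 or not args[0].is_atom:
            raise MacroError("&include expects one file name", node)
        fname = args[0].atom.strip('"')
        path = _resolve_include(fname, env, node)
        sub = env.child()
        sub.current_dir = path.parent
        forest = parse_sexpr(path.read_text())
        out: List[SExpr] = []
        for form in forest.items:
            out.extend(_expand(form, sub))
        env.defines.update(sub.defines)
        return out

    if name == "&foreach-token":
        if env.tokens is None:
            raise MacroError("no alphabet in context for &foreach-token", node)
        if not args or not args[0].is_atom:
            raise MacroError("&foreach-token expects a variable name", node)
        return _splice_body(node, env, args[0].atom, env.tokens, args[1:])

    if name == "&foreach":
        if len(args) < 2 or not args[0].is_atom or not args[1].is_list:
            raise MacroError("&foreach expects a variable and a list", node)
        values = []
        for v in args[1].items:
            values.extend(e.atom for e in _expand(v, env))
        return _splice_body(node, env, args[0].atom, values, args[2:])

    if name == "&foreach-integer":
        if len(args) < 2 or not args[0].is_atom or not args[1].is_list \
                or len(args[1].items) != 2:
            raise MacroError("&foreach-integer expects VAR (FROM TO)", node)
        lo, hi = (_eval_number(a, env, node) for a in args[1].items)
        values = range(int(lo), int(hi) + 1)
        return _splice_body(node, env, args[0].atom, values, args[2:])

    if name in _TREE_ITERS:
        if not args or not args[0].is_atom:
            raise MacroError(f"{name} expects a variable name", node)
        labels = _tree_labels(env, _TREE_ITERS[name], node)
        return _splice_body(node, env, args[0].atom, labels, args[1:])

    if name == "&if":
        if len(args) not in (2, 3):
            raise MacroError("&if expects (condition) (then) [(else)]", node)
        cond = _truth(args[0], env)
        branch = args[1] if cond else (args[2] if len(args) == 3 else None)
        if branch is None:
            return []
        out = _expand(branch, env)
        if len(out) == 1 and out[0].is_list and not out[0].items:
            return []  # branch expanded to (): ignored
        return out

    if name in ("&eq", "&neq"):
        vals = [_atom_value(_expand(a, env), node) for a in args]
        if len(vals) != 2:
            raise MacroError(f"{name} expects two arguments", node)
        eq = vals[0] == vals[1]
        return [SExpr.a("1" if eq == (name == "&eq") else "0")]

    if name in ("&eq-num", "&lt", "&gt", "&leq", "&geq"):
        if len(args) != 2:
            raise MacroError(f"{name} expects two arguments", node)
        x, y = (_eval_number(a, env, node) for a in args)
        ok = {"&eq-num": x == y, "&lt": x < y, "&gt": x > y,
              "&leq": x <= y, "&geq": x >= y}[name]
        return [SExpr.a("1" if ok else "0")]

    if name == "&cat":
        parts: List[str] = []
        for a in args:
            for e in _expand(a, env):
                if not e.is_atom:
                    raise MacroError("&cat arguments must expand to atoms", node)
                parts.append(e.atom)
        return [SExpr.a("".join(parts))]

    if name in ("&+", "&-", "&*", "&/"):
        vals = []
        for a in args:
            ex = _expand(a, env)
            vals.append(_atom_value(ex, node) if (len(ex) == 1 and ex[0].is_atom)
                        else ex[0])
        nums = [parse_rational(v) if isinstance(v, str) else None for v in vals]
        if all(n is not None for n in nums) and nums:
            return [SExpr.a(format_rational(_arith(name, nums, node)))]
        # symbolic operand: rewrite to a macro-free arithmetic form
        op = SExpr.a(name[1:])
        sym = [v if isinstance(v, SExpr) else SExpr.a(v) for v in vals]
        return [SExpr(items=[op] + sym, line=node.line, col=node.col)]

    raise MacroError(f"unknown macro {name!r}", node)


_KNOWN = {"&define", "&include", "&foreach-token", "&foreach",
          "&foreach-integer", "&if", "&eq", "&neq", "&eq-num", "&lt",
          "&gt", "&leq", "&geq", "&cat", "&+", "&-", "&*", "&/",
          *_TREE_ITERS}


def _arith(name: str, nums: List[Fraction], node: SExpr) -> Fraction:
    acc = nums[0]
    for x in nums[1:]:
        if name == "&+":
            acc += x
        elif name == "&-":
            acc -= x
        elif name == "&*":
            acc *= x
        else:
            if x == 0:
                raise MacroError("division by zero in &/", node)
            acc /= x
    if name == "&-" and len(nums) == 1:
        acc = -acc
    return acc


def _eval_number(a: SExpr, env: MacroEnv, node: SExpr) -> Fraction:
    val = _atom_value(_expand(a, env), node)
    num = parse_rational(val)
    if num is None:
        raise MacroError(f"expected a number, got {val!r}", node)
    return num


def _truth(cond: SExpr, env: MacroEnv) -> bool:
    out = _expand(cond, env)
    if len(out) == 1 and out[0].is_atom:
        v = parse_rational(out[0].atom)
        if v is not None:
            return v != 0
        return bool(out[0].atom)
    return bool(out)


def _resolve_include(fname: str, env: MacroEnv, node: SExpr) -> Path:
    candidates = []
    if env.current_dir is not None:
        candidates.append(env.current_dir / fname)
    candidates.extend(d / fname for d in env.include_dirs)
    candidates.append(Path(fname))
    for c in candidates:
        if c.is_file():
            return c
    raise MacroError(f"cannot resolve &include file {fname!r}", node)
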