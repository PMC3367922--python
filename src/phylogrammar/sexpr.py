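"""Lisp-style S-expression reader/writer for grammar files.

Grammar files are UTF-8 text in a small Lisp dialect: atoms separated by
whitespace, lists in parentheses, and ``;;`` line comments which are
discarded at read time.  Every node remembers its source position so that
errors in hand-written grammar files point at the offending token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional

__all__ = ["SExpr", "SExprError", "parse_sexpr", "write_sexpr"]


class SExprError(ValueError):
    """Malformed S-expression input."""

    def __init__(self, message: str, line: int = 0, col: int = 0):
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


@dataclass
class SExpr:
    """Either an atom (``atom`` is a string) or a list (``items`` is set).

    Structural equality ignores source positions, so a parsed expression
    compares equal to its serialized-and-reparsed form.
    """

    atom: Optional[str] = None
    items: Optional[List["SExpr"]] = None
    line: int = 0
    col: int = 0

    def __post_init__(self):
        if (self.atom is None) == (self.items is None):
            raise ValueError("SExpr must be exactly one of atom or list")

    @property
    def is_atom(self) -> bool:
        return self.atom is not None

    @property
    def is_list(self) -> bool:
        return self.items is not None

    def __len__(self) -> int:
        return 0 if self.items is None else len(self.items)

    def __iter__(self) -> Iterator["SExpr"]:
        return iter(self.items or ())

    def __getitem__(self, i):
        if self.items is None:
            raise TypeError("atom is not subscriptable")
        return self.items[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SExpr):
            return NotImplemented
        if self.is_atom or other.is_atom:
            return self.atom == other.atom
        if len(self.items) != len(other.items):
            return False
        return all(a == b for a, b in zip(self.items, other.items))

    def __hash__(self):
        if self.is_atom:
            return hash(("atom", self.atom))
        return hash(("list", tuple(self.items)))

    def __repr__(self):
        return f"SExpr({write_sexpr(self)!r})"

    # Convenience constructors -------------------------------------------
    @staticmethod
    def a(token: str, line: int = 0, col: int = 0) -> "SExpr":
        return SExpr(atom=str(token), line=line, col=col)

    @staticmethod
    def l(*items: "SExpr", line: int = 0, col: int = 0) -> "SExpr":
        return SExpr(items=list(items), line=line, col=col)


_DELIMS = "()"


def _tokenize(text: str):
    """Yield (token, line, col); tokens are '(', ')' or atom strings."""
    line, col = 1, 1
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            col = 1
            i += 1
            continue
        if c.isspace():
            i += 1
            col += 1
            continue
        if text.startswith(";;", i):
            while i < n and text[i] != "\n":
                i += 1
            continue
        if c in _DELIMS:
            yield c, line, col
            i += 1
            col += 1
            continue
        start, scol = i, col
        while i < n and not text[i].isspace() and text[i] not in _DELIMS \
                and not text.startswith(";;", i):
            i += 1
            col += 1
        yield text[start:i], line, scol


def parse_sexpr(text: str) -> SExpr:
    """Parse ``text`` into a single list SExpr holding every top-level form.

    Empty input yields an empty list.  Unbalanced parentheses raise
    :class:`SExprError` with the offending position.
    """
    root = SExpr(items=[], line=1, col=1)
    stack = [root]
    last_open = []
    for tok, line, col in _tokenize(text):
        if tok == "(":
            node = SExpr(items=[], line=line, col=col)
            stack[-1].items.append(node)
            stack.append(node)
            last_open.append((line, col))
        elif tok == ")":
            if len(stack) == 1:
                raise SExprError("unbalanced ')'", line, col)
            stack.pop()
            last_open.pop()
        else:
            stack[-1].items.append(SExpr(atom=tok, line=line, col=col))
    if len(stack) != 1:
        line, col = last_open[-1]
        raise SExprError("unbalanced '(' — missing close parenthesis", line, col)
    return root


def write_sexpr(expr: SExpr, toplevel: bool = False) -> str:
    """Serialize an SExpr.  ``toplevel=True`` renders a parse forest one
    form per line (inverse of :func:`parse_sexpr`)."""
    if expr.is_atom:
        return expr.atom
    inner = [write_sexpr(e) for e in expr.items]
    if toplevel:
        return "\n".join(inner) + ("\n" if inner else "")
    return "(" + " ".join(inner) + ")"
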