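"""Alphabets: ordered token sets with complement, wildcard and gap symbols."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .sexpr import SExpr

__all__ = ["Alphabet", "DNA", "RNA"]

GAP_CHARS = ("-", ".", "_")


@dataclass(frozen=True)
class Alphabet:
    """An ordered alphabet of single-character tokens.

    Token order is significant: it is the iteration order of
    ``&foreach-token`` and fixes the state index map of every chain built
    over this alphabet.  Characters outside the alphabet that are not gaps
    (IUPAC ambiguity codes, ``*``, ``?``, ``n``/``x``) are treated as
    wildcards, i.e. missing data.
    """

    name: str
    tokens: Tuple[str, ...]
    complement: Optional[Dict[str, str]] = None
    wildcard: str = "*"

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens) or not self.tokens:
            raise ValueError("alphabet tokens must be unique and nonempty")
        if self.complement is not None:
            for k, v in self.complement.items():
                if self.complement.get(v) != k:
                    raise ValueError("complement map must be an involution")

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self.tokens.index(token)

    def is_gap(self, ch: str) -> bool:
        return ch in GAP_CHARS

    def indicator(self, ch: str) -> np.ndarray:
        """Observation indicator over tokens for one alignment character.

        A concrete token gives a one-hot vector; gaps, the wildcard and any
        unrecognized (ambiguity) character give all-ones (missing data).
        """
        ch = ch.lower()
        ind = np.zeros(self.size)
        if ch in self.tokens:
            ind[self.index(ch)] = 1.0
            return ind
        return np.ones(self.size)

    # S-expression dialect ------------------------------------------------
    def to_sexpr(self) -> SExpr:
        forms = [SExpr.l(SExpr.a("name"), SExpr.a(self.name)),
                 SExpr.l(SExpr.a("token"),
                         SExpr.l(*[SExpr.a(t) for t in self.tokens]))]
        if self.complement:
            forms.append(SExpr.l(SExpr.a("complement"),
                                 SExpr.l(*[SExpr.a(self.complement[t])
                                           for t in self.tokens])))
        forms.append(SExpr.l(SExpr.a("wildcard"), SExpr.a(self.wildcard)))
        return SExpr.l(SExpr.a("alphabet"), *forms)

    @staticmethod
    def from_sexpr(form: SExpr) -> "Alphabet":
        name, tokens, comp, wildcard = "alphabet", None, None, "*"
        for sub in form.items[1:]:
            if not sub.is_list or not sub.items or not sub[0].is_atom:
                continue
            tag = sub[0].atom
            if tag == "name":
                name = sub[1].atom
            elif tag == "token":
                tokens = tuple(a.atom for a in sub[1].items)
            elif tag == "complement":
                comp = tuple(a.atom for a in sub[1].items)
            elif tag == "wildcard":
                wildcard = sub[1].atom
        if tokens is None:
            raise ValueError("alphabet block lacks a (token (...)) declaration")
        comp_map = None
        if comp is not None:
            if len(comp) != len(tokens):
                raise ValueError("complement list length != token list length")
            comp_map = dict(zip(tokens, comp))
        return Alphabet(name, tokens, comp_map, wildcard)


DNA = Alphabet("dna", ("a", "c", "g", "t"),
               {"a": "t", "t": "a", "c": "g", "g": "c"})
RNA = Alphabet("rna", ("a", "c", "g", "u"),
               {"a": "u", "u": "a", "c": "g", "g": "c"})
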