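"""Parameters: rates, probability groups, constants, and product expressions.

A :class:`ParamExpr` is the parametric form used both for substitution
rates and rule probabilities: a product of factors, each a parameter name
or a rational literal.  ``(rate u class1)`` multiplies ``u`` by the value
bound to ``class1``; ``(prob (/ leaveProb 2))`` is ``leaveProb`` times the
literal ``1/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .macro import format_rational, parse_rational
from .sexpr import SExpr

__all__ = ["ParamExpr", "ParamSet", "ParamError"]

Factor = Union[str, Fraction]


class ParamError(KeyError):
    pass


@dataclass(frozen=True)
class ParamExpr:
    """Product of parameter names and rational literals; value >= 0 for any
    nonnegative parameter assignment."""

    factors: Tuple[Factor, ...] = ()

    @staticmethod
    def of(*factors: Union[str, int, float, Fraction]) -> "ParamExpr":
        out: List[Factor] = []
        for f in factors:
            if isinstance(f, str):
                num = parse_rational(f)
                out.append(num if num is not None else f)
            elif isinstance(f, Fraction):
                out.append(f)
            else:
                out.append(Fraction(f).limit_denominator(10**12)
                           if isinstance(f, float) else Fraction(f))
        return ParamExpr(tuple(out))

    @staticmethod
    def parse(forms: Sequence[SExpr]) -> "ParamExpr":
        """Parse the operand list of a ``(rate ...)`` / ``(prob ...)`` clause.

        Accepts atoms (names or numbers) and the macro-free arithmetic
        forms ``(* a b ...)`` and ``(/ a b)`` with a numeric divisor.
        """
        factors: List[Factor] = []

        def walk(form: SExpr):
            if form.is_atom:
                num = parse_rational(form.atom)
                factors.append(num if num is not None else form.atom)
                return
            if not form.items:
                return
            head = form[0].atom if form[0].is_atom else None
            if head == "*":
                for sub in form.items[1:]:
                    walk(sub)
            elif head == "/":
                if len(form.items) != 3:
                    raise ValueError("(/ a b) takes exactly two operands")
                walk(form[1])
                den = parse_rational(form[2].atom) if form[2].is_atom else None
                if den is None or den == 0:
                    raise ValueError("divisor must be a nonzero number")
                factors.append(Fraction(1) / den)
            else:
                raise ValueError(f"cannot parse expression {form!r}")

        for f in forms:
            walk(f)
        return ParamExpr(tuple(factors))

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(f for f in self.factors if isinstance(f, str))

    def value(self, params: "ParamSet") -> float:
        v = 1.0
        for f in self.factors:
            v *= params.value(f) if isinstance(f, str) else float(f)
        return v

    def value_excluding(self, params: "ParamSet", name: str) -> float:
        """Product of all factors except one occurrence of ``name``."""
        v, skipped = 1.0, False
        for f in self.factors:
            if not skipped and f == name:
                skipped = True
                continue
            v *= params.value(f) if isinstance(f, str) else float(f)
        return v

    def to_sexprs(self) -> List[SExpr]:
        return [SExpr.a(f if isinstance(f, str) else format_rational(f))
                for f in self.factors]


@dataclass
class ParamSet:
    """Rate parameters, probability groups, constants and aliases.

    Probability groups (``pgroup``) are finite distributions whose members
    are renormalized to sum to one; rate parameters are free nonnegative
    reals.  An alias maps a name to a :class:`ParamExpr` over other
    parameters (e.g. the ``Q_a_c = u`` entries a grammar file may declare)
    and contributes no degree of freedom.
    """

    rates: Dict[str, float] = field(default_factory=dict)
    pgroups: List[Dict[str, float]] = field(default_factory=list)
    consts: Dict[str, float] = field(default_factory=dict)
    aliases: Dict[str, ParamExpr] = field(default_factory=dict)

    def copy(self) -> "ParamSet":
        return ParamSet(dict(self.rates), [dict(g) for g in self.pgroups],
                        dict(self.consts), dict(self.aliases))

    # Lookup ---------------------------------------------------------------
    def value(self, name: str) -> float:
        if name in self.rates:
            return self.rates[name]
        for g in self.pgroups:
            if name in g:
                return g[name]
        if name in self.consts:
            return self.consts[name]
        if name in self.aliases:
            return self.aliases[name].value(self)
        raise ParamError(f"unbound parameter {name!r}")

    def has(self, name: str) -> bool:
        try:
            self.value(name)
            return True
        except ParamError:
            return False

    def is_free(self, name: str) -> bool:
        return name in self.rates or any(name in g for g in self.pgroups)

    @property
    def free_parameters(self) -> Tuple[str, ...]:
        names = list(self.rates)
        for g in self.pgroups:
            names.extend(g)
        return tuple(names)

    def pgroup_of(self, name: str) -> Optional[Dict[str, float]]:
        for g in self.pgroups:
            if name in g:
                return g
        return None

    # Mutation -------------------------------------------------------------
    def set(self, name: str, value: float) -> None:
        if name in self.rates:
            self.rates[name] = value
            return
        for g in self.pgroups:
            if name in g:
                g[name] = value
                return
        raise ParamError(f"{name!r} is not a free parameter")

    def normalize_pgroups(self, tol: float = 1e-9) -> None:
        """Renormalize each probability group to sum to one; a group whose
        declared seeds deviate by more than ``tol`` triggers a warning."""
        for g in self.pgroups:
            total = sum(g.values())
            if total <= 0:
                raise ValueError(f"pgroup {tuple(g)} has nonpositive total")
            if abs(total - 1.0) > tol:
                warnings.warn(
                    f"pgroup {tuple(g)} sums to {total:g}; renormalizing")
            for k in g:
                g[k] /= total
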