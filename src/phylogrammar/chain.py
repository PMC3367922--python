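"""Parametric continuous-time Markov chains over token tuples and hidden
classes, and their instantiation to numeric generator matrices.

A chain's state is a tuple of alphabet tokens (arity 1 for a single
column, 2 for paired columns, 3 for a codon triplet), optionally augmented
with a hidden-class label (e.g. slow/fast substitution mode).  States are
ordered token-major, class-minor, giving a deterministic index map.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .alphabet import Alphabet
from .params import ParamError, ParamExpr, ParamSet

__all__ = ["State", "Chain", "HybridChain", "RateMatrix", "instantiate_matrix"]

# A chain state: (token tuple, hidden-class label or None)
State = Tuple[Tuple[str, ...], Optional[str]]


@dataclass
class Chain:
    """A parametric substitution chain.

    ``terminals`` are the pseudoterminal names through which the chain
    emits column tuples; its length is the chain's arity.  ``mutate`` maps
    ordered state pairs to rate expressions; unlisted transitions have rate
    zero and diagonal entries are derived (negative row sums).  ``allowed``
    optionally restricts the state space (e.g. the 61 sense codons of a
    64-tuple codon space).
    """

    terminals: Tuple[str, ...]
    alphabet: Alphabet
    hidden_row: Optional[str] = None            # Stockholm #=GR tag
    hidden_labels: Optional[Tuple[str, ...]] = None
    initial: Dict[State, ParamExpr] = field(default_factory=dict)
    mutate: Dict[Tuple[State, State], ParamExpr] = field(default_factory=dict)
    allowed: Optional[Tuple[Tuple[str, ...], ...]] = None
    seeds: Dict[str, float] = field(default_factory=dict)  # suggested seed values

    @property
    def name(self) -> str:
        return "~".join(self.terminals)

    @property
    def arity(self) -> int:
        return len(self.terminals)

    @property
    def class_labels(self) -> Tuple[str, ...]:
        return self.hidden_labels or (None,)

    @property
    def states(self) -> Tuple[State, ...]:
        tuples = (self.allowed if self.allowed is not None
                  else tuple(itertools.product(self.alphabet.tokens,
                                               repeat=self.arity)))
        return tuple((t, c) for t in tuples for c in self.class_labels)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self) -> Dict[State, int]:
        return {s: i for i, s in enumerate(self.states)}

    def scaled(self, factor) -> "Chain":
        """A copy whose every mutate rate gains an extra multiplicative
        factor (a parameter name or a number)."""
        extra = ParamExpr.of(factor)
        mut = {k: ParamExpr(v.factors + extra.factors)
               for k, v in self.mutate.items()}
        return Chain(self.terminals, self.alphabet, self.hidden_row,
                     self.hidden_labels, dict(self.initial), mut, self.allowed,
                     dict(self.seeds))

    def renamed(self, terminals: Sequence[str]) -> "Chain":
        return Chain(tuple(terminals), self.alphabet, self.hidden_row,
                     self.hidden_labels, dict(self.initial),
                     dict(self.mutate), self.allowed, dict(self.seeds))


@dataclass
class HybridChain:
    """A lineage-specific chain: the substitution process differs across
    tree branches.

    Each branch resolves to a component by the *label of its child node*:
    if that label is a key of ``components`` the branch evolves under that
    component, otherwise under ``default``.  All components must share
    alphabet, arity and hidden-class structure.
    """

    terminals: Tuple[str, ...]
    components: Dict[str, Chain]
    default: Chain

    def __post_init__(self):
        for c in self.components.values():
            if (c.arity != self.default.arity
                    or c.alphabet.tokens != self.default.alphabet.tokens
                    or c.class_labels != self.default.class_labels):
                raise ValueError(
                    "hybrid chain components must share alphabet, arity "
                    "and class labels")

    @property
    def name(self) -> str:
        return "~".join(self.terminals)

    @property
    def arity(self) -> int:
        return self.default.arity

    @property
    def alphabet(self) -> Alphabet:
        return self.default.alphabet

    @property
    def hidden_row(self):
        return self.default.hidden_row

    @property
    def hidden_labels(self):
        return self.default.hidden_labels

    @property
    def class_labels(self):
        return self.default.class_labels

    @property
    def states(self):
        return self.default.states

    @property
    def n_states(self):
        return self.default.n_states

    def resolve(self, child_label: Optional[str]) -> Chain:
        if child_label is not None and child_label in self.components:
            return self.components[child_label]
        return self.default

    def component_set(self) -> List[Chain]:
        seen, out = set(), []
        for c in list(self.components.values()) + [self.default]:
            if id(c) not in seen:
                seen.add(id(c))
                out.append(c)
        return out


@dataclass
class RateMatrix:
    """A numeric generator: off-diagonals >= 0, diagonal = negative row sum,
    plus an initial distribution over the same state order."""

    Q: np.ndarray
    pi: np.ndarray
    states: Tuple[State, ...]

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self) -> Dict[State, int]:
        return {s: i for i, s in enumerate(self.states)}

    def expected_rate(self) -> float:
        """Expected number of events per unit time at the initial
        distribution: -sum_i pi_i Q_ii."""
        return float(-np.dot(self.pi, np.diag(self.Q)))


def _stationary(Q: np.ndarray) -> Optional[np.ndarray]:
    ns = scipy.linalg.null_space(Q.T)
    if ns.shape[1] != 1:
        return None
    v = ns[:, 0].real
    if abs(v.sum()) < 1e-12:
        return None
    v = v / v.sum()
    if np.any(v < -1e-9):
        return None
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


def _is_irreducible(Q: np.ndarray) -> bool:
    adj = (Q > 0).astype(int)
    n_comp, _ = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong")
    return n_comp == 1


def instantiate_matrix(chain: Chain, params: ParamSet) -> RateMatrix:
    """Evaluate a chain's rate expressions to a numeric generator.

    Off-diagonal ``Q[i, j]`` is the product of the factors of the
    ``(i -> j)`` mutate entry (zero if absent); diagonals are filled in as
    negative row sums.  The initial distribution comes from the chain's
    declared ``initial`` entries, renormalized if needed; a chain with no
    initial entries gets its stationary distribution when the generator is
    irreducible, else the uniform distribution.
    """
    states = chain.states
    idx = chain.state_index()
    n = len(states)
    Q = np.zeros((n, n))
    for (src, dst), expr in chain.mutate.items():
        if src not in idx or dst not in idx:
            continue  # entries outside the allowed state space are inert
        try:
            rate = expr.value(params)
        except ParamError as e:
            raise ParamError(
                f"chain {chain.name!r}: {e.args[0]}") from None
        if rate < 0:
            raise ValueError(
                f"chain {chain.name!r}: negative rate for {src}->{dst}")
        Q[idx[src], idx[dst]] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))

    if chain.initial:
        pi = np.zeros(n)
        for s, expr in chain.initial.items():
            if s in idx:
                pi[idx[s]] = expr.value(params)
        total = pi.sum()
        if total <= 0:
            raise ValueError(
                f"chain {chain.name!r}: initial distribution sums to {total}")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"chain {chain.name!r}: initial distribution sums to "
                f"{total:g}; renormalizing")
        pi = pi / total
    else:
        pi = None
        if n > 0 and _is_irreducible(Q):
            pi = _stationary(Q)
        if pi is None:
            pi = np.full(n, 1.0 / n)
    return RateMatrix(Q, pi, states)
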