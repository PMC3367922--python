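"""Per-column phylogenetic likelihood machinery.

Implements Felsenstein's pruning recursion (vectorized across alignment
columns, with per-node scaling so megabase-scale alignments stay in
range), marginal ancestral reconstruction by the inside-outside recursion
on the tree, and the branch integrals that turn endpoint posteriors into
expected substitution counts and state wait times for EM.

Gaps and wildcards are missing data: their observation indicator is one
for every state.  Hybrid chains resolve a component per branch via the
child node's label; the root initial distribution is the default
component's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.linalg

from .chain import Chain, HybridChain, RateMatrix, instantiate_matrix
from .params import ParamSet
from .tree import PhyloTree, TreeNode

__all__ = ["matrix_exponential", "ChainEngine", "PhyloEmitter",
           "felsenstein_likelihood", "ancestral_marginal"]

_TINY = 1e-300


def matrix_exponential(Q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) for a generator Q and branch length t >= 0.

    Rows sum to one; negative entries from roundoff (>= -1e-12) are
    clamped to zero.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    P = scipy.linalg.expm(np.asarray(Q, dtype=float) * t)
    if P.min() < -1e-12:
        raise FloatingPointError("matrix exponential produced a negative "
                                 f"entry {P.min():g}")
    return np.clip(P, 0.0, None)


class ChainEngine:
    """Numeric engine for one concrete chain component.

    Caches transition matrices exp(Qt) per branch length and holds the
    eigendecomposition used both for fast exponentials and for the
    closed-form branch integrals of the EM E-step.  Generators that are
    not diagonalizable to machine tolerance fall back to
    scaling-and-squaring exponentials and quadrature integrals.
    """

    def __init__(self, chain: Chain, params: ParamSet):
        self.chain = chain
        self.rm: RateMatrix = instantiate_matrix(chain, params)
        self.Q = self.rm.Q
        self.pi = self.rm.pi
        self.n = self.rm.n
        self._pcache: Dict[float, np.ndarray] = {}
        self._decompose()

    def _decompose(self) -> None:
        self.eig = None
        if self.n == 0:
            return
        try:
            w, A = np.linalg.eig(self.Q)
            B = np.linalg.inv(A)
            err = np.max(np.abs((A * w) @ B - self.Q))
            scale = max(1.0, np.max(np.abs(self.Q)))
            if np.isfinite(err) and err < 1e-9 * scale:
                self.eig = (w, A, B)
        except np.linalg.LinAlgError:
            pass

    def pmatrix(self, t: float) -> np.ndarray:
        P = self._pcache.get(t)
        if P is None:
            if self.eig is not None:
                w, A, B = self.eig
                P = np.real((A * np.exp(w * t)) @ B)
                P = np.clip(P, 0.0, None)
            else:
                P = matrix_exponential(self.Q, t)
            self._pcache[t] = P
        return P

    # EM branch integrals --------------------------------------------------
    def count_integral(self, t: float, G: np.ndarray) -> np.ndarray:
        """S with S[i, j] = sum_ab G[a, b] * int_0^t P(s)[a, i]
        P(t-s)[j, b] ds.

        Expected substitution counts on the branch are ``Q * S`` off the
        diagonal; expected wait times are ``diag(S)``.  ``G`` is the
        endpoint weight matrix (joint posterior over the branch's
        endpoints divided elementwise by P(t), summed over columns).
        """
        if t == 0:
            return np.zeros((self.n, self.n))
        if self.eig is not None:
            w, A, B = self.eig
            ew = np.exp(w * t)
            diff = w[:, None] - w[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                J = (ew[:, None] - ew[None, :]) / diff
            same = np.abs(diff) < 1e-12 * max(1.0, np.max(np.abs(w)))
            J[same] = (t * ew[:, None] * np.ones_like(J))[same]
            M = A.T @ G @ B.T
            S = B.T @ (J * M) @ A.T
            return np.real(S)
        # quadrature fallback for defective generators
        from scipy.integrate import fixed_quad

        def f(s_arr):
            vals = []
            for s in np.atleast_1d(s_arr):
                vals.append(matrix_exponential(self.Q, s).T @ G
                            @ matrix_exponential(self.Q, t - s).T)
            return np.stack(vals, axis=-1)

        xs, ws = np.polynomial.legendre.leggauss(24)
        xs = 0.5 * t * (xs + 1.0)
        ws = 0.5 * t * ws
        S = np.zeros((self.n, self.n))
        for x, wgt in zip(xs, ws):
            S += wgt * (matrix_exponential(self.Q, x).T @ G
                        @ matrix_exponential(self.Q, t - x).T)
        return S

    # Observation indicators ----------------------------------------------
    def state_indicator(self, tokens: Tuple[str, ...]) -> np.ndarray:
        """Indicator over chain states for one observed token tuple.

        Wildcards and gaps contribute 1 for every token; hidden-class
        labels are always unobserved (1 for every class).
        """
        chain = self.chain
        if len(tokens) != chain.arity:
            raise ValueError(f"token tuple {tokens} does not match chain "
                             f"arity {chain.arity}")
        per_pos = [chain.alphabet.indicator(ch) for ch in tokens]
        ind = np.empty(self.n)
        for k, (toks, _cls) in enumerate(chain.states):
            v = 1.0
            for p, tok in enumerate(toks):
                v *= per_pos[p][chain.alphabet.index(tok)]
            ind[k] = v
        return ind


def _engines_for(chain: Union[Chain, HybridChain],
                 params: ParamSet) -> Tuple[Dict[int, ChainEngine], ChainEngine]:
    if isinstance(chain, HybridChain):
        engines = {id(c): ChainEngine(c, params) for c in chain.component_set()}
        return engines, engines[id(chain.default)]
    eng = ChainEngine(chain, params)
    return {id(chain): eng}, eng


class PhyloEmitter:
    """Pruning/marginal machinery for one chain (plain or hybrid) on one
    tree, vectorized over alignment columns."""

    def __init__(self, chain: Union[Chain, HybridChain], tree: PhyloTree,
                 params: ParamSet):
        self.chain = chain
        self.tree = tree
        self.engines, self.root_engine = _engines_for(chain, params)
        self.pi = self.root_engine.pi
        self.n = self.root_engine.n
        self.states = self.root_engine.rm.states
        # per-branch (node with a parent) transition matrix
        self.P: Dict[int, np.ndarray] = {}
        self.branch_engine: Dict[int, ChainEngine] = {}
        for node in tree.nodes_preorder():
            if node.parent is None:
                continue
            comp = (chain.resolve(node.label) if isinstance(chain, HybridChain)
                    else chain)
            eng = self.engines[id(comp)]
            self.branch_engine[id(node)] = eng
            self.P[id(node)] = eng.pmatrix(node.length)
        self._fit = None

    # ------------------------------------------------------------------
    def leaf_matrix(self, tuples: Sequence[Tuple[str, ...]]) -> np.ndarray:
        """(L, n_states) indicator matrix for a leaf's observed tuples,
        memoizing per distinct tuple."""
        cache: Dict[Tuple[str, ...], np.ndarray] = {}
        rows = []
        for tup in tuples:
            v = cache.get(tup)
            if v is None:
                v = self.root_engine.state_indicator(tup)
                cache[tup] = v
            rows.append(v)
        return np.array(rows)

    def fit(self, leaf_tuples: Dict[str, Sequence[Tuple[str, ...]]]) -> np.ndarray:
        """Run the pruning (up) recursion; returns per-column
        log-likelihoods and stores messages for posterior queries."""
        leaves = {n.label for n in self.tree.leaves()}
        missing = leaves - set(leaf_tuples)
        if missing:
            raise KeyError(f"column data missing for leaf "
                           f"{sorted(missing)[0]!r}")
        L = len(next(iter(leaf_tuples.values())))
        F: Dict[int, np.ndarray] = {}
        s: Dict[int, np.ndarray] = {}
        for node in self.tree.nodes_postorder():
            if node.is_leaf:
                F[id(node)] = self.leaf_matrix(leaf_tuples[node.label])
                s[id(node)] = np.zeros(L)
            else:
                acc = np.ones((L, self.n))
                sc = np.zeros(L)
                for c in node.children:
                    acc = acc * (F[id(c)] @ self.P[id(c)].T)
                    sc = sc + s[id(c)]
                mx = np.maximum(acc.max(axis=1), _TINY)
                F[id(node)] = acc / mx[:, None]
                s[id(node)] = sc + np.log(mx)
        root = self.tree.root
        lik = F[id(root)] @ self.pi
        loglik = np.where(lik > 0, np.log(np.maximum(lik, _TINY)), -np.inf)
        loglik = loglik + s[id(root)]
        self._fit = (F, s, loglik, L)
        return loglik

    def _down(self):
        """Outside (down) recursion; memoized after :meth:`fit`."""
        F, s, loglik, L = self._require_fit()
        if len(self._fit) > 4:
            return self._fit[4], self._fit[5]
        D: Dict[int, np.ndarray] = {}
        mu: Dict[int, np.ndarray] = {}
        root = self.tree.root
        D[id(root)] = np.broadcast_to(self.pi, (L, self.n)).copy()
        mu[id(root)] = np.zeros(L)
        for node in self.tree.nodes_preorder():
            if node.is_leaf:
                continue
            down_msgs = [F[id(c)] @ self.P[id(c)].T for c in node.children]
            for i, c in enumerate(node.children):
                M = D[id(node)].copy()
                m = mu[id(node)].copy()
                for j, cj in enumerate(node.children):
                    if j == i:
                        continue
                    M = M * down_msgs[j]
                    m = m + s[id(cj)]
                Dm = M @ self.P[id(c)]
                mx = np.maximum(Dm.max(axis=1), _TINY)
                D[id(c)] = Dm / mx[:, None]
                mu[id(c)] = m + np.log(mx)
        self._fit = (F, s, loglik, L, D, mu)
        return D, mu

    def _require_fit(self):
        if self._fit is None:
            raise RuntimeError("call fit() first")
        return self._fit[:4]

    def posterior(self, node_label: str) -> np.ndarray:
        """(L, n_states) marginal posterior over states at the named node.

        The columnwise argmax of this distribution is the single
        most-probable state, so point reconstruction always agrees with
        the returned posterior.
        """
        node = self.tree.find(node_label)
        if node is None:
            raise KeyError(f"no node labeled {node_label!r} in tree")
        F, s, loglik, L = self._require_fit()
        D, mu = self._down()
        post = F[id(node)] * D[id(node)]
        total = post.sum(axis=1, keepdims=True)
        return post / np.maximum(total, _TINY)

    # EM statistics -----------------------------------------------------
    def branch_statistics(self, weights: np.ndarray):
        """Expected substitution counts and wait times per component.

        ``weights`` are per-column posterior weights (how much each column
        was emitted by this chain).  Returns ``{id(component): (chain,
        counts_matrix, wait_vector)}`` accumulated over all branches.
        """
        F, s, loglik, L = self._require_fit()
        D, mu = self._down()
        ok = np.isfinite(loglik) & (weights > 0)
        out: Dict[int, Tuple[Chain, np.ndarray, np.ndarray]] = {}
        for eng in self.engines.values():
            comp = eng.chain
            out[id(comp)] = (comp, np.zeros((self.n, self.n)),
                             np.zeros(self.n))
        for node in self.tree.nodes_preorder():
            if node.parent is None:
                continue
            eng = self.branch_engine[id(node)]
            # weight per column: w * exp(mu_c + s_c - loglik)
            expo = mu[id(node)] + s[id(node)] - loglik
            v = np.zeros(L)
            v[ok] = weights[ok] * np.exp(expo[ok])
            # Down message before multiplying through this branch:
            # reconstruct M from D of the parent side: D_c = M @ P, but we
            # stored only D; recompute M cheaply from parent quantities.
            M = self._parent_message(node, F, s, D, mu)
            G = (M * v[:, None]).T @ F[id(node)]
            S = eng.count_integral(node.length, G)
            comp, cmat, wvec = out[id(eng.chain)]
            np.fill_diagonal(S, np.maximum(np.diag(S), 0.0))
            cmat += np.clip(eng.Q * S, 0.0, None) * (1 - np.eye(self.n))
            wvec += np.diag(S)
        return out

    def _parent_message(self, node: TreeNode, F, s, D, mu) -> np.ndarray:
        parent = node.parent
        M = D[id(parent)].copy()
        for sib in parent.children:
            if sib is node:
                continue
            M = M * (F[id(sib)] @ self.P[id(sib)].T)
        return M

    def root_posterior_weighted(self, weights: np.ndarray) -> np.ndarray:
        """Expected root-state counts (for diagnostics)."""
        post = self.posterior(self.tree.root.label) if self.tree.root.label \
            else None
        if post is None:
            F, s, loglik, L = self._require_fit()
            post = F[id(self.tree.root)] * self.pi
            post = post / post.sum(axis=1, keepdims=True)
        return weights @ post


# ---------------------------------------------------------------------------
# Single-column conveniences
# ---------------------------------------------------------------------------

def _as_tuples(col: Dict[str, Union[str, Tuple[str, ...]]]):
    return {leaf: [tuple(tok) if not isinstance(tok, tuple) else tok]
            for leaf, tok in col.items()}


def felsenstein_likelihood(col: Dict[str, Union[str, Tuple[str, ...]]],
                           chain: Union[Chain, HybridChain],
                           tree: PhyloTree, params: ParamSet) -> float:
    """Likelihood of one column tuple: the sum over all ancestral state
    assignments of pi(root) times the product of branch transition
    probabilities times the leaf indicators."""
    em = PhyloEmitter(chain, tree, params)
    ll = em.fit(_as_tuples(col))
    return float(np.exp(ll[0])) if np.isfinite(ll[0]) else 0.0


def ancestral_marginal(col: Dict[str, Union[str, Tuple[str, ...]]],
                       chain: Union[Chain, HybridChain], tree: PhyloTree,
                       params: ParamSet, node: str) -> Dict:
    """Marginal posterior P(state at node | column), as {state: prob}."""
    em = PhyloEmitter(chain, tree, params)
    em.fit(_as_tuples(col))
    post = em.posterior(node)[0]
    return {st: float(p) for st, p in zip(em.states, post)}
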