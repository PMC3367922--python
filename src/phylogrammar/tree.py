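"""Rooted phylogenetic trees: Newick IO, rerooting, neighbor-joining.

Branch lengths are expected substitutions per site.  Newick necessarily
specifies a rooted tree; for time-reversible substitution models the root
placement is arbitrary and likelihoods are invariant under rerooting.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["TreeNode", "PhyloTree", "NewickError", "parse_newick",
           "write_newick", "neighbor_joining", "jc_distance_matrix"]


class NewickError(ValueError):
    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (position {pos})")
        self.pos = pos


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: float = 0.0          # branch length to parent; 0 at the root
    parent: Optional["TreeNode"] = None
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


@dataclass
class PhyloTree:
    root: TreeNode

    # Traversal ------------------------------------------------------------
    def nodes_preorder(self) -> List[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def nodes_postorder(self) -> List[TreeNode]:
        return list(reversed([n for n in self._rev_post()]))

    def _rev_post(self):
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.nodes_preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> Optional[TreeNode]:
        for n in self.nodes_preorder():
            if n.label == label:
                return n
        return None

    def subtree_labels(self, node: TreeNode) -> List[str]:
        """Labels of every node in the subtree rooted at ``node``
        (including ``node`` itself)."""
        sub = PhyloTree(node)
        return [n.label for n in sub.nodes_preorder()]

    def validate(self) -> None:
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("leaf names must be unique")
        for n in self.nodes_preorder():
            if not np.isfinite(n.length) or n.length < 0:
                raise ValueError(f"branch length {n.length} at {n.label!r} "
                                 "must be finite and >= 0")

    def auto_label(self, prefix: str = "node") -> None:
        """Deterministically label unlabeled nodes (preorder ``node1``,
        ``node2``, ...), so hybrid-chain selectors are reproducible."""
        i = 0
        for n in self.nodes_preorder():
            if not n.label:
                i += 1
                n.label = f"{prefix}{i}"

    def copy(self) -> "PhyloTree":
        return parse_newick(write_newick(self))

    def rerooted(self, label: str) -> "PhyloTree":
        """A copy rooted at the named node (edges above it reversed,
        branch lengths preserved)."""
        t = self.copy()
        node = t.find(label)
        if node is None:
            raise KeyError(f"no node labeled {label!r}")
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent
        for child, par in zip(path, path[1:]):
            par.children.remove(child)
            child.add(par)
            par.length = child.length
        node.parent = None
        node.length = 0.0
        return PhyloTree(node)

    def __str__(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_RESERVED = set("();:,'")


def parse_newick(text: str) -> PhyloTree:
    """Parse standard Newick (branch lengths, internal labels, quoted
    labels); errors carry the character position."""
    s = text.strip()
    pos = 0

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def skip_ws():
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def read_label() -> Optional[str]:
        nonlocal pos
        skip_ws()
        if peek() == "'":
            end = s.find("'", pos + 1)
            if end < 0:
                raise NewickError("unterminated quoted label", pos)
            label = s[pos + 1:end]
            pos = end + 1
            return label
        start = pos
        while pos < len(s) and not s[pos].isspace() and s[pos] not in _RESERVED:
            pos += 1
        return s[start:pos] or None

    def read_length() -> float:
        nonlocal pos
        skip_ws()
        if peek() != ":":
            return 0.0
        pos += 1
        start = pos
        while pos < len(s) and (s[pos].isdigit() or s[pos] in ".+-eE"):
            pos += 1
        try:
            return float(s[start:pos])
        except ValueError:
            raise NewickError("malformed branch length", start) from None

    def read_clade() -> TreeNode:
        nonlocal pos
        skip_ws()
        node = TreeNode()
        if peek() == "(":
            pos += 1
            while True:
                node.add(read_clade())
                skip_ws()
                if peek() == ",":
                    pos += 1
                    continue
                if peek() == ")":
                    pos += 1
                    break
                raise NewickError("expected ',' or ')'", pos)
        node.label = read_label()
        node.length = read_length()
        return node

    root = read_clade()
    skip_ws()
    if peek() == ";":
        pos += 1
    skip_ws()
    if pos != len(s):
        raise NewickError("trailing characters after tree", pos)
    tree = PhyloTree(root)
    tree.validate()
    return tree


def _fmt_label(label: Optional[str]) -> str:
    if not label:
        return ""
    if any(c in _RESERVED or c.isspace() for c in label):
        return f"'{label}'"
    return label


def _fmt_len(x: float) -> str:
    return repr(float(x))


def write_newick(tree: PhyloTree) -> str:
    def render(n: TreeNode, at_root: bool) -> str:
        inner = ""
        if n.children:
            inner = "(" + ",".join(render(c, False) for c in n.children) + ")"
        out = inner + _fmt_label(n.label)
        if not at_root:
            out += ":" + _fmt_len(n.length)
        return out

    return render(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: np.ndarray, names: Sequence[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    The agglomeration is delegated to scikit-bio; negative inferred branch
    lengths are clamped to zero with a warning.  The output is rooted
    arbitrarily at the final join (root placement is irrelevant for
    reversible models).  Two taxa yield a single edge with the distance
    split evenly across the root.
    """
    d = np.asarray(d, dtype=float)
    n = len(names)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if not np.allclose(d, d.T, atol=1e-12) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        root = TreeNode()
        root.add(TreeNode(label=names[0], length=d[0, 1] / 2.0))
        root.add(TreeNode(label=names[1], length=d[0, 1] / 2.0))
        return PhyloTree(root)

    from skbio import DistanceMatrix
    from skbio.tree import nj

    sk = nj(DistanceMatrix(d, ids=list(names)))
    buf = io.StringIO()
    sk.write(buf, format="newick")
    tree = parse_newick_clamped(buf.getvalue())
    return tree


def parse_newick_clamped(text: str) -> PhyloTree:
    """Parse Newick, clamping negative branch lengths to 0 with a warning
    (NJ can infer negative lengths)."""
    import re

    def clamp(m):
        v = float(m.group(1))
        if v < 0:
            warnings.warn(f"clamping negative branch length {v} to 0")
            return ":0.0"
        return m.group(0)

    return parse_newick(re.sub(r":(-[\d.eE+-]+)", clamp, text.strip()))


def jc_distance_matrix(rows: Sequence[str]) -> np.ndarray:
    """Pairwise Jukes-Cantor-corrected distances between aligned rows.

    Sites where either row has a gap or unrecognized character are
    skipped.  Mismatch fractions at or beyond the JC divergence ceiling
    (3/4) are clamped just below it, giving a large but finite distance.
    """
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = diff = 0
            for a, b in zip(rows[i].lower(), rows[j].lower()):
                if a in "acgtu" and b in "acgtu":
                    if a == b:
                        same += 1
                    else:
                        diff += 1
            total = same + diff
            p = diff / total if total else 0.0
            p = min(p, 0.74999)
            d[i, j] = d[j, i] = max(0.0, -0.75 * np.log(1.0 - 4.0 * p / 3.0))
    return d
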