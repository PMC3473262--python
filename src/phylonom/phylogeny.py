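"""Tree inference for protein alignments.

Implements the tree-building stack used to delineate ortholog groups:
neighbor joining on Poisson-corrected distances, Fitch parsimony scoring,
maximum-likelihood inference under an empirical amino-acid model
(Felsenstein pruning, per-branch optimization, NNI topology search),
nonparametric bootstrap supports, Robinson-Foulds comparison, and Newick
input/output.

Conventions
-----------
* Unrooted trees are stored with a trifurcating root node.
* Branch lengths are expected substitutions per site, bounded to
  ``[BRANCH_MIN, BRANCH_MAX]`` during optimization.
* Bootstrap supports are percentages in [0, 100] attached to internal
  edges (stored on the child node of the edge).
* All stochastic operations take explicit seeds; replicate streams are
  derived from ``(seed, replicate_index)`` so partial re-runs reproduce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._aa import AMINO_ACIDS, MISSING_CODE, encode

logger = logging.getLogger(__name__)

BRANCH_MIN = 1e-8
BRANCH_MAX = 50.0
#: Poisson distances are clamped here when p approaches 1 (saturation)
DISTANCE_MAX = 10.0


# ---------------------------------------------------------------------------
# Tree structure and Newick I/O
# ---------------------------------------------------------------------------

class Node:
    """A tree node. Leaves carry a name; internal nodes may carry support."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.support: float | None = None
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length}, n_children={len(self.children)})"


class PhyloTree:
    """Rooted or unrooted phylogenetic tree.

    Unrooted trees use a trifurcating root; ``rooted`` distinguishes a true
    (degree-2) root introduced by outgroup rooting.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf labels in tree")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n is not self.root]

    def internal_edges(self) -> list[Node]:
        return [n for n in self.edges() if not n.is_leaf]

    # -- utilities ---------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for c in node.children:
                new.add(rec(c))
            return new

        return PhyloTree(rec(self.root), rooted=self.rooted)

    def clade_leafsets(self) -> dict[Node, frozenset[str]]:
        sets: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.name])
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= sets[c]
                sets[node] = frozenset(s)
        return sets

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, each normalized to the side excluding the
        lexicographically smallest leaf (rooting-independent)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        n = len(all_leaves)
        splits: set[frozenset[str]] = set()
        sets = self.clade_leafsets()
        for node in self.edges():
            side = sets[node]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        return splits

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two leaves."""
        nodes = {n.name: n for n in self.leaves()}
        pa, pb = nodes[a], nodes[b]
        anc_a: dict[int, float] = {}
        node, d = pa, 0.0
        while node is not None:
            anc_a[id(node)] = d
            d += node.length or 0.0
            node = node.parent
        node, d = pb, 0.0
        while node is not None:
            if id(node) in anc_a:
                return d + anc_a[id(node)]
            d += node.length or 0.0
            node = node.parent
        raise ValueError(f"leaves {a!r} and {b!r} are not connected")

    def unroot(self) -> "PhyloTree":
        """Collapse a degree-2 root into a trifurcation."""
        t = self.copy()
        if len(t.root.children) != 2:
            t.rooted = False
            return t
        a, b = t.root.children
        keep, fold = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            t.rooted = False
            return t
        fold.length = (fold.length or 0.0) + (keep.length or 0.0)
        new_root = Node()
        for c in keep.children:
            new_root.add(c)
        new_root.add(fold)
        return PhyloTree(new_root, rooted=False)

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "PhyloTree":
        """Return a rooted copy with the root inserted on the edge above
        ``child`` (a node of this tree), splitting its length by ``fraction``
        on the child side."""
        # work on a copy; locate the corresponding node via postorder index
        order = list(self.postorder())
        idx = order.index(child)
        t = self.copy()
        child_c = list(t.postorder())[idx]
        if child_c.parent is None:
            raise ValueError("cannot root on the root node")
        length = child_c.length if child_c.length is not None else 0.0
        new_root = Node()
        # invert the parent chain above child; edge lengths and supports
        # travel with their edge (after inversion the edge between p and its
        # former parent q is stored on q, not p)
        below_len = length * fraction
        node = child_c.parent
        node.children.remove(child_c)
        new_root.add(child_c)
        child_c.length = below_len
        prev, prev_len, prev_sup = new_root, length - below_len, child_c.support
        while node is not None:
            parent = node.parent
            up_len, up_sup = node.length, node.support
            if parent is not None:
                parent.children.remove(node)
            node.parent = None
            node.length = prev_len
            node.support = prev_sup
            prev.add(node)
            prev, prev_len, prev_sup = node, up_len, up_sup
            node = parent
        _suppress_unary(new_root)
        return PhyloTree(new_root, rooted=True)


def _suppress_unary(root: Node) -> None:
    """Remove internal nodes with a single child (in place, below root)."""
    stack = list(root.children)
    while stack:
        node = stack.pop()
        while len(node.children) == 1 and not node.is_leaf:
            only = node.children[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            pos = parent.children.index(node)
            parent.children[pos] = only
            only.parent = parent
            node = only
        stack.extend(node.children)


class NewickError(ValueError):
    pass


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string. Numeric internal labels become supports."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("missing terminating ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = parse_label()
            if not label:
                raise error("empty leaf label")
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise error(f"invalid branch length {s[start:pos]!r}")
        return node

    root = parse_node()
    if pos != len(s):
        raise NewickError(f"trailing characters at position {pos}")
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def write_newick(tree: PhyloTree, decimals: int = 6) -> str:
    """Serialize to Newick; supports are written as internal node labels."""

    def fmt_len(node: Node) -> str:
        if node.length is None:
            return ""
        return f":{node.length:.{decimals}f}"

    def rec(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}{fmt_len(node)}"
        inner = ",".join(rec(c) for c in node.children)
        label = ""
        if node.support is not None:
            label = f"{node.support:g}"
        elif node.name:
            label = node.name
        return f"({inner}){label}{fmt_len(node)}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(m).any():
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m


def pairwise_distances(alignment, mode: str = "poisson") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion of gap/X columns.

    ``p`` is the mismatch fraction over columns where both rows hold a
    canonical residue; ``poisson`` applies d = -ln(1 - p), clamped at
    ``DISTANCE_MAX`` with a saturation flag.
    """
    if mode not in ("poisson", "p"):
        raise ValueError(f"unknown distance mode {mode!r}")
    ids = list(alignment.ids)
    if len(ids) < 2:
        raise ValueError("need at least two rows")
    codes = np.stack([encode(row) for row in alignment.rows])
    n = len(ids)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    ok = codes < MISSING_CODE
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((codes[i, comp] != codes[j, comp]).sum()) / n_comp
            if mode == "p":
                dij = p
            else:
                if p >= 1.0 - math.exp(-DISTANCE_MAX):
                    dij = DISTANCE_MAX
                    saturated.append((ids[i], ids[j]))
                else:
                    dij = -math.log1p(-p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids, d, saturated)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration (Saitou-Nei with Studier-Keppler Q).

    Deterministic: on equal Q the lexicographically smallest pair of cluster
    labels is merged (a cluster is labeled by its smallest leaf name).
    Negative intermediate branch lengths are clamped to zero with a log note.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(dm.ids)
    nodes: list[Node] = [Node(name) for name in dm.ids]
    d = dm.matrix.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("NJ: negative branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        vj = clamp(d[i, j] / 2 + (r[j] - r[i]) / (2 * (m - 2)))
        new = Node()
        nodes[i].length = vi
        nodes[j].length = vj
        new.add(nodes[i])
        new.add(nodes[j])
        # distances from the new cluster
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = max(0.0, (d[i, k] + d[j, k] - d[i, j]) / 2)
        nodes[i] = new
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = sorted(active, key=lambda a: labels[a])
    root = Node()
    nodes[i].length = clamp((d[i, j] + d[i, k] - d[j, k]) / 2)
    nodes[j].length = clamp((d[i, j] + d[j, k] - d[i, k]) / 2)
    nodes[k].length = clamp((d[i, k] + d[j, k] - d[i, j]) / 2)
    for a in (i, j, k):
        root.add(nodes[a])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def fitch_parsimony_score(tree: PhyloTree, alignment) -> int:
    """Minimal number of state changes, summed over columns (Fitch).

    Gaps and X are missing data: they impose no constraint and no cost.
    Multifurcations (the trifurcating root) are folded pairwise, which is
    exact for unrooted binary trees.
    """
    _check_leaves(tree, alignment)
    codes = {rid: encode(row) for rid, row in zip(alignment.ids, alignment.rows)}
    ncol = len(alignment.rows[0])
    full = frozenset(range(20))
    total = 0
    order = list(tree.postorder())
    for col in range(ncol):
        sets: dict[int, frozenset[int]] = {}
        for node in order:
            if node.is_leaf:
                c = codes[node.name][col]
                sets[id(node)] = full if c >= MISSING_CODE else frozenset([int(c)])
            else:
                cur = None
                for child in node.children:
                    s = sets[id(child)]
                    if cur is None:
                        cur = s
                        continue
                    inter = cur & s
                    if inter:
                        cur = inter
                    else:
                        cur = cur | s
                        total += 1
                sets[id(node)] = cur
    return total


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

# WAG (Whelan & Goldman 2001) exchangeabilities, lower triangle column-major
# in ARNDCQEGHILKMFPSTWYV order, with the published equilibrium frequencies.
_WAG_RATES = [
    0.551571, 0.509848, 0.738998, 1.027040, 0.908598, 1.582850,
    1.416720, 0.316954, 0.193335, 0.397915, 0.906265, 0.893496,
    0.210494, 1.438550, 3.370790, 2.121110, 0.113133, 0.240735,
    2.006010, 0.635346, 0.147304, 0.528191, 3.035500, 0.439157,
    0.584665, 2.137150, 0.186979, 0.497671, 5.351420, 0.683162,
    0.102711, 0.679489, 1.224190, 0.554413, 1.163920, 0.381533,
    0.170887, 5.429420, 0.265256, 1.543640, 0.947198, 1.125560,
    3.956290, 0.554236, 0.131528, 0.198221, 0.036904, 0.096162,
    0.498138, 0.131366, 1.001400, 0.361819, 0.165001, 0.719167,
    0.512984, 0.543833, 0.302936, 0.265256, 0.234087, 0.727255,
    1.685770, 0.523742, 0.094464, 0.055288, 0.089586, 0.035855,
    0.579665, 0.594945, 0.457121, 0.331344, 0.161444, 0.111773,
    0.429437, 0.195081, 3.887920, 0.845100, 4.050460, 0.199094,
    0.489798, 0.411954, 1.439980, 0.109404, 1.377340, 0.399036,
    1.694310, 0.656604, 0.418296, 1.059470, 0.161074, 0.371004,
    4.254600, 1.122460, 0.812339, 0.257555, 0.934276, 0.248862,
    4.134020, 0.140766, 0.245034, 0.301281, 2.261490, 0.389490,
    0.654324, 1.338430, 0.740169, 0.319440, 0.344739, 0.967130,
    0.493905, 0.545931, 1.613280, 2.842680, 0.349680, 0.723509,
    0.182885, 1.757900, 0.063452, 0.666091, 0.398565, 0.109373,
    0.442472, 1.799290, 0.256491, 0.983693, 0.828219, 4.864400,
    0.347660, 0.303507, 1.900740, 5.649530, 0.890432, 0.406194,
    0.443320, 0.168921, 0.508851, 2.434500, 0.990012, 0.584262,
    0.119013, 0.597054, 0.159069, 4.294110, 4.128390, 0.213179,
    0.252457, 0.157721, 0.934264, 1.192410, 1.125830, 1.190770,
    0.210332, 0.348847, 0.423579, 0.044265, 0.069673, 0.739810,
    0.823960, 0.313311, 0.124700, 0.262569, 1.061300, 0.615636,
    0.291148, 1.241990, 0.130053, 0.936989, 0.556896, 0.084805,
    0.287583, 0.025548, 0.123598, 0.171329, 0.346983, 0.171300,
    0.119715, 0.120037, 0.417839, 0.262560, 1.473040, 0.234217,
    0.186510, 0.604445, 0.077852, 0.079081, 0.268491, 0.054679,
    0.108882, 0.366317, 0.697264, 0.442910, 0.682139, 0.508518,
    2.145580,
]

_WAG_FREQS = [
    0.086628, 0.043972, 0.039089, 0.057045, 0.019308,
    0.036728, 0.058059, 0.083252, 0.024431, 0.048466,
    0.086209, 0.062029, 0.019503, 0.038432, 0.045763,
    0.069518, 0.061013, 0.014386, 0.035274, 0.070896,
]


class RateModel:
    """Reversible amino-acid rate matrix Q, normalized to 1 expected
    substitution per unit branch length.

    Transition matrices are computed from the eigendecomposition of the
    pi-symmetrized Q; scaling-and-squaring (``scipy.linalg.expm``) is the
    fallback if the decomposition fails to reproduce Q.
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray,
                 name: str = "custom"):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 table")
        if pi.shape != (20,) or abs(pi.sum() - 1.0) > 1e-12 or (pi <= 0).any():
            raise ValueError("frequencies must be a positive simplex over 20 residues")
        self.name = name
        self.frequencies = pi
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -float(np.dot(pi, np.diag(q)))
        q /= scale
        self.Q = q
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        sym = (sym + sym.T) / 2
        evals, evecs = np.linalg.eigh(sym)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]
        self._right = evecs.T * sqrt_pi[None, :]
        self._use_eig = np.allclose(
            self._left @ np.diag(evals) @ self._right, q, atol=1e-10
        )
        if not self._use_eig:  # pragma: no cover - conditioning fallback
            logger.warning("eigendecomposition ill-conditioned; using expm fallback")
        self._cache: dict[float, np.ndarray] = {}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1. Cached per branch length (the
        optimizer re-evaluates the same lengths many times per sweep)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        cached = self._cache.get(t)
        if cached is not None:
            return cached
        if self._use_eig:
            p = (self._left * np.exp(self._evals * t)) @ self._right
        else:  # pragma: no cover
            from scipy.linalg import expm

            p = expm(self.Q * t)
        np.maximum(p, 0.0, out=p)
        if len(self._cache) > 50000:
            self._cache.clear()
        self._cache[t] = p
        return p

    @classmethod
    def wag(cls) -> "RateModel":
        s = np.zeros((20, 20))
        k = 0
        for j in range(20):          # lower triangle, column-major
            for i in range(j + 1, 20):
                s[i, j] = s[j, i] = _WAG_RATES[k]
                k += 1
        return cls(s, np.array(_WAG_FREQS) / sum(_WAG_FREQS), name="WAG")

    @classmethod
    def poisson(cls) -> "RateModel":
        """Equal-rates model with uniform frequencies (20-state analogue of
        Jukes-Cantor); handy for closed-form checks."""
        s = np.ones((20, 20))
        np.fill_diagonal(s, 0.0)
        return cls(s, np.full(20, 1 / 20), name="poisson")


# ---------------------------------------------------------------------------
# Likelihood (Felsenstein pruning)
# ---------------------------------------------------------------------------

def _check_leaves(tree: PhyloTree, alignment) -> None:
    if set(tree.leaf_names()) != set(alignment.ids):
        raise ValueError("tree leaves and alignment rows do not match")


def _site_patterns(alignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Compress alignment columns into unique patterns with weights."""
    codes = np.stack([encode(row) for row in alignment.rows])
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return list(alignment.ids), patterns, weights.astype(float)


def _tip_partial(codes_col: np.ndarray) -> np.ndarray:
    """20 x P one-hot partials; missing columns are all-ones."""
    p = codes_col.shape[0]
    out = np.zeros((20, p))
    miss = codes_col >= MISSING_CODE
    out[:, miss] = 1.0
    idx = np.nonzero(~miss)[0]
    out[codes_col[idx], idx] = 1.0
    return out


class _Pruner:
    """Shared pruning state for one alignment/model pair.

    Holds pattern-compressed tip partials keyed by row id, so repeated
    likelihood evaluations across trees (branch sweeps, NNI candidates)
    reuse them.
    """

    def __init__(self, alignment, model: RateModel):
        ids, patterns, weights = _site_patterns(alignment)
        self.model = model
        self.weights = weights
        self.tips = {rid: _tip_partial(patterns[i]) for i, rid in enumerate(ids)}
        self.ids = set(ids)

    def _down(self, tree: PhyloTree) -> dict[int, np.ndarray]:
        down: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                down[id(node)] = self.tips[node.name]
            else:
                acc = None
                for c in node.children:
                    m = self.model.transition_matrix(c.length) @ down[id(c)]
                    acc = m if acc is None else acc * m
                down[id(node)] = acc
        return down

    def loglik(self, tree: PhyloTree) -> float:
        down = self._down(tree)
        site = self.model.frequencies @ down[id(tree.root)]
        if (site <= 0).any():
            return -np.inf
        return float(self.weights @ np.log(site))

    def messages(self, tree: PhyloTree):
        """Down partials plus, for every non-root node v, the conditional
        likelihood of all data outside v's subtree as a function of the
        state at v's parent (the root prior is applied by the caller)."""
        down = self._down(tree)
        out: dict[int, np.ndarray] = {}
        P = self.model.transition_matrix
        for node in tree.preorder():
            if node.is_leaf and node is not tree.root:
                continue
            transported = {
                id(c): P(c.length) @ down[id(c)] for c in node.children
            }
            if node is tree.root:
                base = None
            else:
                base = P(node.length) @ out[id(node)]
            for c in node.children:
                acc = base.copy() if base is not None else None
                for s in node.children:
                    if s is c:
                        continue
                    m = transported[id(s)]
                    acc = m.copy() if acc is None else acc * m
                out[id(c)] = acc
        return down, out

    def edge_loglik(self, node: Node, t: float,
                    down: dict[int, np.ndarray], out: dict[int, np.ndarray]) -> float:
        """Log-likelihood with the length of the edge above ``node`` set to
        ``t``, all other branch lengths fixed (messages precomputed)."""
        inner = self.model.transition_matrix(t) @ down[id(node)]
        site = self.model.frequencies @ (out[id(node)] * inner)
        if (site <= 0).any():
            return -np.inf
        return float(self.weights @ np.log(site))

    # -- incremental down-partial cache (one tree at a time) ---------------
    def down_init(self, tree: PhyloTree) -> None:
        self._down_cache = self._down(tree)

    def down_refresh(self, node: Node) -> None:
        """Recompute cached down partials on the ancestor path of ``node``
        (call after changing the length of the edge above it)."""
        P = self.model.transition_matrix
        n = node.parent
        while n is not None:
            acc = None
            for c in n.children:
                m = P(c.length) @ self._down_cache[id(c)]
                acc = m if acc is None else acc * m
            self._down_cache[id(n)] = acc
            n = n.parent

    def edge_context(self, tree: PhyloTree, node: Node,
                     cached: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(prior-weighted outside message, down partial) for one edge.

        Computes the outside message only along the root-to-node path, which
        is all a single-branch optimization needs. With ``cached`` the down
        partials maintained by ``down_init``/``down_refresh`` are reused.
        """
        down = self._down_cache if cached else self._down(tree)
        P = self.model.transition_matrix
        path: list[Node] = []
        n = node
        while n.parent is not None:
            path.append(n)
            n = n.parent
        path.reverse()
        cur: np.ndarray | None = None     # out message for the previous node
        prev: Node | None = None
        for v in path:
            parent = v.parent
            acc = None if cur is None else P(prev.length) @ cur
            for s in parent.children:
                if s is v:
                    continue
                m = P(s.length) @ down[id(s)]
                acc = m if acc is None else acc * m
            cur = acc
            prev = v
        w = self.model.frequencies[:, None] * cur
        return w, down[id(node)]

    def edge_loglik_fast(self, w: np.ndarray, d: np.ndarray, t: float) -> float:
        site = (w * (self.model.transition_matrix(t) @ d)).sum(axis=0)
        if (site <= 0).any():
            return -np.inf
        return float(self.weights @ np.log(site))


def log_likelihood(tree: PhyloTree, alignment, model: RateModel,
                   gamma_shape: float | None = None,
                   gamma_categories: int = 4) -> float:
    """Felsenstein pruning log-likelihood.

    Sites are independent; gap/X leaf states are marginalized (all-ones
    partials). Raises on negative branch lengths.

    ``gamma_shape`` enables discrete-gamma rate heterogeneity: per-site
    likelihoods are averaged over ``gamma_categories`` equal-probability
    rate classes (category rates = means of the gamma quantile slices,
    normalized to mean 1). The default is a single rate class.
    """
    _check_leaves(tree, alignment)
    for node in tree.edges():
        if node.length is None or node.length < 0 or not np.isfinite(node.length):
            raise ValueError(f"invalid branch length on edge above {node.name or 'internal'}")
    pruner = _Pruner(alignment, model)
    if gamma_shape is None:
        return pruner.loglik(tree)
    rates = discrete_gamma_rates(gamma_shape, gamma_categories)
    site_liks = None
    for rate in rates:
        scaled = tree.copy()
        for node in scaled.edges():
            node.length = node.length * rate
        down = pruner._down(scaled)
        site = model.frequencies @ down[id(scaled.root)]
        site_liks = site if site_liks is None else site_liks + site
    site_liks = site_liks / len(rates)
    if (site_liks <= 0).any():
        return -np.inf
    return float(pruner.weights @ np.log(site_liks))


def discrete_gamma_rates(shape: float, categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability gamma slices (mean-1 gamma)."""
    if shape <= 0 or categories < 1:
        raise ValueError("shape must be > 0 and categories >= 1")
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.linspace(0, 1, categories + 1),
                           a=shape, scale=1.0 / shape)
    # mean of each slice via the incomplete-gamma identity
    upper = gamma_dist.cdf(edges[1:], a=shape + 1, scale=1.0 / shape)
    lower = gamma_dist.cdf(edges[:-1], a=shape + 1, scale=1.0 / shape)
    rates = (upper - lower) * categories
    return rates / rates.mean()


def _optimize_edges(tree: PhyloTree, pruner: _Pruner,
                    edges: Sequence[Node] | None = None,
                    max_sweeps: int = 20, tol: float = 1e-6) -> float:
    """In-place per-branch optimization; returns the final log-likelihood."""
    current = pruner.loglik(tree)
    if not np.isfinite(current):
        raise ValueError("non-finite likelihood at starting branch lengths")
    all_edges = edges is None
    pruner.down_init(tree)
    for _ in range(max_sweeps):
        target_edges = tree.edges() if all_edges else edges
        for node in target_edges:
            w, d = pruner.edge_context(tree, node, cached=True)

            def neg(t: float, w=w, d=d) -> float:
                return -pruner.edge_loglik_fast(w, d, t)

            res = minimize_scalar(neg, bounds=(BRANCH_MIN, BRANCH_MAX),
                                  method="bounded",
                                  options={"xatol": 1e-6, "maxiter": 24})
            if -res.fun > pruner.edge_loglik_fast(w, d, node.length):
                node.length = float(res.x)
                pruner.down_refresh(node)
        new = pruner.loglik(tree)
        if new - current < tol:
            current = max(new, current)
            break
        current = new
    return current


def optimize_branch_lengths(tree: PhyloTree, alignment, model: RateModel,
                            max_sweeps: int = 20, tol: float = 1e-6) -> PhyloTree:
    """Iterative bounded univariate optimization of every branch length.

    Sweeps until the log-likelihood improves by less than ``tol`` or
    ``max_sweeps`` is reached; the returned tree's likelihood is never below
    the input's.
    """
    _check_leaves(tree, alignment)
    out = tree.copy()
    for node in out.edges():
        node.length = min(max(node.length or BRANCH_MIN, BRANCH_MIN), BRANCH_MAX)
    pruner = _Pruner(alignment, model)
    _optimize_edges(out, pruner, None, max_sweeps=max_sweeps, tol=tol)
    return out


# ---------------------------------------------------------------------------
# NNI topology search
# ---------------------------------------------------------------------------

def _nni_candidates(tree: PhyloTree) -> list[tuple[PhyloTree, list[Node]]]:
    """Both NNI rearrangements for every internal edge, as tree copies,
    each with the list of edges adjacent to the rearranged edge."""
    out: list[tuple[PhyloTree, list[Node]]] = []
    order = list(tree.postorder())
    for idx, node in enumerate(order):
        if node is tree.root or node.is_leaf:
            continue
        for ci in range(2):
            t = tree.copy()
            order_c = list(t.postorder())
            v = order_c[idx]
            u = v.parent
            partner = [c for c in u.children if c is not v][0]
            child = v.children[ci]
            # exchange child and partner between v and u
            v.children[ci] = partner
            partner.parent = v
            u.children[u.children.index(partner)] = child
            child.parent = u
            local = [v, child, partner] + list(v.children)
            if u is not t.root:
                local.append(u)
            out.append((t, local))
    return out


def nni_search(tree: PhyloTree, alignment, model: RateModel,
               max_rounds: int = 20, tol: float = 1e-6) -> PhyloTree:
    """Greedy nearest-neighbor-interchange search.

    Each round evaluates both rearrangements of every internal edge with
    re-optimized branch lengths around the edge, accepts the best strict
    improvement, and stops when none exists. The final likelihood is never
    below the initial one.
    """
    _check_leaves(tree, alignment)
    if len(tree.leaf_names()) < 4:
        return tree.copy()
    pruner = _Pruner(alignment, model)
    current = tree.copy()
    current_ll = _optimize_edges(current, pruner)
    for _ in range(max_rounds):
        best: PhyloTree | None = None
        best_ll = current_ll
        for cand, local_edges in _nni_candidates(current):
            # re-optimize the branch lengths around the rearranged edge
            _optimize_edges(cand, pruner, edges=local_edges, max_sweeps=1)
            ll = pruner.loglik(cand)
            if ll > best_ll + tol:
                best, best_ll = cand, ll
        if best is None:
            break
        current = best
        current_ll = _optimize_edges(current, pruner)
    return current


def infer_ml_tree(alignment, model: RateModel, seed: int = 0) -> PhyloTree:
    """NJ starting tree -> branch-length optimization -> NNI search.

    Deterministic given the inputs (the seed is part of the interface for
    callers that derive replicate streams from it).
    """
    ids = list(alignment.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 rows to infer a tree")
    dm = pairwise_distances(alignment, "poisson")
    start = neighbor_joining(dm)
    if len(ids) == 3:
        return optimize_branch_lengths(start, alignment, model)
    return nni_search(start, alignment, model)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapConfig:
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


class _ResampledAlignment:
    """Column-resampled view satisfying the alignment protocol."""

    def __init__(self, ids: list[str], rows: list[str]):
        self.ids = ids
        self.rows = rows


def bootstrap_supports(alignment, model: RateModel, cfg: BootstrapConfig,
                       point_tree: PhyloTree | None = None) -> PhyloTree:
    """Nonparametric bootstrap supports on the point-estimate ML tree.

    Columns are resampled with replacement per replicate, an ML tree is
    inferred per replicate, and each internal edge of the point tree gets
    support = percent of replicate trees containing the same bipartition.
    """
    if point_tree is None:
        point_tree = infer_ml_tree(alignment, model, cfg.seed)
    chars = np.stack([np.frombuffer(r.encode(), dtype=np.uint8)
                      for r in alignment.rows])
    ncol = chars.shape[1]
    ids = list(alignment.ids)
    counts: dict[frozenset[str], int] = {}
    for r in range(cfg.replicates):
        rng = np.random.default_rng((int(cfg.seed) & 0x7FFFFFFF, r))
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(map(chr, chars[i, cols])) for i in range(len(ids))]
        rep = _ResampledAlignment(ids, rows)
        rep_tree = infer_ml_tree(rep, model, cfg.seed)
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    out = point_tree.copy()
    all_leaves = frozenset(out.leaf_names())
    ref = min(all_leaves)
    sets = out.clade_leafsets()
    n = len(all_leaves)
    for node in out.internal_edges():
        side = sets[node]
        if ref in side:
            side = all_leaves - side
        if not (2 <= len(side) <= n - 2):
            continue
        node.support = 100.0 * counts.get(side, 0) / cfg.replicates
    return out


# ---------------------------------------------------------------------------
# Tree comparison
# ---------------------------------------------------------------------------

def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())
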