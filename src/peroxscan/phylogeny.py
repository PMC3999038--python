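"""Poisson-corrected distances, neighbor-joining, bootstrap support, Newick I/O.

Distances are amino-acid p-distances with pairwise deletion of gapped
columns, corrected for multiple hits with the Poisson model
``d = -ln(1 - p)`` (uniform site rates), in units of substitutions per
site.  Trees are built with the Saitou–Nei neighbor-joining criterion;
clade support is the percentage of column-resampled bootstrap replicate
trees containing each bipartition of the original tree.

Saturated pairs (p >= 0.99, where the correction diverges) are flagged
UNDEFINED and rejected by tree building with an explicit error rather
than silently capped.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UNDEFINED",
    "is_undefined",
    "SaturationError",
    "UndefinedDistanceError",
    "NewickParseError",
    "MSA",
    "DistanceMatrix",
    "Node",
    "Tree",
    "p_distance",
    "poisson_correct",
    "distance_matrix",
    "nj_tree",
    "nj_join_order",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

GAP = "-"
#: sentinel for saturated / incomparable distances
UNDEFINED = float("nan")

#: p-distance at or above which the Poisson correction is considered saturated
SATURATION_P = 0.99


def is_undefined(x: float) -> bool:
    return math.isnan(x)


class SaturationError(ValueError):
    """Poisson correction is undefined at p >= 1."""


class UndefinedDistanceError(ValueError):
    """A distance matrix handed to NJ contains UNDEFINED entries."""


class NewickParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass(frozen=True)
class MSA:
    """A protein multiple alignment: row ids plus equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least two rows")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("rows differ in length")
        if L == 0 or all(all(r[c] == GAP for r in self.rows) for c in range(L)):
            raise ValueError("MSA has no non-gap column")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "MSA":
        """Bootstrap replicate: columns drawn with replacement."""
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return MSA(self.ids, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal; NaN marks UNDEFINED."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
            raise ValueError("matrix not symmetric")
        if np.any(np.diagonal(m) != 0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(m[~np.isnan(m)] < 0):
                raise ValueError("negative distance")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.ids)

    def has_undefined(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool(np.isnan(self.matrix[off]).any())


def p_distance(msa: MSA, i: int, j: int) -> float:
    """Observed proportion of differing residues with pairwise gap deletion.

    Columns where either row carries a gap are excluded for this pair
    only; returns UNDEFINED (NaN) when no comparable column remains.
    """
    a, b = msa.rows[i], msa.rows[j]  # IndexError on bad indices, as documented
    compared = differing = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            differing += 1
    if compared == 0:
        return UNDEFINED
    return differing / compared


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p), substitutions per site."""
    if not 0 <= p < 1:
        raise SaturationError(f"p-distance {p} outside [0, 1)")
    return -math.log1p(-p)


def distance_matrix(msa: MSA) -> DistanceMatrix:
    """Poisson-corrected pairwise distances; saturated pairs flagged UNDEFINED.

    Vectorized equivalent of applying :func:`p_distance` and
    :func:`poisson_correct` to every pair.
    """
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != GAP
    n = msa.n_rows
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            compared = int(both.sum())
            if compared == 0:
                m[i, j] = m[j, i] = UNDEFINED
                continue
            p = float((arr[i, both] != arr[j, both]).sum()) / compared
            m[i, j] = m[j, i] = UNDEFINED if p >= SATURATION_P else poisson_correct(p)
    return DistanceMatrix(tuple(msa.ids), m)


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class Node:
    """A tree node; leaves carry a name, internal nodes may carry a support value."""

    name: str | None = None
    branch_length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    """An unrooted tree stored with an arbitrary internal node as root."""

    root: Node

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.walk() if n.is_leaf]

    def total_length(self) -> float:
        return sum(n.branch_length for n in self.root.walk() if n is not self.root)

    def bipartitions(self) -> dict[frozenset[str], Node]:
        """Canonical internal bipartitions -> the child node defining each.

        A bipartition is keyed by the leaf-name side not containing the
        lexicographically smallest leaf, so keys are rooting-invariant.
        Trivial splits (single leaf / full set) are omitted.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset[str], Node] = {}

        def side(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            return frozenset().union(*(side(c) for c in node.children))

        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            s = side(node)
            key = all_leaves - s if anchor in s else s
            if 1 < len(s) < len(all_leaves) - 1:
                out[key] = node
        return out


# ---------------------------------------------------------------------------
# Neighbor joining


def _nj_agglomerate(
    m: np.ndarray,
) -> tuple[list[tuple[int, int, float, float]], list[int], np.ndarray]:
    """Run Saitou–Nei agglomeration on a working copy of ``m``.

    Returns the joins as (id_i, id_j, branch_i, branch_j) over cluster
    ids (leaves are 0..n-1; each join creates the next id), the ids of
    the final <=3 remaining clusters, and their distance sub-matrix.
    Ties on the Q criterion break to the lowest (i, j) pair in cluster-id
    order (numpy's row-major argmin).
    """
    D = np.asarray(m, dtype=float).copy()
    n = D.shape[0]
    ids = list(range(n))
    next_id = n
    joins: list[tuple[int, int, float, float]] = []
    while len(ids) > 3:
        mm = len(ids)
        r = D.sum(axis=1)
        Q = (mm - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (mm - 2))
        bj = dij - bi
        joins.append((ids[i], ids[j], max(bi, 0.0), max(bj, 0.0)))
        du = 0.5 * (D[i] + D[j] - dij)  # distances of the merged cluster
        keep = [k for k in range(mm) if k not in (i, j)]
        D2 = np.empty((mm - 1, mm - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D2[-1, -1] = 0.0
        D = D2
        ids = [ids[k] for k in keep] + [next_id]
        next_id += 1
    return joins, ids, D


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree (Saitou–Nei Q criterion).

    Negative branch-length estimates are clamped to zero; for additive
    input the generating topology and path lengths are recovered exactly.
    """
    if dm.n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if dm.has_undefined():
        raise UndefinedDistanceError(
            "distance matrix contains UNDEFINED (saturated or incomparable) entries"
        )
    joins, final_ids, final_D = _nj_agglomerate(dm.matrix)

    nodes: dict[int, Node] = {i: Node(name=nm) for i, nm in enumerate(dm.ids)}
    next_id = dm.n
    for a, b, ba, bb in joins:
        na, nb = nodes.pop(a), nodes.pop(b)
        na.branch_length, nb.branch_length = ba, bb
        nodes[next_id] = Node(children=[na, nb])
        next_id += 1

    if len(final_ids) == 3:
        d01, d02, d12 = final_D[0, 1], final_D[0, 2], final_D[1, 2]
        lengths = (
            max(0.5 * (d01 + d02 - d12), 0.0),
            max(0.5 * (d01 + d12 - d02), 0.0),
            max(0.5 * (d02 + d12 - d01), 0.0),
        )
        for cid, bl in zip(final_ids, lengths):
            nodes[cid].branch_length = bl
        root = Node(children=[nodes[c] for c in final_ids])
    else:  # n == 3 never reaches here; defensive two-cluster case
        a, b = final_ids
        nodes[a].branch_length = final_D[0, 1]
        root = Node(children=[nodes[a], nodes[b]])
    return Tree(root)


def nj_join_order(m: np.ndarray) -> list[tuple[int, int]]:
    """Cluster-merge order for guide-tree use.

    Leaves are clusters 0..n-1; each returned pair (a, b) merges into a
    new cluster with the next free id.  The trailing star of three is
    resolved by joining its two lowest ids first, giving n-1 binary
    merges in total.
    """
    n = m.shape[0]
    if n == 2:
        return [(0, 1)]
    joins, final_ids, _ = _nj_agglomerate(np.asarray(m, dtype=float))
    order = [(a, b) for a, b, _, _ in joins]
    next_id = n + len(joins)
    rem = sorted(final_ids)
    while len(rem) > 1:
        order.append((rem[0], rem[1]))
        rem = rem[2:] + [next_id]
        next_id += 1
    return order


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(msa: MSA, replicates: int = 1000, seed: int = 0) -> Tree:
    """NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement per replicate and a replicate
    NJ tree is built; an edge's support is the percentage of usable
    replicates whose tree contains the same bipartition.  Replicates
    whose resampled distances saturate are discarded from the
    denominator.  Deterministic under ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be positive")
    base = distance_matrix(msa)
    tree = nj_tree(base)
    target = tree.bipartitions()
    counts = {k: 0 for k in target}
    rng = np.random.default_rng(seed)
    usable = 0
    for _ in range(replicates):
        rep = msa.resample_columns(rng)
        dm = distance_matrix(rep)
        if dm.has_undefined():
            continue
        usable += 1
        rep_bip = nj_tree(dm).bipartitions()
        for k in counts:
            if k in rep_bip:
                counts[k] += 1
    if usable == 0:
        raise ValueError("no usable bootstrap replicate (degenerate MSA)")
    for k, node in target.items():
        node.support = round(100 * counts[k] / usable)
    return tree


# ---------------------------------------------------------------------------
# Newick serialization


def write_newick(tree: Tree, min_support: int | None = None) -> str:
    """Serialize to Newick; supports become internal node labels.

    ``min_support`` is the display filter: supports below it are
    omitted from the output (the tree itself is untouched).
    """

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.branch_length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        label = ""
        if node.support is not None and (min_support is None or node.support >= min_support):
            label = str(node.support)
        return f"({inner}){label}:{node.branch_length:.6f}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    label = str(tree.root.support) if tree.root.support is not None else ""
    return f"({inner}){label};"


_TOKEN = re.compile(r"[^,():;]+")


def read_newick(text: str) -> Tree:
    """Parse a Newick string (supports as internal integer labels)."""
    text = text.strip()
    pos = 0

    def error(msg: str):
        raise NewickParseError(msg, pos)

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(text) and text[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(text) or text[pos] != ")":
                error("expected ')'")
            pos += 1
        m = _TOKEN.match(text, pos)
        if m:
            label = m.group(0)
            pos = m.end()
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = int(label)
                except ValueError:
                    error(f"non-integer support label {label!r}")
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", text[pos:])
            if not m:
                error("expected branch length after ':'")
            node.branch_length = float(m.group(0))
            pos += m.end()
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        error("expected ';'")
    return Tree(root)
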