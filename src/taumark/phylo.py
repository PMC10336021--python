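"""Trees: Newick round-tripping, patristic distances, neighbor joining.

The Newick dialect is deliberately plain — unquoted labels restricted
to ``[A-Za-z0-9_.-]``, optional ``:length`` on any node, internal node
names tolerated and ignored, no comments or NHX annotations. Written
output is canonical: children are ordered by their smallest descendant
leaf label and branch lengths carry 6 decimals, so equal trees always
serialize identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import DistanceMatrix

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "write_newick",
    "patristic_matrix",
    "neighbor_joining",
]


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


class Tree:
    """A rooted (possibly trifurcating) leaf-labeled phylogeny."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.name for n in self.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise ValueError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf label(s): {', '.join(dup)}")

    def leaves(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    @property
    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves()]  # type: ignore[misc]

    def relabel(self, mapping: dict[str, str]) -> "Tree":
        """Return a copy with leaf labels replaced via *mapping*."""

        def copy(node: Node) -> Node:
            new = Node(name=node.name, length=node.length)
            if node.is_leaf:
                new.name = mapping.get(node.name, node.name)
            for c in node.children:
                new.add(copy(c))
            return new

        return Tree(copy(self.root))


# -- Newick parsing -----------------------------------------------------

_LABEL_CHARS = set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.-"
)
_NUMBER_CHARS = set("0123456789+-.eE")


class NewickError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (must end in ``;``) into a :class:`Tree`."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("newick string must end in ';'", len(s))
    pos = 0

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] in _LABEL_CHARS:
            pos += 1
        return s[start:pos]

    def read_length() -> float | None:
        nonlocal pos
        if peek() != ":":
            return None
        pos += 1
        start = pos
        while pos < len(s) and s[pos] in _NUMBER_CHARS:
            pos += 1
        tok = s[start:pos]
        try:
            return float(tok)
        except ValueError:
            raise NewickError(f"invalid branch length {tok!r}", start) from None

    def read_clade() -> Node:
        nonlocal pos
        node = Node()
        if peek() == "(":
            pos += 1
            node.add(read_clade())
            while peek() == ",":
                pos += 1
                node.add(read_clade())
            if peek() != ")":
                raise NewickError("unbalanced parentheses: expected ')'", pos)
            pos += 1
            # optional internal node name: tolerated, ignored
            read_label()
        else:
            name = read_label()
            if not name:
                raise NewickError("expected a leaf label", pos)
            node.name = name
        node.length = read_length()
        return node

    root = read_clade()
    if peek() != ";":
        raise NewickError(f"trailing garbage {s[pos:pos + 10]!r}", pos)
    pos += 1
    if pos != len(s):
        raise NewickError("text after terminating ';'", pos)
    return Tree(root)


def _min_leaf(node: Node) -> str:
    if node.is_leaf:
        return node.name  # type: ignore[return-value]
    return min(_min_leaf(c) for c in node.children)


def write_newick(tree: Tree) -> str:
    """Canonical Newick: children ordered by smallest descendant label."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            kids = sorted(node.children, key=_min_leaf)
            body = "(" + ",".join(fmt(c) for c in kids) + ")"
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    return fmt(tree.root) + ";"


# -- patristic distances ------------------------------------------------


def patristic_matrix(tree: Tree) -> DistanceMatrix:
    """Matrix of path-length distances between every leaf pair.

    Every non-root edge must carry a branch length.
    """
    leaves = sorted(tree.leaves(), key=lambda n: n.name)  # type: ignore[arg-type]
    if len(leaves) < 2:
        raise ValueError("patristic distances require at least 2 leaves")
    # distance from each leaf to each of its ancestors
    anc: list[dict[int, float]] = []
    for leaf in leaves:
        d: dict[int, float] = {}
        node, total = leaf, 0.0
        while node is not None:
            d[id(node)] = total
            if node.parent is not None:
                if node.length is None:
                    raise ValueError(
                        "patristic distances require branch lengths on every edge"
                    )
                total += node.length
            node = node.parent
        anc.append(d)
    n = len(leaves)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # LCA = nearest ancestor of i that is also an ancestor of j
            node = leaves[i]
            while id(node) not in anc[j]:
                node = node.parent  # type: ignore[assignment]
            dij = anc[i][id(node)] + anc[j][id(node)]
            values[i, j] = values[j, i] = dij
    labels = [n_.name for n_ in leaves]
    return DistanceMatrix(labels=labels, values=values, meta="patristic")  # type: ignore[arg-type]


# -- neighbor joining ---------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining on a fully observed distance matrix.

    Joins the pair minimizing ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``;
    ties are broken by the lexicographically smallest pair of node keys
    (a node's key is its smallest descendant leaf label). Negative
    branch lengths are clamped to zero. The returned tree is unrooted,
    represented with a trifurcating root.
    """
    off = ~np.eye(dm.n, dtype=bool)
    if np.any(dm.mask & off):
        raise ValueError(
            "neighbor joining requires a fully observed matrix; "
            "masked entries present — consider a stricter core_fraction"
        )
    if dm.n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    order = sorted(dm.labels)
    dm = dm.reorder(order)
    nodes: list[Node] = [Node(name=lab) for lab in order]
    keys: list[str] = list(order)
    d = dm.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12))):
            if i >= j:
                continue
            key = tuple(sorted((keys[i], keys[j])))
            if best is None or key < best:
                best, bi, bj = key, int(i), int(j)
        li = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = d[bi, bj] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node()
        a, b = nodes[bi], nodes[bj]
        a.length, b.length = li, lj
        new.add(a)
        new.add(b)
        dnew = 0.5 * (d[bi] + d[bj] - d[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[bi], keys[bj])]
        d = d2

    # final three nodes join at a trifurcating root (three-point formulas)
    root = Node()
    (x, y, z) = nodes
    lx = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    ly = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lz = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, ln in ((x, lx), (y, ly), (z, lz)):
        node.length = max(ln, 0.0)
        root.add(node)
    return Tree(root)
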