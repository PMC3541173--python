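"""Neighbor-joining trees with bootstrap support.

Trees are unrooted and represented with a trifurcating root node; branch
lengths are in the units of the input distances (p-distance or Poisson
substitutions/site). Bootstrap support resamples alignment *columns* with
replacement, rebuilds distance matrix + NJ per replicate, and reports for
each internal branch of the original tree the percentage of replicates
containing the same leaf bipartition, as integer percentages.

Negative branch-length estimates (a standard NJ artifact on non-additive
data) are clamped to zero with the deficit transferred to the sister
branch, so the sum of the two sibling branch lengths is preserved.
Undefined distances (pairs lost to pairwise deletion) and saturated Poisson
distances abort tree building with explicit errors rather than being
silently imputed; in a bootstrap such replicates are skipped and tallied.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, MissingDistanceError, SaturationError
from .pairalign import DistanceMatrix, MultipleAlignment, p_distance, poisson_matrix

__all__ = [
    "TreeNode",
    "PhyloTree",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    root: TreeNode
    #: replicates skipped during bootstrap (undefined/saturated distances)
    skipped_replicates: int = 0

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial splits, keyed by the smaller-side leaf set under a node."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, TreeNode] = {}

        def side(node) -> frozenset:
            return frozenset(n.name for n in node.walk() if n.is_leaf)

        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            s = side(node)
            canon = min(s, all_leaves - s, key=lambda x: (len(x), sorted(x)))
            out[canon] = node
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths; the additivity check for NJ."""
        names = self.leaf_names()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        vals = np.zeros((n, n))

        def below(node):
            if node.is_leaf:
                return {idx[node.name]: node.length}
            acc = {}
            groups = []
            for c in node.children:
                d = below(c)
                groups.append(d)
                for k, v in d.items():
                    acc[k] = v
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            vals[a, b] = vals[b, a] = da + db
            if node.length:
                acc = {k: v + node.length for k, v in acc.items()}
            return acc

        below(self.root)
        return DistanceMatrix(names, vals, "path")


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration by Q-matrix minimization.

    For an additive input matrix the leaf-to-leaf path lengths of the
    output reproduce the input exactly. Ties in Q break on the smallest
    index pair; negative branch estimates are clamped to zero with the
    deficit moved to the sister branch.
    """
    und = d.undefined_pairs()
    if und:
        raise MissingDistanceError(
            f"undefined distance between {und[0][0]!r} and {und[0][1]!r}"
        )
    n = len(d.ids)
    if n < 3:
        raise InvalidInputError("neighbor joining needs at least 3 taxa")
    D = d.values.astype(float).copy()
    nodes = [TreeNode(name=i) for i in d.ids]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties resolved by smallest (i, j) position
        flat = np.argmin(Q)
        qi, qj = divmod(flat, m)
        if qi > qj:
            qi, qj = qj, qi
        i, j = active[qi], active[qj]
        dij = D[i, j]
        li = 0.5 * dij + (r[qi] - r[qj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final three-point join
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb = clamp(la, lb)
    lc = max(lc, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    nodes[a].length = la
    nodes[b].length = lb
    nodes[c].length = lc
    return PhyloTree(root)


def bootstrap_support(
    msa: MultipleAlignment,
    replicates: int = 500,
    rng_seed: int = 0,
    distance_kind: str = "p_distance",
) -> PhyloTree:
    """NJ tree of the alignment with column-bootstrap branch supports.

    Deterministic for a fixed seed. Replicates whose distance matrix has
    undefined (or, for Poisson distances, saturated) entries are skipped and
    tallied on the returned tree.
    """
    if replicates < 1:
        raise InvalidInputError("need at least one bootstrap replicate")
    if distance_kind not in ("p_distance", "poisson"):
        raise InvalidInputError(f"unknown distance kind {distance_kind!r}")

    def matrix_of(alignment: MultipleAlignment) -> DistanceMatrix:
        dm = p_distance(alignment)
        if distance_kind == "poisson":
            dm = poisson_matrix(dm)
        return dm

    tree = neighbor_joining(matrix_of(msa))
    target = tree.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(rng_seed)
    ncols = msa.ncols
    rows = [np.array(list(r)) for r in msa.rows]
    skipped = 0
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        boot = MultipleAlignment(
            list(msa.ids), ["".join(r[cols]) for r in rows]
        )
        try:
            rep_tree = neighbor_joining(matrix_of(boot))
        except (MissingDistanceError, SaturationError):
            skipped += 1
            continue
        done += 1
        rep_splits = rep_tree.bipartitions().keys()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in target.items():
        node.support = (
            int(round(100.0 * counts[split] / done)) if done else None
        )
    tree.skipped_replicates = skipped
    return tree


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _quote(name: str) -> str:
    if any(c in name for c in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree) -> str:
    """Newick string with branch lengths and integer supports as labels."""

    def fmt(node: TreeNode, top: bool = False) -> str:
        if node.is_leaf:
            body = _quote(node.name or "")
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{node.length:.6f}"

    return fmt(tree.root, top=True) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse the Newick dialect written by :func:`write_newick`."""
    s = text.strip()
    if not s.endswith(";"):
        raise InvalidInputError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        out = []
        while pos < len(s) and s[pos] not in "(),:;":
            out.append(s[pos])
            pos += 1
        return "".join(out)

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(s) or s[pos] != ")":
                raise InvalidInputError("unbalanced parentheses in newick")
            pos += 1
            label = parse_label()
            if label:
                node.support = int(label)
        else:
            node.name = parse_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise InvalidInputError(f"trailing characters in newick at {pos}")
    return PhyloTree(root)
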