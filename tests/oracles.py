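"""Independent brute-force oracles used by the test suite.

These deliberately re-derive scores by explicit enumeration over model
state paths (profile HMM) and alignment extension choices (local
alignment), sharing no code path with the package implementations.
"""
from __future__ import annotations

import math
from functools import lru_cache

from plantsdr.alphabet import encode


def viterbi_enumerate(hmm, seq: str) -> float:
    """Best local path score by depth-first enumeration of all legal paths."""
    x = encode(seq)
    L = len(x)
    M = hmm.match_count
    c = hmm._logs()
    ELO = c["ELO"]
    entry = c["entry"]
    lME = c["ltME"]
    if M > 1:
        lMM, lMI, lMD = c["ltMM"], c["ltMI"], c["ltMD"]
        lIM, lII = c["ltIM"], c["ltII"]
        lDM, lDD = c["ltDM"], c["ltDD"]
    best = [-math.inf]

    def step(kind: str, j: int, i: int, acc: float) -> None:
        # `i` is the index of the next residue to be consumed
        if kind == "M":
            if i >= L:
                return
            sc = acc + ELO[j, x[i]]
            best[0] = max(best[0], sc + lME[j])
            if j < M - 1:
                step("M", j + 1, i + 1, sc + lMM[j])
                step("I", j, i + 1, sc + lMI[j])
                step("D", j + 1, i + 1, sc + lMD[j])
        elif kind == "I":
            if i >= L:
                return
            step("I", j, i + 1, acc + lII[j])
            step("M", j + 1, i + 1, acc + lIM[j])
        else:  # delete state D_j, silent
            if j == M - 1:
                best[0] = max(best[0], acc)  # terminal delete exits freely
            else:
                step("M", j + 1, i, acc + lDM[j - 1])
                step("D", j + 1, i, acc + lDD[j - 1])

    for start in range(L):
        for j0 in range(M):
            step("M", j0, start, entry)
    return best[0]


def local_align_enumerate(a: str, b: str, sub, gap_open: float = 11.0,
                          gap_extend: float = 1.0) -> float:
    """Best local alignment score over all start/end/path choices.

    Gap of length k costs gap_open + k*gap_extend; an alignment must start
    and end on an aligned residue pair (leading/trailing gaps can only
    lower the score, so this loses no optima).
    """
    La, Lb = len(a), len(b)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, last: str) -> float:
        opts = [0.0]  # stop the alignment here
        if i < La and j < Lb:
            opts.append(sub(a[i], b[j]) + ext(i + 1, j + 1, "m"))
        if i < La:
            cost = gap_extend if last == "a" else gap_open + gap_extend
            opts.append(-cost + ext(i + 1, j, "a"))
        if j < Lb:
            cost = gap_extend if last == "b" else gap_open + gap_extend
            opts.append(-cost + ext(i, j + 1, "b"))
        return max(opts)

    best = 0.0
    for i in range(La):
        for j in range(Lb):
            best = max(best, sub(a[i], b[j]) + ext(i + 1, j + 1, "m"))
    ext.cache_clear()
    return best


def random_additive_tree(rng, n_leaves: int):
    """A random binary tree with positive branch lengths and its leaf
    distance matrix, built independently of the package's tree types."""
    import numpy as np

    nodes = [{"name": f"T{i}", "children": []} for i in range(n_leaves)]
    active = list(range(n_leaves))
    lengths = {}
    all_nodes = list(nodes)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = {"name": None, "children": [a, b]}
        all_nodes.append(parent)
        pid = len(all_nodes) - 1
        lengths[a] = float(rng.uniform(0.1, 1.0))
        lengths[b] = float(rng.uniform(0.1, 1.0))
        active = [k for k in active if k not in (a, b)] + [pid]
    a, b = active
    lengths[a] = float(rng.uniform(0.1, 1.0))
    lengths[b] = float(rng.uniform(0.1, 1.0))
    root = {"name": None, "children": [a, b]}
    all_nodes.append(root)

    # leaf sets and pairwise path lengths by recursion
    D = np.zeros((n_leaves, n_leaves))

    def below(idx):
        node = all_nodes[idx]
        if not node["children"]:
            return {idx: lengths.get(idx, 0.0)}
        acc = {}
        groups = [below(c) for c in node["children"]]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for u, du in groups[gi].items():
                    for v, dv in groups[gj].items():
                        D[u, v] = D[v, u] = du + dv
        for g in groups:
            for k, v in g.items():
                acc[k] = v + lengths.get(idx, 0.0)
        return acc

    below(len(all_nodes) - 1)

    def splits(idx, parent_split=None):
        """Non-trivial leaf bipartitions (as frozensets of leaf names)."""
        node = all_nodes[idx]
        out = set()
        if not node["children"]:
            return out, {node["name"]}
        leaves = set()
        for c in node["children"]:
            sub, sl = splits(c)
            out |= sub
            leaves |= sl
        if 1 < len(leaves) < n_leaves - 1:
            out.add(frozenset(leaves))
        return out, leaves

    split_set, _ = splits(len(all_nodes) - 1)
    names = [f"T{i}" for i in range(n_leaves)]
    return names, D, split_set
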