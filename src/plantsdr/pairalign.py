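"""Pairwise and progressive alignment plus the distance computations.

This module feeds three downstream consumers: truncated-protein rescue (via
:func:`local_align` and :func:`segment_identity_pass`), orphan-family
clustering (via :func:`evalue`), and tree building (via
:func:`progressive_msa`, :func:`p_distance`, :func:`poisson_correct`).

Conventions
-----------
* Substitution table BLOSUM62; affine gap cost ``gap_open + k * gap_extend``
  for a gap of length ``k`` (defaults 11/1, conventional protein values).
* Pairwise identity is computed over aligned columns excluding columns that
  are gaps in both rows; a column gapped in one row counts as a mismatch.
* p-distances use pairwise deletion: only columns where both rows carry a
  residue are compared, and a pair with no comparable column is undefined
  (stored as NaN, written as ``NA``).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage

from .alphabet import AA, blosum62
from .errors import InvalidInputError, SaturationError

__all__ = [
    "PairwiseAlignment",
    "MultipleAlignment",
    "DistanceMatrix",
    "local_align",
    "segment_identity_pass",
    "progressive_msa",
    "p_distance",
    "poisson_correct",
    "poisson_matrix",
    "evalue",
]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored local alignment of two sequences.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings covering only
    the locally aligned region; degapping them recovers contiguous substrings
    of the inputs. ``identity`` is the fraction of identical columns over all
    aligned columns (dual-gap columns cannot occur in a pairwise local
    alignment).
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    aligned_length: int

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise InvalidInputError("aligned rows differ in length")


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over the input sequences, in input order."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise InvalidInputError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise InvalidInputError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        aln = AlignIO.read(path, "fasta")
        return cls([r.id for r in aln], [str(r.seq).upper() for r in aln])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with an undefined-entry marker (NaN)."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "p_distance" or "poisson"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidInputError("distance matrix shape does not match ids")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.10g}" for v in self.values[i]
                ]
                fh.write(name + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append(
                    [float("nan") if c == "NA" else float(c) for c in parts[1:]]
                )
        return cls(header, np.array(rows), kind)


# ---------------------------------------------------------------------------
# pairwise local alignment
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython charges open_gap_score for the first gapped column, so a gap
    # of length k costs open+k*extend under the convention used here.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


EMPTY_ALIGNMENT = PairwiseAlignment("", "", 0.0, 0.0, 0)


def local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal-score Smith-Waterman local alignment under affine gaps.

    Returns the empty alignment (score 0) when no positive-scoring pair of
    segments exists. Among co-optimal alignments, the first alignment in
    Biopython's deterministic traceback order is reported; the score, which is
    what every downstream decision consumes, is unique.
    """
    if not a or not b:
        raise InvalidInputError("cannot align an empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return EMPTY_ALIGNMENT
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    ncols = len(sa)
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return PairwiseAlignment(sa, sb, float(score), matches / ncols, ncols)


def segment_identity_pass(
    aln: PairwiseAlignment, window: int = 60, min_identity: float = 0.5
) -> bool:
    """Does some window of exactly ``window`` columns exceed ``min_identity``?

    Implements the truncated-protein rescue criterion: a segment of 60
    aligned positions with strictly more than 50% identity. Windows containing
    dual-gap columns do not qualify; identity within a window is
    matches / window.
    """
    if window <= 0:
        raise InvalidInputError("window must be positive")
    n = aln.aligned_length
    if n < window:
        return False
    sa, sb = aln.aligned_a, aln.aligned_b
    match = np.fromiter(
        (1 if x == y and x != "-" else 0 for x, y in zip(sa, sb)), dtype=int, count=n
    )
    dual = np.fromiter(
        (1 if x == "-" and y == "-" else 0 for x, y in zip(sa, sb)), dtype=int, count=n
    )
    cm = np.concatenate([[0], np.cumsum(match)])
    cd = np.concatenate([[0], np.cumsum(dual)])
    for s in range(n - window + 1):
        if cd[s + window] - cd[s] > 0:
            continue
        if (cm[s + window] - cm[s]) / window > min_identity:
            return True
    return False


def evalue(
    score: float,
    query_len: int,
    db_len: int,
    K: float = 0.041,
    lam: float = 0.267,
) -> float:
    """Karlin-Altschul expect value E = K*m*n*exp(-lambda*score).

    Defaults are the conventional gapped BLOSUM62 parameters. Used only for
    thresholding similarity links when clustering orphan families; no attempt
    is made to reproduce any particular search tool's E-values.
    """
    if K <= 0 or lam <= 0:
        raise InvalidInputError("K and lambda must be positive")
    if query_len <= 0 or db_len <= 0:
        raise InvalidInputError("sequence lengths must be positive")
    return K * query_len * db_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    """Per-column residue frequencies (ncols, 20); gaps contribute no mass."""
    ncols = len(rows[0])
    counts = np.zeros((ncols, 20))
    for r in rows:
        for j, c in enumerate(r):
            if c == "-":
                continue
            k = AA.find(c)
            if k >= 0:
                counts[j, k] += 1
    return counts / len(rows)


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap Needleman-Wunsch of two profiles (frequency-vector columns)."""
    S = blosum62()
    fa, fb = _profile_freqs(rows_a), _profile_freqs(rows_b)
    na, nb = fa.shape[0], fb.shape[0]
    col = fa @ S @ fb.T  # (na, nb) expected column-pair score
    NEG = -1e30
    go, ge = -(gap_open + gap_extend), -gap_extend
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, nb + 1):
        Y[0, j] = go + ge * (j - 1)
    ptrM = np.zeros((na + 1, nb + 1), dtype=np.int8)
    ptrX = np.zeros((na + 1, nb + 1), dtype=np.int8)
    ptrY = np.zeros((na + 1, nb + 1), dtype=np.int8)
    ptrX[2:, 0] = 1  # leading gap runs continue in their own state
    ptrY[0, 2:] = 2
    for i in range(1, na + 1):
        cm = M[i - 1]
        cx = X[i - 1]
        cy = Y[i - 1]
        for j in range(1, nb + 1):
            # M: consume one column from each
            best, arg = cm[j - 1], 0
            if cx[j - 1] > best:
                best, arg = cx[j - 1], 1
            if cy[j - 1] > best:
                best, arg = cy[j - 1], 2
            M[i, j] = best + col[i - 1, j - 1]
            ptrM[i, j] = arg
            # X: consume column of A against a gap
            ox, ax = cm[j] + go, 0
            ex = cx[j] + ge
            if ex > ox:
                ox, ax = ex, 1
            oy = cy[j] + go
            if oy > ox:
                ox, ax = oy, 2
            X[i, j] = ox
            ptrX[i, j] = ax
            # Y: consume column of B against a gap (pointer values are the
            # state ids 0=M, 1=X, 2=Y of the predecessor at (i, j-1))
            oy2, ay = M[i, j - 1] + go, 0
            ey = Y[i, j - 1] + ge
            if ey > oy2:
                oy2, ay = ey, 2
            xx = X[i, j - 1] + go
            if xx > oy2:
                oy2, ay = xx, 1
            Y[i, j] = oy2
            ptrY[i, j] = ay
    # traceback from the best of the three end states (prefer M, then X, then Y)
    i, j = na, nb
    state = int(np.argmax([M[na, nb], X[na, nb], Y[na, nb]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("m")
            prev = ptrM[i, j]
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            ops.append("a")
            prev = ptrX[i, j]
            i -= 1
            state = prev
        else:
            ops.append("b")
            prev = ptrY[i, j]
            j -= 1
            state = prev
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = jb = 0
    for op in ops:
        if op == "m":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[jb]
            ia += 1
            jb += 1
        elif op == "a":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[jb]
            jb += 1
    return out_a, out_b


def progressive_msa(
    seqs: Sequence[str],
    ids: Sequence[str] | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Progressive multiple alignment over an average-linkage guide tree.

    The guide tree is agglomerated from pairwise p-distances (1 - local
    alignment identity); profiles are merged leaf-to-root with affine-gap
    profile-profile alignment. Output rows are returned in input order. This
    is a deliberately simple progressive scheme in the ClustalW mould, not a
    clone of any particular aligner.
    """
    if len(seqs) < 2:
        raise InvalidInputError("progressive_msa needs at least 2 sequences")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    ids = list(ids)
    n = len(seqs)
    if n == 2:
        a, b = _align_profiles([seqs[0]], [seqs[1]], gap_open, gap_extend)
        return MultipleAlignment(ids, [a[0], b[0]])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(seqs[i], seqs[j], matrix, gap_open, gap_extend)
            dist[i, j] = dist[j, i] = 1.0 - aln.identity
    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    # nodes: index -> (rows, member input indices); children ordered by the
    # lexicographically smallest member id so the result is independent of
    # input permutation for well-separated sequences.
    nodes: dict[int, tuple[list[str], list[int]]] = {
        i: ([seqs[i]], [i]) for i in range(n)
    }
    nxt = n
    for za, zb, _, _ in Z:
        a_rows, a_idx = nodes.pop(int(za))
        b_rows, b_idx = nodes.pop(int(zb))
        if min(ids[k] for k in b_idx) < min(ids[k] for k in a_idx):
            a_rows, b_rows = b_rows, a_rows
            a_idx, b_idx = b_idx, a_idx
        out_a, out_b = _align_profiles(a_rows, b_rows, gap_open, gap_extend)
        nodes[nxt] = (out_a + out_b, a_idx + b_idx)
        nxt += 1
    rows, order = nodes.popitem()[1]
    final = [""] * n
    for r, k in zip(rows, order):
        final[k] = r
    return MultipleAlignment(ids, final)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def p_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """p-distance with pairwise deletion.

    For each pair of rows only columns where both carry a residue are
    compared; the distance is mismatches / compared columns. A pair with zero
    comparable columns gets the undefined marker (NaN).
    """
    n = len(msa.rows)
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            total = int(both.sum())
            if total == 0:
                vals[i, j] = vals[j, i] = float("nan")
                continue
            mism = int((arr[i][both] != arr[j][both]).sum())
            vals[i, j] = vals[j, i] = mism / total
    return DistanceMatrix(list(msa.ids), vals, "p_distance")


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p), substitutions/site."""
    if p < 0 or p > 1:
        raise InvalidInputError(f"p-distance {p} outside [0, 1]")
    if p == 1:
        raise SaturationError("p-distance of 1 cannot be Poisson-corrected")
    return -math.log1p(-p)


def poisson_matrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Apply the Poisson correction elementwise; NaN entries propagate."""
    if dm.kind != "p_distance":
        raise InvalidInputError("poisson correction applies to p-distances")
    vals = dm.values.copy()
    n = len(dm.ids)
    for i in range(n):
        for j in range(n):
            if i == j or math.isnan(vals[i, j]):
                continue
            vals[i, j] = poisson_correct(vals[i, j])
    return DistanceMatrix(list(dm.ids), vals, "poisson")
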