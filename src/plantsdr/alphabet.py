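"""Amino-acid alphabet, background frequencies, BLOSUM62 helpers."""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
#: index used for ambiguity codes (X, B, Z, ...) in encoded sequences
AMBIG = 20

# Standard BLOSUM62 marginal amino-acid frequencies (Robinson-Robinson style
# background as used by protein search tools), renormalized to sum to 1.
_BG = {
    "A": 0.0787, "C": 0.0183, "D": 0.0540, "E": 0.0629, "F": 0.0397,
    "G": 0.0710, "H": 0.0219, "I": 0.0564, "K": 0.0591, "L": 0.0963,
    "M": 0.0224, "N": 0.0432, "P": 0.0493, "Q": 0.0383, "R": 0.0512,
    "S": 0.0680, "T": 0.0557, "V": 0.0656, "W": 0.0130, "Y": 0.0296,
}
BACKGROUND = np.array([_BG[a] for a in AA])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


@lru_cache(maxsize=None)
def blosum62() -> np.ndarray:
    """BLOSUM62 scores as a float (20, 20) array in :data:`AA` order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = m[a, b]
    return out


@lru_cache(maxsize=None)
def substitution_conditionals() -> np.ndarray:
    """Conditional substitution probabilities q(b | a) derived from BLOSUM62.

    BLOSUM62 scores are half-bit log-odds s(a,b) = 2*log2(p(a,b)/(p(a)p(b))),
    so p(b|a) is proportional to bg(b) * 2**(s/2). Row a of the returned
    (20, 20) array is the distribution over replacement residues b.
    """
    s = blosum62()
    q = BACKGROUND[None, :] * np.exp2(s / 2.0)
    return q / q.sum(axis=1, keepdims=True)


def encode(seq: str) -> np.ndarray:
    """Encode a protein sequence as indices into :data:`AA`.

    Any character outside the 20 canonical residues (ambiguity codes such as
    X/B/Z/J/U/O) maps to :data:`AMBIG` and is scored as background.
    """
    return np.array([AA_INDEX.get(c, AMBIG) for c in seq.upper()], dtype=np.int64)
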