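"""Position-specific profile hidden Markov models for SDR classification.

The inventory machinery uses three tiers of models built on this one type:
broad Rossmann-fold detectors (``pfam_set``), one model per SDR structural
type (``type_set``: classical, extended, divergent, ...), and fine-grained
family models (``family_set``). A model is a linear chain of match states
with position-specific emissions, flanked by insert and delete states, scored
in *local* mode: alignment may enter at any match state (uniform entry
probability 1/M), exit early from any match state with a small fixed exit
probability, and sequence residues outside the aligned core are emitted by
the background at zero log-odds cost. Local scoring is what lets truncated
gene models still reach meaningful scores.

Scores are Viterbi (best state path) log-odds in bits against a fixed
background amino-acid distribution; residues outside the 20-letter alphabet
are emitted as background (zero contribution). Every model carries an
inclusion cutoff in bits, and type models additionally carry an "unknown
floor": a lower bound above which a sequence is still safely a superfamily
member even though its type cannot be called.

Model architecture, in detail
-----------------------------
For a model with M match states (0-based ``j``):

* entry ``B -> M_j`` with probability 1/M for every j;
* match state ``j < M-1`` distributes (1 - exit_prob) over
  ``{M->M, M->I, M->D}`` as estimated from the seed alignment, and
  ``exit_prob`` to E; the last match state exits with probability 1;
* insert state ``I_j`` (between j and j+1) emits background residues and
  moves over ``{I->I, I->M}``;
* delete state ``D_j`` (skipping match position j, 1 <= j <= M-1) moves over
  ``{D->D, D->M}``; the final delete state ``D_{M-1}`` exits silently.

All stochastic vectors sum to 1; the brute-force path-enumeration oracle in
the test suite mirrors this parameterization exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .alphabet import AA, AA_INDEX, AMBIG, BACKGROUND, encode, substitution_conditionals
from .errors import (
    CalibrationError,
    DegenerateModelError,
    InvalidInputError,
)

__all__ = [
    "SeedAlignment",
    "ProfileHMM",
    "TrainResult",
    "build_profile",
    "train_iterative",
    "calibrate_cutoff",
    "write_profile",
    "read_profile",
]

GAP_CHARS = set("-.")
#: fixed per-match-state early-exit probability of the local model
DEFAULT_EXIT_PROB = 0.01


@dataclass
class SeedAlignment:
    """An aligned set of representative family sequences."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise InvalidInputError("ids and rows differ in number")
        if len(self.rows) < 2:
            raise InvalidInputError("a seed alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise InvalidInputError("seed alignment rows differ in length")
        self.rows = [r.upper().replace(".", "-") for r in self.rows]

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    def sequences(self) -> list[str]:
        return [r.replace("-", "") for r in self.rows]

    @classmethod
    def from_file(cls, path, fmt: str = "fasta") -> "SeedAlignment":
        aln = AlignIO.read(path, fmt)
        return cls([r.id for r in aln], [str(r.seq) for r in aln])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")

    def to_stockholm(self, path) -> None:
        width = max(len(i) for i in self.ids) + 2
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for i, r in zip(self.ids, self.rows):
                fh.write(i.ljust(width) + r + "\n")
            fh.write("//\n")


@dataclass
class ProfileHMM:
    """A trained profile HMM with its score thresholds.

    Emission/transition arrays are probabilities (not logs); `score` works on
    cached log-odds arrays. ``model_class`` labels the tier the model belongs
    to (pfam_set / type_set / family_set).
    """

    model_id: str
    model_class: str
    match_count: int
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    tMM: np.ndarray  # (M-1,) M_j -> M_{j+1}
    tMI: np.ndarray  # (M-1,)
    tMD: np.ndarray  # (M-1,)
    tME: np.ndarray  # (M,)  early/terminal exit
    tIM: np.ndarray  # (M-1,)
    tII: np.ndarray  # (M-1,)
    tDM: np.ndarray  # (max(M-2,0),) D_j -> M_{j+1}, j = 1..M-2
    tDD: np.ndarray  # (max(M-2,0),)
    inclusion_cutoff: float = 0.0
    unknown_floor: float | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self, tol: float = 1e-9) -> None:
        M = self.match_count
        if M < 1:
            raise InvalidInputError("match_count must be >= 1")
        if not np.isfinite(self.inclusion_cutoff):
            raise InvalidInputError("inclusion_cutoff must be finite")
        if np.abs(self.match_emissions.sum(axis=1) - 1).max() > tol:
            raise InvalidInputError("match emissions do not sum to 1")
        for vec in (self.insert_emissions, self.background):
            if abs(vec.sum() - 1) > tol:
                raise InvalidInputError("emission vector does not sum to 1")
        if M > 1:
            out = self.tMM + self.tMI + self.tMD + self.tME[:-1]
            if np.abs(out - 1).max() > tol:
                raise InvalidInputError("match transitions do not sum to 1")
            if abs(self.tME[-1] - 1) > tol:
                raise InvalidInputError("terminal match state must exit")
            if np.abs(self.tIM + self.tII - 1).max() > tol:
                raise InvalidInputError("insert transitions do not sum to 1")
            if M > 2 and np.abs(self.tDM + self.tDD - 1).max() > tol:
                raise InvalidInputError("delete transitions do not sum to 1")

    # -- cached log-odds parameterization ---------------------------------
    def _logs(self):
        if "ELO" not in self._cache:
            with np.errstate(divide="ignore"):
                elo = np.zeros((self.match_count, 21))
                elo[:, :20] = np.log2(self.match_emissions / self.background)
                # ambiguity codes: background emission, zero log-odds
                elo[:, AMBIG] = 0.0
                self._cache["ELO"] = elo
                for name in ("tMM", "tMI", "tMD", "tME", "tIM", "tII", "tDM", "tDD"):
                    self._cache["l" + name] = np.log2(getattr(self, name))
                self._cache["entry"] = -np.log2(self.match_count)
        return self._cache

    def score(self, seq: str) -> float:
        """Viterbi log-odds score (bits) of the best local alignment."""
        if not seq:
            raise InvalidInputError("cannot score an empty sequence")
        M = self.match_count
        c = self._logs()
        x = encode(seq)
        L = len(x)
        ELO = c["ELO"]
        entry = c["entry"]
        NEG = -np.inf
        if M == 1:
            return float(ELO[0, x].max() + entry)  # enter, emit once, exit free
        lMM, lMI, lMD = c["ltMM"], c["ltMI"], c["ltMD"]
        lME, lIM, lII = c["ltME"], c["ltIM"], c["ltII"]
        lDM, lDD = c["ltDM"], c["ltDD"]
        # cumulative delete-chain costs: s[t] = sum of lDD for D_1..D_{t-1}->D_t
        s = np.zeros(M - 1)
        if M > 2:
            s[1:] = np.cumsum(lDD)
        prevM = np.full(M, NEG)
        prevI = np.full(M - 1, NEG)
        prevD = np.full(M - 1, NEG)  # prevD[t-1] is D_t, t = 1..M-1
        best = NEG
        for i in range(L):
            e = ELO[:, x[i]]
            cand = np.full(M, entry)
            np.maximum(cand[1:], prevM[:-1] + lMM, out=cand[1:])
            np.maximum(cand[1:], prevI + lIM, out=cand[1:])
            if M > 2:
                # D_t -> M_{t+1} for t = 1..M-2 lands on match index 2..M-1
                np.maximum(cand[2:], prevD[:-1] + lDM, out=cand[2:])
            curM = e + cand
            curI = np.maximum(prevM[:-1] + lMI, prevI + lII)
            # delete chain within this row: enter D_t from M_{t-1}
            A = curM[:-1] + lMD  # A[t-1] = entry into D_t
            curD = s + np.maximum.accumulate(A - s)
            row_best = (curM + lME).max()
            if curD[-1] > row_best:
                row_best = curD[-1]  # exit via terminal delete, prob 1
            if row_best > best:
                best = row_best
            prevM, prevI, prevD = curM, curI, curD
        return float(best)

    def score_many(self, seqs: Mapping[str, str]) -> dict[str, float]:
        return {sid: self.score(s) for sid, s in seqs.items()}


def _match_columns(rows: Sequence[str], gap_threshold: float) -> list[int]:
    ncols = len(rows[0])
    n = len(rows)
    cols = []
    for j in range(ncols):
        gaps = sum(1 for r in rows if r[j] in GAP_CHARS)
        if gaps / n < gap_threshold:
            cols.append(j)
    return cols


def build_profile(
    aln: SeedAlignment,
    gap_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    model_id: str = "model",
    model_class: str = "family_set",
    exit_prob: float = DEFAULT_EXIT_PROB,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose gap fraction is strictly below ``gap_threshold`` become
    match states (a column at exactly the threshold is excluded). Match
    emissions are observed counts smoothed with a BLOSUM62-mixture
    pseudocount of total weight ``pseudocount_weight``; transitions are
    estimated from the observed state paths with Laplace (add-one)
    smoothing. Sequences are weighted uniformly.
    """
    if not 0 < gap_threshold <= 1:
        raise InvalidInputError("gap_threshold must be in (0, 1]")
    if pseudocount_weight <= 0:
        raise InvalidInputError("pseudocount_weight must be positive")
    rows = aln.rows
    match_cols = _match_columns(rows, gap_threshold)
    M = len(match_cols)
    if M == 0:
        raise DegenerateModelError(
            f"no column of {aln.ncols} qualifies as a match state"
        )
    nseq = len(rows)
    Q = substitution_conditionals()

    counts = np.zeros((M, 20))
    for r in rows:
        for mj, j in enumerate(match_cols):
            k = AA_INDEX.get(r[j])
            if k is not None:
                counts[mj, k] += 1.0
    freqs = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300)
    # substitution-mixture pseudocount: what residues the observed column
    # plausibly mutates into under BLOSUM62 conditionals
    mix = freqs @ Q
    mix[counts.sum(axis=1) == 0] = BACKGROUND
    emis = counts + pseudocount_weight * mix
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts from per-row state paths
    cMM = np.zeros(max(M - 1, 0))
    cMI = np.zeros(max(M - 1, 0))
    cMD = np.zeros(max(M - 1, 0))
    cIM = np.zeros(max(M - 1, 0))
    cII = np.zeros(max(M - 1, 0))
    cDM = np.zeros(max(M - 2, 0))
    cDD = np.zeros(max(M - 2, 0))
    match_set = {j: mj for mj, j in enumerate(match_cols)}
    for r in rows:
        path: list[tuple[str, int]] = []
        cur_m = -1
        for j, ch in enumerate(r):
            if j in match_set:
                cur_m = match_set[j]
                path.append(("M" if ch not in GAP_CHARS else "D", cur_m))
            elif ch not in GAP_CHARS:
                path.append(("I", cur_m))
        for (s1, j1), (s2, j2) in zip(path, path[1:]):
            if s1 == "M" and j1 < M - 1:
                if s2 == "M" and j2 == j1 + 1:
                    cMM[j1] += 1
                elif s2 == "I" and j2 == j1:
                    cMI[j1] += 1
                elif s2 == "D" and j2 == j1 + 1:
                    cMD[j1] += 1
            elif s1 == "I" and 0 <= j1 < M - 1:
                if s2 == "I" and j2 == j1:
                    cII[j1] += 1
                elif s2 == "M" and j2 == j1 + 1:
                    cIM[j1] += 1
                # I->D has no profile transition; such adjacencies are dropped
            elif s1 == "D" and 1 <= j1 <= M - 2:
                if s2 == "D" and j2 == j1 + 1:
                    cDD[j1 - 1] += 1
                elif s2 == "M" and j2 == j1 + 1:
                    cDM[j1 - 1] += 1

    def _norm3(a, b, c_):
        tot = a + b + c_
        return a / tot, b / tot, c_ / tot

    tMM, tMI, tMD = _norm3(cMM + 1.0, cMI + 1.0, cMD + 1.0)
    scale = 1.0 - exit_prob
    tME = np.full(M, exit_prob)
    tME[-1] = 1.0
    tMM, tMI, tMD = tMM * scale, tMI * scale, tMD * scale
    tot = cIM + cII + 2.0
    tIM, tII = (cIM + 1.0) / tot, (cII + 1.0) / tot
    tot = cDM + cDD + 2.0
    tDM, tDD = (cDM + 1.0) / tot, (cDD + 1.0) / tot

    hmm = ProfileHMM(
        model_id=model_id,
        model_class=model_class,
        match_count=M,
        match_emissions=emis,
        insert_emissions=BACKGROUND.copy(),
        background=BACKGROUND.copy(),
        tMM=tMM, tMI=tMI, tMD=tMD, tME=tME,
        tIM=tIM, tII=tII, tDM=tDM, tDD=tDD,
    )
    hmm.validate()
    return hmm


def calibrate_cutoff(
    hmm: ProfileHMM,
    positives: Iterable[str],
    decoys: Iterable[str],
    margin: float = 0.0,
) -> float:
    """Inclusion cutoff = min(positive scores) - margin, floored above decoys.

    The published inventory prints type-model thresholds but no per-family
    thresholds, so family cutoffs are calibrated from the model's own
    training sequences against supplied decoys. Raises
    :class:`CalibrationError` when the score ranges overlap.
    """
    pos = [hmm.score(s) for s in positives]
    dec = [hmm.score(s) for s in decoys]
    if not pos or not dec:
        raise InvalidInputError("need at least one positive and one decoy")
    if max(dec) >= min(pos):
        raise CalibrationError(min(pos), max(dec))
    eps = 1e-6
    return max(min(pos) - margin, max(dec) + eps)


@dataclass
class TrainResult:
    hmm: ProfileHMM
    member_ids: set[str]
    converged: bool
    rounds: int


def train_iterative(
    seed_aln: SeedAlignment,
    database: Mapping[str, str],
    cutoff: float,
    max_rounds: int = 5,
    gap_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    model_id: str = "model",
    model_class: str = "family_set",
) -> TrainResult:
    """Iteratively refine a model until no new members are recruited.

    Each round builds a profile from the current member alignment, scores
    the database, and adds every sequence at or above ``cutoff``. The member
    set is monotone non-shrinking and always contains the seeds; the result
    is flagged unconverged if ``max_rounds`` is exhausted while members are
    still being added.
    """
    from .pairalign import progressive_msa  # local import to avoid cycle at import time

    if not np.isfinite(cutoff):
        raise InvalidInputError("cutoff must be finite")
    if max_rounds < 1:
        raise InvalidInputError("max_rounds must be >= 1")
    members: dict[str, str] = {i: s for i, s in zip(seed_aln.ids, seed_aln.sequences())}
    aln = seed_aln
    hmm = build_profile(aln, gap_threshold, pseudocount_weight, model_id, model_class)
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        hmm = build_profile(aln, gap_threshold, pseudocount_weight, model_id, model_class)
        hmm.inclusion_cutoff = cutoff
        new = {
            sid: s
            for sid, s in database.items()
            if sid not in members and hmm.score(s) >= cutoff
        }
        if not new:
            converged = True
            break
        members.update(new)
        ids = sorted(members)
        msa = progressive_msa([members[i] for i in ids], ids)
        aln = SeedAlignment(msa.ids, msa.rows)
    return TrainResult(hmm, set(members), converged, rounds)


# ---------------------------------------------------------------------------
# plain-text serialization (bit-exact round trip via float hex)
# ---------------------------------------------------------------------------


def _fmt(arr: np.ndarray) -> str:
    return " ".join(float(v).hex() for v in np.atleast_1d(arr))


def _parse(line: str) -> np.ndarray:
    parts = line.split()
    return np.array([float.fromhex(p) for p in parts]) if parts else np.zeros(0)


def write_profile(hmm: ProfileHMM, path) -> None:
    """Serialize a model to the package's plain-text profile format.

    One header block (id, class, match count, cutoffs), then the shared
    vectors, then one ``state`` line per match state with its emission row.
    Floats are written as C99 hex literals so the round trip is bit-exact.
    """
    with open(path, "w") as fh:
        fh.write("PLANTSDR-PROFILE 1\n")
        fh.write(f"model_id {hmm.model_id}\n")
        fh.write(f"model_class {hmm.model_class}\n")
        fh.write(f"match_count {hmm.match_count}\n")
        fh.write(f"inclusion_cutoff {float(hmm.inclusion_cutoff).hex()}\n")
        floor = "none" if hmm.unknown_floor is None else float(hmm.unknown_floor).hex()
        fh.write(f"unknown_floor {floor}\n")
        fh.write(f"alphabet {AA}\n")
        fh.write(f"background {_fmt(hmm.background)}\n")
        fh.write(f"insert_emissions {_fmt(hmm.insert_emissions)}\n")
        for name in ("tMM", "tMI", "tMD", "tME", "tIM", "tII", "tDM", "tDD"):
            fh.write(f"{name} {_fmt(getattr(hmm, name))}\n")
        for j in range(hmm.match_count):
            fh.write(f"state {j} {_fmt(hmm.match_emissions[j])}\n")
        fh.write("end\n")


def read_profile(path) -> ProfileHMM:
    fields: dict[str, str] = {}
    states: dict[int, np.ndarray] = {}
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != "PLANTSDR-PROFILE 1":
            raise InvalidInputError(f"not a profile file: {magic!r}")
        for line in fh:
            line = line.rstrip("\n")
            if line == "end":
                break
            key, _, rest = line.partition(" ")
            if key == "state":
                idx, _, vals = rest.partition(" ")
                states[int(idx)] = _parse(vals)
            else:
                fields[key] = rest
    M = int(fields["match_count"])
    emis = np.vstack([states[j] for j in range(M)])
    floor = fields["unknown_floor"]
    hmm = ProfileHMM(
        model_id=fields["model_id"],
        model_class=fields["model_class"],
        match_count=M,
        match_emissions=emis,
        insert_emissions=_parse(fields["insert_emissions"]),
        background=_parse(fields["background"]),
        tMM=_parse(fields["tMM"]), tMI=_parse(fields["tMI"]),
        tMD=_parse(fields["tMD"]), tME=_parse(fields["tME"]),
        tIM=_parse(fields["tIM"]), tII=_parse(fields["tII"]),
        tDM=_parse(fields["tDM"]), tDD=_parse(fields["tDD"]),
        inclusion_cutoff=float.fromhex(fields["inclusion_cutoff"]),
        unknown_floor=None if floor == "none" else float.fromhex(floor),
    )
    hmm.validate()
    return hmm
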