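"""The SDR inventory: three HMM tiers combined through a decision tree.

Classification combines three independently-run model tiers:

1. broad Rossmann-fold detectors (``pfam_set``),
2. one model per SDR structural type (``type_set``), each with an inclusion
   cutoff and, for classical/extended/divergent, a lower "unknown floor"
   above which a sequence is still safely an SDR but untyped,
3. fine-grained nomenclature-style family models (``family_set``), whose
   trailing suffix letter encodes the type (C/E/D/U/A).

Decision tree, in rule order, for one sequence:

1. a family-tier pass is directly positive; the type comes from the family
   suffix;
2. else a pfam-tier pass corroborated by a type-tier pass is positive with
   the best passing type;
3. else a pfam-tier pass with the best type score above that type's unknown
   floor is positive with type "unknown";
4. else, if exactly one tier recognizes the sequence, the call is deferred:
   an explicit whitelist (curated structural evidence, e.g. the atypical
   PLR/IFR family) makes it positive, an exclusion list (e.g. medium-chain
   dehydrogenases) makes it negative, otherwise it lands on the ambiguous
   list;
5. no recognition at all is negative.

Refinement then (a) keeps one gene model per locus (max HMM score, alignment
score on other genomes as tie-break, disagreement flagged for manual
review), (b) rescues truncated proteins that align to an already-classified
sequence with a 60-residue segment above 50% identity, and (c) groups the
remaining family-less positives into orphan families by single-linkage
clustering at E <= 1e-40.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import pairalign
from .errors import ConfigurationError, InvalidInputError
from .io import ProteinRecord
from .pairalign import local_align, p_distance, progressive_msa, segment_identity_pass
from .profilehmm import ProfileHMM

__all__ = [
    "TypeCutoffs",
    "HmmHit",
    "DecisionOutcome",
    "OrphanCluster",
    "InventoryTable",
    "InventoryConfig",
    "scan_three_tiers",
    "decide",
    "select_gene_model",
    "rescue_truncated",
    "cluster_orphans",
    "build_inventory",
    "family_type",
]

#: fixed tie-break order between type models at equal score
TYPE_ORDER = ("classical", "extended", "divergent", "intermediate", "complex")

SUFFIX_TYPE = {
    "C": "classical",
    "E": "extended",
    "D": "divergent",
    "U": "unknown",
    "A": "atypical",
}


def family_type(family_id: str) -> str:
    """SDR type encoded by the nomenclature-style suffix letter."""
    if family_id and family_id[-1] in SUFFIX_TYPE:
        return SUFFIX_TYPE[family_id[-1]]
    return "unknown"


@dataclass
class TypeCutoffs:
    """Published type-model thresholds in bits.

    ``inclusion`` is the per-type significance cutoff; ``unknown_floor`` is
    the lower bound above which a hit still safely marks an SDR without a
    confident type call. The default plant configuration drops the
    intermediate and complex types, which do not occur in plants.
    """

    inclusion: dict[str, float] = field(
        default_factory=lambda: {
            "classical": 138.0,
            "extended": 108.0,
            "intermediate": 162.0,
            "divergent": 160.0,
            "complex": 140.0,
        }
    )
    unknown_floor: dict[str, float] = field(
        default_factory=lambda: {
            "classical": 29.0,
            "extended": 75.0,
            "divergent": 100.0,
        }
    )

    def __post_init__(self):
        for t, floor in self.unknown_floor.items():
            if t in self.inclusion and floor >= self.inclusion[t]:
                raise InvalidInputError(
                    f"unknown floor for {t} must sit below the inclusion cutoff"
                )

    @classmethod
    def default_plant(cls) -> "TypeCutoffs":
        c = cls()
        for t in ("intermediate", "complex"):
            c.inclusion.pop(t, None)
        return c

    def apply(self, type_models: Sequence[ProfileHMM]) -> None:
        """Stamp these thresholds onto type-tier models by model id."""
        for m in type_models:
            if m.model_id in self.inclusion:
                m.inclusion_cutoff = self.inclusion[m.model_id]
            m.unknown_floor = self.unknown_floor.get(m.model_id)


@dataclass(frozen=True)
class HmmHit:
    sequence_id: str
    model_id: str
    model_class: str  # pfam_set / type_set / family_set
    score: float
    passes_cutoff: bool
    passes_floor: bool


@dataclass
class DecisionOutcome:
    sequence_id: str
    verdict: str  # positive / ambiguous / negative
    sdr_type: str | None = None
    family_id: str | None = None
    evidence: list[str] = field(default_factory=list)
    manual_review: bool = False

    def __post_init__(self):
        if self.verdict == "positive" and self.sdr_type is None:
            raise InvalidInputError("positive outcome requires a type")
        if self.verdict == "negative" and (self.sdr_type or self.family_id):
            raise InvalidInputError("negative outcome carries no type/family")


@dataclass
class OrphanCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str
    mean_pairwise_identity: float | None  # None for singletons
    tiers: set[str] = field(default_factory=set)


@dataclass
class InventoryTable:
    """Classified inventory of one genome set: main + ambiguous lists."""

    main: list[DecisionOutcome]
    ambiguous: list[DecisionOutcome]
    negative: list[DecisionOutcome]
    counts: pd.DataFrame  # family x genome
    clusters: list[OrphanCluster]
    unclassified_ids: list[str]
    genomes: list[str]
    tiers: dict[str, str]

    def branch_counts(self) -> dict[str, int]:
        return {
            "positive": len(self.main),
            "ambiguous": len(self.ambiguous),
            "negative": len(self.negative),
        }

    def outcome_for(self, sequence_id: str) -> DecisionOutcome | None:
        for lst in (self.main, self.ambiguous, self.negative):
            for o in lst:
                if o.sequence_id == sequence_id:
                    return o
        return None

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        def _dump(path, outcomes):
            with open(path, "w") as fh:
                fh.write(
                    "genome\tlocus\tmodel\tverdict\tsdr_type\tfamily_id"
                    "\tmanual_review\tevidence\n"
                )
                for o in outcomes:
                    g, l, m = o.sequence_id.split("|")
                    fh.write(
                        f"{g}\t{l}\t{m}\t{o.verdict}\t{o.sdr_type or '-'}"
                        f"\t{o.family_id or '-'}\t{int(o.manual_review)}"
                        f"\t{'; '.join(o.evidence)}\n"
                    )

        _dump(out / "main_inventory.tsv", self.main)
        _dump(out / "ambiguous.tsv", self.ambiguous)
        self.counts.to_csv(out / "family_counts.tsv", sep="\t", lineterminator="\n")
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("cluster_id\trepresentative\tmean_pairwise_identity\tmembers\n")
            for c in self.clusters:
                mpi = "-" if c.mean_pairwise_identity is None else f"{c.mean_pairwise_identity:.3f}"
                fh.write(
                    f"{c.cluster_id}\t{c.representative_id}\t{mpi}"
                    f"\t{','.join(c.member_ids)}\n"
                )


@dataclass
class InventoryConfig:
    """Thresholds and curated lists steering the decision tree."""

    rescue_window: int = 60
    rescue_min_identity: float = 0.5
    cluster_evalue: float = 1e-40
    evalue_K: float = 0.041
    evalue_lambda: float = 0.267
    whitelist: Mapping[str, str] = field(default_factory=dict)  # seq id -> type
    exclusion: frozenset = frozenset()  # seq ids

    def __post_init__(self):
        if self.rescue_window <= 0 or not 0 <= self.rescue_min_identity <= 1:
            raise ConfigurationError("invalid rescue thresholds")
        if self.cluster_evalue <= 0:
            raise ConfigurationError("cluster E-value threshold must be positive")
        clash = set(self.whitelist) & set(self.exclusion)
        if clash:
            raise ConfigurationError(
                f"ids both whitelisted and excluded: {sorted(clash)}"
            )


# ---------------------------------------------------------------------------
# scanning and the decision tree
# ---------------------------------------------------------------------------


def scan_three_tiers(
    proteome: Mapping[str, str],
    pfam_models: Sequence[ProfileHMM],
    type_models: Sequence[ProfileHMM],
    family_models: Sequence[ProfileHMM],
) -> list[HmmHit]:
    """Score every sequence against every model of the three tiers."""
    if not (pfam_models and type_models and family_models):
        raise InvalidInputError("need at least one model per tier")
    hits: list[HmmHit] = []
    for sid in proteome:
        seq = proteome[sid]
        for tier, models in (
            ("pfam_set", pfam_models),
            ("type_set", type_models),
            ("family_set", family_models),
        ):
            for m in models:
                s = m.score(seq)
                hits.append(
                    HmmHit(
                        sequence_id=sid,
                        model_id=m.model_id,
                        model_class=tier,
                        score=s,
                        passes_cutoff=s >= m.inclusion_cutoff,
                        passes_floor=(
                            m.unknown_floor is not None and s >= m.unknown_floor
                        ),
                    )
                )
    return hits


def _best(hits: Iterable[HmmHit]) -> HmmHit | None:
    """Deterministic best hit: max score, ties by model id."""
    best = None
    for h in hits:
        if best is None or (h.score, h.model_id) > (best.score, best.model_id):
            # note: higher score wins; for equal scores the later model id
            # wins lexicographically, which is fixed and input-order free
            best = h
    return best


def _best_type(hits: list[HmmHit]) -> HmmHit | None:
    """Best type-tier hit; equal scores break by the fixed type order."""
    rank = {t: i for i, t in enumerate(TYPE_ORDER)}
    best = None
    for h in hits:
        key = (-h.score, rank.get(h.model_id, len(TYPE_ORDER)))
        if best is None or key < best[0]:
            best = (key, h)
    return best[1] if best else None


def decide(
    sequence_id: str,
    hits: Sequence[HmmHit],
    cutoffs: TypeCutoffs | None = None,
    whitelist: Mapping[str, str] | None = None,
    exclusion: Iterable[str] = (),
) -> DecisionOutcome:
    """Apply the decision tree to the complete hit table of one sequence.

    The outcome is a pure function of the hit set (passes flags included);
    permuting the hit rows never changes the verdict.
    """
    whitelist = whitelist or {}
    exclusion = set(exclusion)
    clash = set(whitelist) & exclusion
    if clash:
        raise ConfigurationError(f"ids both whitelisted and excluded: {sorted(clash)}")
    hits = [h for h in hits if h.sequence_id == sequence_id]
    fam_hits = [h for h in hits if h.model_class == "family_set"]
    pfam_hits = [h for h in hits if h.model_class == "pfam_set"]
    type_hits = [h for h in hits if h.model_class == "type_set"]

    evidence: list[str] = []
    fam_best = _best([h for h in fam_hits if h.passes_cutoff])
    if fam_best is not None:
        sdr_type = family_type(fam_best.model_id)
        evidence.append(
            f"family-tier pass: {fam_best.model_id} score {fam_best.score:.1f}"
        )
        return DecisionOutcome(sequence_id, "positive", sdr_type,
                               fam_best.model_id, evidence)

    pfam_best = _best([h for h in pfam_hits if h.passes_cutoff])
    pfam_pass = pfam_best is not None
    if pfam_pass:
        evidence.append(
            f"pfam-tier pass: {pfam_best.model_id} score {pfam_best.score:.1f}"
        )
    passing_types = [h for h in type_hits if h.passes_cutoff]
    if pfam_pass and passing_types:
        bt = _best_type(passing_types)
        evidence.append(f"type-tier pass: {bt.model_id} score {bt.score:.1f}")
        return DecisionOutcome(sequence_id, "positive", bt.model_id, None, evidence)

    floor_types = [h for h in type_hits if h.passes_floor]
    if pfam_pass and floor_types:
        bt = _best_type(floor_types)
        evidence.append(
            f"type-tier above unknown floor: {bt.model_id} score {bt.score:.1f}"
        )
        return DecisionOutcome(sequence_id, "positive", "unknown", None, evidence)

    type_recognized = bool(passing_types or floor_types)
    tiers_recognizing = int(pfam_pass) + int(type_recognized)  # family tier was 0
    if tiers_recognizing == 1:
        if type_recognized:
            bt = _best_type(passing_types or floor_types)
            evidence.append(
                f"single-tier recognition: type {bt.model_id} score {bt.score:.1f}"
            )
        else:
            evidence.append("single-tier recognition: pfam tier only")
        if sequence_id in whitelist:
            wl_type = whitelist[sequence_id]
            evidence.append(f"whitelisted with type {wl_type}")
            return DecisionOutcome(sequence_id, "positive", wl_type, None, evidence)
        if sequence_id in exclusion:
            evidence.append("on the exclusion list")
            return DecisionOutcome(sequence_id, "negative", evidence=evidence)
        evidence.append("no structural corroboration: ambiguous")
        return DecisionOutcome(sequence_id, "ambiguous", evidence=evidence)

    return DecisionOutcome(sequence_id, "negative", evidence=[])


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


def select_gene_model(
    models: Mapping[str, str],
    hits: Sequence[HmmHit],
    cross_genome_db: Mapping[str, str] | None = None,
) -> tuple[str, bool]:
    """Pick one gene model per locus.

    Criterion 1 is the maximum best-HMM score; exact score ties fall back to
    the maximum local-alignment score against the other genomes. When the
    HMM winner and the alignment winner disagree, the HMM winner is kept
    provisionally and the locus is flagged for manual review.
    """
    if not models:
        raise InvalidInputError("locus has no gene models")
    ids = sorted(models)
    if len(ids) == 1:
        return ids[0], False
    best_hmm = {
        m: max((h.score for h in hits if h.sequence_id == m), default=float("-inf"))
        for m in ids
    }

    def aln_score(m: str) -> float:
        if not cross_genome_db:
            return 0.0
        return max(
            local_align(models[m], s).score for s in cross_genome_db.values()
        )

    top = max(best_hmm.values())
    tied = [m for m in ids if best_hmm[m] == top]
    if len(tied) > 1:
        hmm_winner = min(tied, key=lambda m: (-aln_score(m), m))
    else:
        hmm_winner = tied[0]
    flag = False
    if cross_genome_db:
        aln_winner = min(ids, key=lambda m: (-aln_score(m), m))
        flag = aln_winner != hmm_winner
    return hmm_winner, flag


@dataclass(frozen=True)
class RescueAssignment:
    sequence_id: str
    homolog_id: str
    sdr_type: str
    family_id: str | None
    alignment_score: float
    segment_identity: float


def _best_window_identity(aln: pairalign.PairwiseAlignment, window: int) -> float:
    """Highest identity over any qualifying window (whole alignment if shorter)."""
    n = aln.aligned_length
    if n == 0:
        return 0.0
    match = [1 if x == y and x != "-" else 0 for x, y in zip(aln.aligned_a, aln.aligned_b)]
    if n < window:
        return sum(match) / n
    best = 0.0
    cur = sum(match[:window])
    best = cur / window
    for s in range(1, n - window + 1):
        cur += match[s + window - 1] - match[s - 1]
        best = max(best, cur / window)
    return best


def rescue_truncated(
    unassigned: Mapping[str, str],
    positives: Sequence[tuple[str, str, str, str | None]],
    window: int = 60,
    min_identity: float = 0.5,
) -> dict[str, RescueAssignment]:
    """Associate HMM-missed sequences with their closest classified homolog.

    ``positives`` rows are (sequence_id, sequence, sdr_type, family_id). For
    each unassigned sequence the closest homolog is the positive with the
    highest local-alignment score (ties by higher segment identity, then
    lexicographic id); the assignment is made only if the alignment shows a
    ``window``-column segment with identity strictly above ``min_identity``.
    """
    out: dict[str, RescueAssignment] = {}
    for sid in unassigned:
        seq = unassigned[sid]
        best_key = None
        best = None
        for pid, pseq, ptype, pfam in positives:
            aln = local_align(seq, pseq)
            if aln.aligned_length == 0:
                continue
            key = (aln.score, _best_window_identity(aln, window), _RevLex(pid))
            if best_key is None or key > best_key:
                best_key = key
                best = (pid, ptype, pfam, aln)
        if best is None:
            continue
        pid, ptype, pfam, aln = best
        if segment_identity_pass(aln, window, min_identity):
            out[sid] = RescueAssignment(
                sid, pid, ptype, pfam, aln.score, _best_window_identity(aln, window)
            )
    return out


class _RevLex(str):
    """Orders lexicographically *smaller* strings as larger keys."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# orphan clustering
# ---------------------------------------------------------------------------


def cluster_orphans(
    orphans: Mapping[str, str],
    evalue_threshold: float = 1e-40,
    K: float = 0.041,
    lam: float = 0.267,
) -> tuple[list[OrphanCluster], list[str]]:
    """Single-linkage families over similarity links at E <= threshold.

    All-vs-all local alignments define edges wherever the Karlin-Altschul
    E-value of the score is at or below the threshold; connected components
    of size >= 2 become new sequence-conservation families, each with a
    representative (lowest mean p-distance to the rest) and a mean pairwise
    identity from a progressive alignment. Unlinked sequences are returned
    as unclassified singletons.
    """
    ids = sorted(orphans)
    n = len(ids)
    if n == 0:
        return [], []
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = orphans[ids[i]], orphans[ids[j]]
            aln = local_align(a, b)
            if aln.score <= 0:
                continue
            e = pairalign.evalue(aln.score, len(a), len(b), K, lam)
            if e <= evalue_threshold:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = connected_components(graph, directed=False)
    clusters: list[OrphanCluster] = []
    unclassified: list[str] = []
    cluster_no = 0
    for comp in range(ncomp):
        member_idx = [i for i in range(n) if labels[i] == comp]
        members = [ids[i] for i in member_idx]
        if len(members) == 1:
            unclassified.append(members[0])
            continue
        cluster_no += 1
        msa = progressive_msa([orphans[m] for m in members], members)
        dm = p_distance(msa)
        vals = dm.values.copy()
        np.fill_diagonal(vals, np.nan)
        with np.errstate(invalid="ignore"):
            mean_d = np.nanmean(vals, axis=1)
        rep = members[int(np.nanargmin(mean_d))]
        mean_ident = float(np.nanmean(1.0 - vals[np.triu_indices(len(members), k=1)]))
        clusters.append(
            OrphanCluster(
                cluster_id=f"NF{cluster_no:02d}",
                member_ids=members,
                representative_id=rep,
                mean_pairwise_identity=mean_ident,
            )
        )
    return clusters, unclassified


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def build_inventory(
    proteins: Sequence[ProteinRecord],
    tiers: Mapping[str, str],
    pfam_models: Sequence[ProfileHMM],
    type_models: Sequence[ProfileHMM],
    family_models: Sequence[ProfileHMM],
    cutoffs: TypeCutoffs | None = None,
    config: InventoryConfig | None = None,
) -> InventoryTable:
    """Run scan -> decide -> gene-model selection -> rescue -> clustering.

    One outcome per locus; the main, ambiguous and negative lists partition
    the loci; per-family per-genome counts are recomputed from the main
    list. Deterministic for fixed inputs.
    """
    config = config or InventoryConfig()
    genomes = sorted({p.genome for p in proteins})
    loci: dict[tuple[str, str], dict[str, ProteinRecord]] = {}
    for p in proteins:
        loci.setdefault((p.genome, p.locus), {})[p.model] = p

    all_seqs = {p.seq_id: p.seq for p in proteins}
    hits = scan_three_tiers(all_seqs, pfam_models, type_models, family_models)
    hits_by_seq: dict[str, list[HmmHit]] = {}
    for h in hits:
        hits_by_seq.setdefault(h.sequence_id, []).append(h)

    # one gene model per locus
    chosen: dict[tuple[str, str], ProteinRecord] = {}
    review_flags: dict[str, bool] = {}
    for (genome, locus), models in sorted(loci.items()):
        if len(models) == 1:
            rec = next(iter(models.values()))
            chosen[(genome, locus)] = rec
            continue
        cross_db = {
            p.seq_id: p.seq
            for p in proteins
            if p.genome != genome and not p.locus.startswith("decoy")
        }
        model_seqs = {m: rec.seq for m, rec in models.items()}
        model_hits = [
            replace(h, sequence_id=m)
            for m, rec in models.items()
            for h in hits_by_seq.get(rec.seq_id, [])
        ]
        winner, flag = select_gene_model(model_seqs, model_hits, cross_db)
        chosen[(genome, locus)] = models[winner]
        review_flags[models[winner].seq_id] = flag

    outcomes: dict[str, DecisionOutcome] = {}
    for key in sorted(chosen):
        rec = chosen[key]
        out = decide(
            rec.seq_id,
            hits_by_seq.get(rec.seq_id, []),
            cutoffs,
            config.whitelist,
            config.exclusion,
        )
        out.manual_review = review_flags.get(rec.seq_id, False)
        outcomes[rec.seq_id] = out

    # rescue: align every non-positive against the classified positives
    positives = [
        (o.sequence_id, all_seqs[o.sequence_id], o.sdr_type, o.family_id)
        for o in outcomes.values()
        if o.verdict == "positive"
    ]
    unassigned = {
        sid: all_seqs[sid]
        for sid, o in outcomes.items()
        if o.verdict != "positive"
    }
    rescued = rescue_truncated(
        unassigned, positives, config.rescue_window, config.rescue_min_identity
    )
    for sid, r in rescued.items():
        o = outcomes[sid]
        o.verdict = "positive"
        o.sdr_type = r.sdr_type
        o.family_id = r.family_id
        o.evidence.append(
            f"rescued via {r.homolog_id}: alignment score {r.alignment_score:.0f},"
            f" best {config.rescue_window}-column identity {r.segment_identity:.2f}"
        )

    # orphan clustering over family-less positives
    orphan_seqs = {
        sid: all_seqs[sid]
        for sid, o in outcomes.items()
        if o.verdict == "positive" and o.family_id is None
    }
    clusters, unclassified = cluster_orphans(
        orphan_seqs, config.cluster_evalue, config.evalue_K, config.evalue_lambda
    )
    for c in clusters:
        c.tiers = {tiers[m.split("|")[0]] for m in c.member_ids if m.split("|")[0] in tiers}
        for m in c.member_ids:
            outcomes[m].family_id = c.cluster_id
            outcomes[m].evidence.append(
                f"orphan cluster {c.cluster_id} (representative {c.representative_id})"
            )
    for sid in unclassified:
        outcomes[sid].evidence.append("orphan: no similarity link, unclassified")

    main = [o for o in outcomes.values() if o.verdict == "positive"]
    ambiguous = [o for o in outcomes.values() if o.verdict == "ambiguous"]
    negative = [o for o in outcomes.values() if o.verdict == "negative"]

    fam_ids = sorted({o.family_id for o in main if o.family_id})
    counts = pd.DataFrame(0, index=fam_ids, columns=genomes, dtype=int)
    for o in main:
        if o.family_id:
            counts.loc[o.family_id, o.sequence_id.split("|")[0]] += 1

    return InventoryTable(
        main=main,
        ambiguous=ambiguous,
        negative=negative,
        counts=counts,
        clusters=clusters,
        unclassified_ids=unclassified,
        genomes=genomes,
        tiers=dict(tiers),
    )
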