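"""Synthetic SDR-like proteomes with known ground truth.

The generator emulates the statistical structure the inventory machinery
assumes, so that every downstream stage (HMM training and scoring, the
decision tree, truncated-protein rescue, orphan clustering, trees, PCA) can
be exercised and validated without any external proteome:

* genomes sit on a taxon hierarchy (alga / bryophyte / lycophyte /
  angiosperm), mirroring the ten-genome design of real plant surveys;
* each family descends from an ancestor sequence carrying SDR-like motifs
  (a Gly-rich cofactor-binding motif and the catalytic S...YxxxK residues);
  families of the same structural type share a type ancestor, emulating the
  common Rossmann core that type-level HMMs exploit;
* members are sampled at a controlled sequence identity to the family
  ancestor using BLOSUM62-conditional substitutions, with motif columns
  mutated at a reduced rate;
* truncated gene models are contiguous fragments (>= 40 residues) of full
  members, so both rescue-pass (>= 60 aligned residues) and rescue-fail
  cases occur;
* decoys are residue-shuffled members (motifs destroyed) plus an optional
  medium-chain-dehydrogenase-like class that shares only the cofactor motif.

Every generated protein has exactly one truth record; identical seeds give
byte-identical output.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AA, BACKGROUND, substitution_conditionals
from .diversify import DistributionMatrix
from .errors import InvalidSpecError
from .io import ProteinRecord
from .profilehmm import SeedAlignment

__all__ = [
    "FamilySpec",
    "TruthRecord",
    "FamilyBuild",
    "SyntheticGenomeSet",
    "DEFAULT_ROSTER",
    "TYPE_SUFFIX",
    "random_ancestor",
    "make_family",
    "make_genome_set",
    "make_expansion_matrix",
    "default_family_specs",
]

#: genome roster modelled on the ten-genome study design
DEFAULT_ROSTER: list[tuple[str, str]] = [
    ("Creinhardtii", "alga"),
    ("Ppatens", "bryophyte"),
    ("Smoellendorffii", "lycophyte"),
    ("Athaliana", "angiosperm"),
    ("Ptrichocarpa", "angiosperm"),
    ("Vvinifera", "angiosperm"),
    ("Gmax", "angiosperm"),
    ("Osativa", "angiosperm"),
    ("Zmays", "angiosperm"),
    ("Sbicolor", "angiosperm"),
]

TIERS = ("alga", "bryophyte", "lycophyte", "angiosperm")

#: nomenclature-style suffix letter per SDR type
TYPE_SUFFIX = {
    "classical": "C",
    "extended": "E",
    "divergent": "D",
    "unknown": "U",
    "atypical": "A",
}

#: classical core ~250 aa; extended types carry an extra ~100-residue
#: C-terminal domain
TYPE_LENGTH = {
    "classical": 250,
    "extended": 350,
    "divergent": 250,
    "unknown": 250,
    "atypical": 250,
}

COFACTOR_MOTIF = "GASRGIG"  # matches the Gly-rich GxxxGxG pattern
COFACTOR_POS = 8
CATALYTIC_RE = re.compile("Y...K")


@dataclass
class FamilySpec:
    """Blueprint of one synthetic family."""

    family_id: str
    sdr_type: str  # classical / extended / divergent / atypical / unknown
    ancestor: str
    target_identity: float
    members_per_genome: Mapping[str, int]
    motif_positions: Sequence[int] = ()


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted protein; decoys carry no family."""

    genome_id: str
    locus_id: str
    model_id: str
    family_id: str | None
    sdr_type: str | None
    truncated: bool
    planted_identity: float

    @property
    def seq_id(self) -> str:
        return f"{self.genome_id}|{self.locus_id}|{self.model_id}"

    @property
    def is_decoy(self) -> bool:
        return self.family_id is None


@dataclass
class FamilyBuild:
    spec: FamilySpec
    seed_alignment: SeedAlignment
    #: genome -> list of (sequence, planted identity)
    members: dict[str, list[tuple[str, float]]]


@dataclass
class SyntheticGenomeSet:
    roster: dict[str, str]  # genome -> tier
    proteins: list[ProteinRecord]
    truth: list[TruthRecord]
    seed_alignments: dict[str, SeedAlignment]
    specs: list[FamilySpec]
    seed: int

    def proteome(self, genome: str) -> dict[str, str]:
        return {p.seq_id: p.seq for p in self.proteins if p.genome == genome}

    def all_sequences(self) -> dict[str, str]:
        return {p.seq_id: p.seq for p in self.proteins}

    def truth_by_seq_id(self) -> dict[str, TruthRecord]:
        return {t.seq_id: t for t in self.truth}

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for genome in self.roster:
            with open(out / f"{genome}.faa", "w") as fh:
                for p in self.proteins:
                    if p.genome == genome:
                        fh.write(f">{p.seq_id}\n{p.seq}\n")
        with open(out / "truth.tsv", "w") as fh:
            fh.write(
                "genome_id\tlocus_id\tmodel_id\tfamily_id\tsdr_type"
                "\ttruncated\tplanted_identity\n"
            )
            for t in self.truth:
                fh.write(
                    f"{t.genome_id}\t{t.locus_id}\t{t.model_id}"
                    f"\t{t.family_id or 'DECOY'}\t{t.sdr_type or '-'}"
                    f"\t{int(t.truncated)}\t{t.planted_identity:.4f}\n"
                )
        for fam, aln in self.seed_alignments.items():
            aln.to_fasta(out / f"{fam}.afa")
            aln.to_stockholm(out / f"{fam}.sto")


# ---------------------------------------------------------------------------
# sequence-level generators
# ---------------------------------------------------------------------------


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_ancestor(length: int, rng) -> tuple[str, list[int]]:
    """Sample an ancestor from background frequencies and plant the motifs.

    Returns the sequence and the motif positions (cofactor-binding Gly motif
    plus the catalytic Ser/Tyr/Lys residues).
    """
    rng = _rng(rng)
    if length < 60:
        raise InvalidSpecError("ancestor too short to carry the motifs")
    core = min(length, 250)  # motifs live in the Rossmann core
    seq = list(rng.choice(list(AA), size=length, p=BACKGROUND))
    motifs: list[int] = []
    for k, ch in enumerate(COFACTOR_MOTIF):
        seq[COFACTOR_POS + k] = ch
        motifs.append(COFACTOR_POS + k)
    cat = int(core * 0.6)
    seq[cat - 14] = "S"
    seq[cat] = "Y"
    seq[cat + 4] = "K"
    motifs += [cat - 14, cat, cat + 4]
    return "".join(seq), motifs


def derive_sequence(
    ancestor: str,
    identity: float,
    rng,
    motif_positions: Sequence[int] = (),
    indel_prob: float = 0.0,
    motif_weight: float = 0.2,
) -> tuple[str, float]:
    """Mutate an ancestor down to a planted identity.

    Exactly ``round((1 - identity) * L)`` positions are substituted, sampled
    with reduced weight at motif positions; replacements are drawn from
    BLOSUM62 conditional probabilities (excluding the original residue).
    With probability ``indel_prob`` a single short indel (1-4 residues) is
    applied afterwards. Returns the sequence and the planted identity.
    """
    rng = _rng(rng)
    L = len(ancestor)
    k = int(round((1.0 - identity) * L))
    seq = list(ancestor)
    if k > 0:
        Q = substitution_conditionals()
        w = np.ones(L)
        for p in motif_positions:
            if p < L:
                w[p] = motif_weight
        pos = rng.choice(L, size=k, replace=False, p=w / w.sum())
        for p in pos:
            a = AA.index(ancestor[p])
            probs = Q[a].copy()
            probs[a] = 0.0
            probs /= probs.sum()
            seq[p] = AA[rng.choice(20, p=probs)]
    if indel_prob > 0 and rng.random() < indel_prob and identity < 1.0:
        ln = int(rng.integers(1, 5))
        if rng.random() < 0.5 and L > 80:
            start = int(rng.integers(0, L - ln))
            del seq[start : start + ln]
        else:
            start = int(rng.integers(0, L))
            ins = rng.choice(list(AA), size=ln, p=BACKGROUND)
            seq[start:start] = list(ins)
    return "".join(seq), (L - k) / L


# ---------------------------------------------------------------------------
# family and genome-set construction
# ---------------------------------------------------------------------------

N_SEEDS = 4
SEED_IDENTITY = 0.70


def make_family(spec: FamilySpec, rng_seed, indel_prob: float = 0.25) -> FamilyBuild:
    """Generate the seed alignment and per-genome members of one family.

    Seeds are sampled without indels at identity ``max(0.70, target)`` to the
    ancestor, so the seed alignment is gap-free; members are sampled at the
    spec's target identity with occasional short indels. A target identity of
    1.0 yields exact copies of the ancestor.
    """
    rng = _rng(rng_seed)
    if not spec.ancestor:
        raise InvalidSpecError(f"{spec.family_id}: empty ancestor")
    if not 0 < spec.target_identity <= 1:
        raise InvalidSpecError(
            f"{spec.family_id}: target_identity {spec.target_identity} not in (0, 1]"
        )
    if any(n < 0 for n in spec.members_per_genome.values()):
        raise InvalidSpecError(f"{spec.family_id}: negative member count")
    seed_identity = max(SEED_IDENTITY, spec.target_identity)
    seed_rows = []
    for i in range(N_SEEDS):
        s, _ = derive_sequence(
            spec.ancestor, seed_identity, rng, spec.motif_positions, indel_prob=0.0
        )
        seed_rows.append(s)
    seed_aln = SeedAlignment(
        [f"{spec.family_id}_seed{i + 1}" for i in range(N_SEEDS)], seed_rows
    )
    members: dict[str, list[tuple[str, float]]] = {}
    for genome in spec.members_per_genome:
        members[genome] = []
        for _ in range(spec.members_per_genome[genome]):
            members[genome].append(
                derive_sequence(
                    spec.ancestor,
                    spec.target_identity,
                    rng,
                    spec.motif_positions,
                    indel_prob=indel_prob,
                )
            )
    return FamilyBuild(spec, seed_aln, members)


def _shuffle_decoy(rng, source: str) -> str:
    """Composition-matched shuffle with the catalytic motif destroyed."""
    for _ in range(20):
        shuffled = "".join(rng.permutation(list(source)))
        if not CATALYTIC_RE.search(shuffled):
            return shuffled
    return shuffled.replace("Y", "A")  # pathological composition; drop tyrosines


def _mdr_like_decoy(rng, length: int = 340) -> str:
    """Medium-chain-dehydrogenase-like decoy: cofactor motif, no catalytic."""
    for _ in range(20):
        seq = list(rng.choice(list(AA), size=length, p=BACKGROUND))
        for k, ch in enumerate(COFACTOR_MOTIF):
            seq[COFACTOR_POS + k] = ch
        s = "".join(seq)
        if not CATALYTIC_RE.search(s):
            return s
    return s


def make_genome_set(
    specs: Sequence[FamilySpec],
    decoy_count: int = 0,
    truncation_rate: float = 0.0,
    multimodel_rate: float = 0.0,
    rng_seed: int = 0,
    roster: Sequence[tuple[str, str]] | None = None,
    indel_prob: float = 0.25,
) -> SyntheticGenomeSet:
    """Emit proteomes, seed alignments and a complete truth table.

    Truncated copies are added as extra loci (contiguous fragments of a full
    member, >= 40 residues); multi-model loci get a second, shorter gene
    model of the same protein; decoys alternate between residue-shuffled
    members and medium-chain-like sequences.
    """
    rng = _rng(rng_seed)
    if not 0 <= truncation_rate <= 1 or not 0 <= multimodel_rate <= 1:
        raise InvalidSpecError("rates must be in [0, 1]")
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise InvalidSpecError("duplicate family_id in specs")
    if roster is None:
        used = {g for s in specs for g in s.members_per_genome}
        roster = [(g, t) for g, t in DEFAULT_ROSTER if g in used] or DEFAULT_ROSTER
    roster_map = dict(roster)
    proteins: list[ProteinRecord] = []
    truth: list[TruthRecord] = []
    seed_alignments: dict[str, SeedAlignment] = {}

    for spec in specs:
        build = make_family(spec, rng, indel_prob=indel_prob)
        seed_alignments[spec.family_id] = build.seed_alignment
        for genome, _tier in roster:
            for n, (seq, ident) in enumerate(build.members.get(genome, []), start=1):
                locus = f"{spec.family_id}_{genome}_{n:03d}"
                proteins.append(ProteinRecord(genome, locus, "m1", seq))
                truth.append(
                    TruthRecord(genome, locus, "m1", spec.family_id, spec.sdr_type,
                                False, ident)
                )
                if multimodel_rate > 0 and rng.random() < multimodel_rate:
                    ln = int(rng.integers(len(seq) // 2, max(len(seq) - 10, len(seq) // 2 + 1)))
                    start = int(rng.integers(0, len(seq) - ln + 1))
                    frag = seq[start : start + ln]
                    proteins.append(ProteinRecord(genome, locus, "m2", frag))
                    truth.append(
                        TruthRecord(genome, locus, "m2", spec.family_id,
                                    spec.sdr_type, True, ident)
                    )
                if truncation_rate > 0 and rng.random() < truncation_rate:
                    hi = max(41, len(seq) - 10)
                    ln = int(rng.integers(40, hi))
                    start = int(rng.integers(0, len(seq) - ln + 1))
                    frag = seq[start : start + ln]
                    tlocus = f"{locus}t"
                    proteins.append(ProteinRecord(genome, tlocus, "m1", frag))
                    truth.append(
                        TruthRecord(genome, tlocus, "m1", spec.family_id,
                                    spec.sdr_type, True, ident)
                    )

    genome_cycle = [g for g, _ in roster]
    members_pool = [t for t in truth if not t.truncated]
    for k in range(decoy_count):
        genome = genome_cycle[k % len(genome_cycle)]
        if k % 2 == 0 and members_pool:
            src = members_pool[int(rng.integers(0, len(members_pool)))]
            seq = _shuffle_decoy(rng, next(p.seq for p in proteins if p.seq_id == src.seq_id))
        else:
            seq = _mdr_like_decoy(rng)
        locus = f"decoy_{k + 1:03d}"
        proteins.append(ProteinRecord(genome, locus, "m1", seq))
        truth.append(TruthRecord(genome, locus, "m1", None, None, False, 0.0))

    return SyntheticGenomeSet(
        roster=roster_map,
        proteins=proteins,
        truth=truth,
        seed_alignments=seed_alignments,
        specs=list(specs),
        seed=rng_seed if isinstance(rng_seed, int) else -1,
    )


def default_family_specs(
    n_families: int,
    rng_seed,
    members_per_genome: int = 3,
    target_identity: float = 0.5,
    roster: Sequence[tuple[str, str]] | None = None,
    absent_tiers: Mapping[str, set[str]] | None = None,
    type_cycle: Sequence[str] = ("classical", "classical", "extended", "divergent", "unknown"),
) -> list[FamilySpec]:
    """Build a realistic family roster sharing per-type ancestors.

    Families cycle through SDR types; families of one type derive their
    ancestors from a common type ancestor at ~0.55 identity, which gives
    type- and broad-tier models a shared core to learn while keeping family
    models discriminative. Family ids carry the nomenclature-style type
    suffix (e.g. ``SYN03E``).
    """
    rng = _rng(rng_seed)
    if roster is None:
        roster = DEFAULT_ROSTER
    absent_tiers = absent_tiers or {}
    type_anc: dict[str, tuple[str, list[int]]] = {}
    specs = []
    for i in range(n_families):
        sdr_type = type_cycle[i % len(type_cycle)]
        if sdr_type not in type_anc:
            type_anc[sdr_type] = random_ancestor(TYPE_LENGTH[sdr_type], rng)
        anc_seq, motifs = type_anc[sdr_type]
        fam_anc, _ = derive_sequence(anc_seq, 0.55, rng, motifs, indel_prob=0.0)
        fam_id = f"SYN{i + 1:02d}{TYPE_SUFFIX[sdr_type]}"
        absent = absent_tiers.get(fam_id, set())
        mpg = {
            g: (0 if t in absent else members_per_genome)
            for g, t in roster
        }
        specs.append(
            FamilySpec(
                family_id=fam_id,
                sdr_type=sdr_type,
                ancestor=fam_anc,
                target_identity=target_identity,
                members_per_genome=mpg,
                motif_positions=motifs,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# expansion (distribution) matrix generator
# ---------------------------------------------------------------------------

#: mean member count of a diversified family per taxon tier; the increase
#: toward angiosperms emulates the expansion of secondary-metabolism families
DIVERSIFIED_TIER_MEAN = {"alga": 2.0, "bryophyte": 5.0, "lycophyte": 15.0, "angiosperm": 30.0}


def make_expansion_matrix(
    n_families: int,
    n_genomes: int,
    diversified_ids: set[str] | Sequence[str] = (),
    rng_seed: int = 0,
) -> DistributionMatrix:
    """Family-by-genome count matrix with planted diversified families.

    Background families hold a small near-constant count everywhere;
    diversified families draw Poisson counts whose mean (hence variance)
    grows toward the angiosperm tier.
    """
    rng = _rng(rng_seed)
    if n_families <= 1:
        raise InvalidSpecError("need at least 2 families")
    if n_genomes < 1:
        raise InvalidSpecError("need at least 1 genome")
    families = [f"F{i + 1:02d}" for i in range(n_families)]
    genomes = [f"G{j + 1:02d}" for j in range(n_genomes)]
    tier_order = ["alga", "bryophyte", "lycophyte"]
    tiers = {
        g: (tier_order[j] if j < len(tier_order) else "angiosperm")
        for j, g in enumerate(genomes)
    }
    diversified = set(diversified_ids)
    unknown = diversified - set(families)
    if unknown:
        raise InvalidSpecError(f"diversified ids not among families: {sorted(unknown)}")
    counts = np.zeros((n_families, n_genomes), dtype=int)
    for i, fam in enumerate(families):
        for j, g in enumerate(genomes):
            if fam in diversified:
                counts[i, j] = rng.poisson(DIVERSIFIED_TIER_MEAN[tiers[g]])
            else:
                counts[i, j] = 1 + rng.poisson(0.5)
    import pandas as pd

    df = pd.DataFrame(counts, index=families, columns=genomes)
    return DistributionMatrix(df, tiers)
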