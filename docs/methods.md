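# Methods

## Profile HMM architecture and scoring

Each model is a linear chain of `M` match states estimated from a seed
alignment. Columns whose gap fraction is strictly below `gap_threshold`
(default 0.5; a column exactly at the threshold is excluded) become match
states. Match emissions are observed residue counts (uniform sequence
weights) smoothed with a substitution-mixture pseudocount of total weight
1: the mixture is the observed column distribution pushed through BLOSUM62
conditional substitution probabilities, which keeps small seed sets from
collapsing onto their literal residues. Transitions are estimated from the
observed per-row state paths with add-one (Laplace) smoothing;
insert→delete adjacencies, which have no profile transition, are dropped.

Scoring is local Viterbi log-odds in bits against a fixed background
distribution (standard BLOSUM62 marginal frequencies): alignment may enter
any match state (uniform entry probability `1/M`), exit early from any
match state with a fixed probability of 0.01 (the last match state and the
terminal delete state exit freely), insert states emit background at zero
log-odds, and residues outside the aligned core are free. Residues outside
the 20-letter alphabet (X, B, Z, ...) are emitted as background and
contribute zero. The local parameterization is what lets truncated gene
models score; a glocal model would zero them out. Viterbi (best path)
rather than forward defines the reported score: the decision tree
thresholds on scores, which is insensitive to that choice at the margins
used, and the best-path score has an exact brute-force enumeration oracle
(`tests/oracles.py`) that the implementation is checked against on random
small models.

The model text format serializes all probabilities as C99 hex float
literals, so write→read round trips are bit-exact.

## Cutoff calibration

The published type-model thresholds (classical 138, extended 108,
intermediate 162, divergent 160, complex 140 bits; unknown floors 29, 75
and 100 bits for classical/extended/divergent) are the package defaults in
`TypeCutoffs`, with the plant configuration dropping the intermediate and
complex types, which do not occur in plants. Those constants belong to the
original model library; synthetic stand-in models need their own
calibration, implemented as `calibrate_cutoff`: the cutoff is
`min(positive scores) − margin`, floored just above the best decoy score,
and calibration fails loudly when the two ranges overlap.

What the calibration positives should be differs by tier, and the choice
was made from measured score distributions on the generator's conditions:

* **Family tier.** Raw seeds (~0.7 identity to the family ancestor) score
  several hundred bits above genuine remote members (~0.5 identity), so
  seeds make useless calibration positives. Instead each seed is degraded
  to 0.55 residual identity (≈37–40% to the family consensus, the bottom
  of the published within-family identity range) and the margin is 40
  bits, which absorbs the score variance of genuine members around the
  simulated ones. Cross-family seeds are included among the decoys, so
  between-family discrimination is part of the calibration contract.
  The resulting cutoffs land between the remote-member score regime and
  the cross-family noise floor (roughly 30–110 bits on the synthetic
  models).
* **Type and broad tiers.** Pooled multi-family models have diffuse
  emissions; at member-level divergence their score distributions for
  same-type and other-type sequences overlap, so no member-sensitive
  cutoff exists. These tiers are therefore calibrated on the seeds
  themselves with a 50-bit margin: they make confident calls near
  seed-level identity, and sensitivity to remote or truncated members is
  deliberately left to the family tier and the rescue stage. Unknown
  floors sit 30 bits under the calibrated cutoff (clamped above the decoy
  maximum).

## Decision tree

Rule order for a sequence's complete hit table: (1) family-tier pass ⇒
positive, type from the family suffix (C/E/D/U/A); (2) broad-tier pass and
type-tier pass ⇒ positive with the best passing type (equal scores break
classical > extended > divergent); (3) broad-tier pass and best type score
at or above its unknown floor ⇒ positive, type *unknown*; (4) exactly one
tier recognizes the sequence ⇒ deferred — whitelist entries become
positive with their declared type (the hook for structure-backed families
such as the atypical PLR/IFR group), exclusion entries become negative
(the hook for structurally distinct look-alikes such as medium-chain
dehydrogenases), the rest is ambiguous; (5) no recognition ⇒ negative.
Step (3) deliberately requires broad-tier corroboration: a lone above-floor
type hit goes to step (4), since floors alone are only safe for sequences
otherwise recognized. All tie-breaks are deterministic (score, then
segment identity, then lexicographic id), so permuting hit-table rows
never changes an outcome.

Gene-model selection keeps, per locus, the model with the best HMM score;
exact ties fall to the best local-alignment score against the other
genomes; when the HMM winner and the alignment winner disagree the HMM
winner is kept and the locus is flagged `manual-review` rather than
silently resolved.

Truncation rescue aligns every non-positive sequence against all
positives (Smith–Waterman, BLOSUM62, gap open 11 / extend 1) and inherits
the type and family of the closest homolog — highest score, ties by best
60-column window identity, then id — provided the alignment contains a
window of exactly 60 columns (no dual-gap columns) with strictly more than
50% identity. "Strictly more" makes 30/60 fail and 31/60 pass, and a
59-column perfect alignment fails for want of a full window; these
boundaries are pinned by tests. The 60-column reading of the rule (rather
than identity over the whole alignment) is this package's interpretation
of an ambiguous published criterion.

Orphan clustering links family-less positives whose pairwise
Karlin–Altschul E-value (`E = K·m·n·e^{−λS}`, K = 0.041, λ = 0.267 — the
conventional gapped BLOSUM62 parameters) is at most 1e-40, takes
single-linkage components of size ≥ 2 as new sequence-conservation
families, computes each cluster's mean pairwise identity from a
progressive alignment, and picks the representative with the lowest mean
p-distance to the rest. The E-value formula is a thresholding device, not
an attempt to reproduce any specific search tool's statistics.

## Alignments and distances

Pairwise local alignment is Biopython's `PairwiseAligner` (affine
Smith–Waterman) under the convention that a gap of length *k* costs
`open + k·extend` (defaults 11/1); scores are checked against an
exhaustive enumeration oracle. Among co-optimal alignments the first in
Biopython's deterministic traceback order is used; every downstream
decision consumes only the score, window identities and column sets, which
are far less tie-sensitive than the exact traceback.

The progressive multiple aligner builds an average-linkage guide tree from
pairwise distances (1 − local-alignment identity, via
`scipy.cluster.hierarchy`) and merges profiles leaf-to-root with
affine-gap profile–profile alignment (column score = frequency-weighted
expected BLOSUM62 score; gaps contribute no mass). Children are merged in
canonical order (smallest member id first) so column content is invariant
to input permutation; rows return in input order. It is a simple
progressive scheme in the ClustalW mould, not a clone of any tool.

p-distances use pairwise deletion — only columns where both rows carry a
residue are compared — and a pair with no comparable column is undefined
(NaN, exported as `NA`). Poisson correction `d = −ln(1−p)` (substitutions
per site) errors at p = 1 rather than capping; tree building refuses
undefined or saturated inputs explicitly because silent imputation or
capping distorts topology.

## Trees and bootstrap

Neighbor joining is the standard Q-matrix agglomeration with ties broken
on the smallest index pair. Negative branch-length estimates are clamped
to zero with the deficit moved to the sister branch, preserving the sibling
sum. On additive inputs the output path lengths reproduce the matrix to
1e-9 (verified on 1000 random 5–8-leaf trees; topology cross-checked
against dendropy's NJ). Bootstrap resamples alignment columns with
replacement (500 replicates by default, fixed-seed deterministic),
rebuilds distances and the NJ tree per replicate, and reports integer
percentages per internal bipartition of the original tree; replicates with
undefined or saturated distances are skipped and tallied on the result.

## Distribution matrix, occurrence, PCA

The distribution matrix counts main-list members per family and genome.
Occurrence classes walk the taxon hierarchy outward: presence (count > 0
in ≥1 genome of a tier) in the alga tier ⇒ ViridP, else bryophyte ⇒ LandP,
else lycophyte ⇒ TracheoP, else FlowerP; an all-zero family row is an
error. Families whose algal presence is established from algae outside the
analysed set are handled by an explicit starred-override list, never
computed.

PCA is a plain SVD of the column-centered count matrix with families as
individuals and genomes as variables, unscaled by default (the centering
and scaling choice is recorded in the result for transparency); axes are
ordered by decreasing variance, each axis's sign is fixed so its
largest-magnitude loading is positive, and variance fractions are
percentages over all axes (they sum to 100). The robustness check removes
the family with the largest centered row norm, reruns the PCA, and reports
the Spearman concordance of first-axis scores over the shared families.
scikit-learn's PCA serves as an independent cross-check in the tests, not
as the implementation.

## Synthetic data: what it emulates and what it does not

`synthfam` plants families whose ancestors carry the SDR motifs (Gly-rich
cofactor motif `GASRGIG` at a fixed N-terminal position; catalytic Ser/
Tyr/Lys with the `YxxxK` spacing): classical-type ancestors are 250
residues, extended-type 350 (the extra C-terminal domain). Families of one
structural type descend from a shared type ancestor at 0.55 identity,
emulating the common Rossmann core that type-level models exploit; seeds
are drawn at 0.70 identity to the family ancestor without indels (so seed
alignments are trivially gap-free), members at the spec'd target identity
with BLOSUM62-conditional substitutions, motif positions mutated at 0.2×
weight, and occasional short indels (one 1–4-residue event per member with
probability 0.25). Substitution counts are exact, so the planted identity
is exact before indels; measured local-alignment identity tracks the
target within ±0.05. Truncated loci are uniform contiguous windows of ≥40
residues of a full member, giving both rescue-pass (≥60 residues) and
rescue-fail cases; multi-model loci add a shorter second gene model;
decoys alternate residue-shuffled members (catalytic motif destroyed,
composition preserved) and medium-chain-like sequences sharing only the
cofactor motif. The expansion-matrix generator draws background family
counts near a small constant (1 + Poisson(0.5)) and diversified-family
counts from Poisson means rising over the tiers (alga 2, bryophyte 5,
lycophyte 15, angiosperm 30), so mean and variance grow toward the
angiosperms.

The generator does **not** emulate: nucleotide sequences or gene
structure, chromosomal clustering of paralogs, real domain architectures
(the extended domain is plain extra sequence, not a structured domain),
compositional bias, annotation noise other than truncation, or the actual
sequence content of any real family. Passing tests therefore demonstrate
that the machinery is correct and well-calibrated on data satisfying its
own assumptions — not that the published ten-genome inventory would be
reproduced; the published accession-level results require the original
proteomes and model libraries, which are out of scope.

## Problem sizes and reproducibility

The end-to-end validation cohort is 10 families over 4 genomes (one per
taxon tier), 3 members per genome at 0.5 target identity, 20 decoys, 10%
truncation and multi-model rates — roughly 140 proteins against 17
models, which keeps a full pipeline run around a minute on one CPU while
leaving every decision path exercised. The expansion-matrix analysis uses
49 families × 10 genomes with 5 diversified families, matching the scale
of the published family set. All randomness flows through
`numpy.random.default_rng` seeds carried in configuration; identical seeds
give byte-identical FASTA, truth tables, trees and matrices.

## Known limitations

* Family cutoff calibration assumes the calibration-identity/margin pair
  matches the divergence regime of the data; families far more divergent
  than ~0.45 identity to their ancestor will lose members to the rescue
  stage or the orphan clusters.
* The type tier is calibrated for precision near seed-level identity and
  contributes little sensitivity; on real data the published cutoffs
  should be used with the original model library instead.
* Orphan-cluster E-values come from a fixed Karlin–Altschul
  parameterization, so absolute agreement with any specific search tool's
  E-values is not expected; only the thresholding behavior is meaningful.
* The progressive aligner is quadratic all-vs-all at the guide-tree step
  and intended for family-sized inputs (tens of sequences), not
  genome-scale search.
* Maximum-likelihood tree inference, E-value calibration for HMM bit
  scores, and automated literature curation (the real whitelist content)
  are out of scope.
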