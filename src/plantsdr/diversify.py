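"""Family-by-genome distribution analyses: occurrence classes, heat map, PCA.

Given the classified inventory, this module builds the family x genome count
matrix, assigns each family an occurrence class over the taxon hierarchy
(ViridP: present down to the algae; LandP: land plants; TracheoP: vascular
plants; FlowerP: angiosperms only), exports the matrix as TSV/heat map, and
decomposes it by PCA with families as individuals and genomes as variables.
The PCA separates the handful of strongly diversified families (large,
variable member counts, expanded toward vascular plants) from the quiet
majority; its robustness is checked by re-running after removal of the most
extreme family.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import (
    DegenerateVarianceError,
    EmptyFamilyError,
    InvalidInputError,
)

__all__ = [
    "DistributionMatrix",
    "OccurrenceLabel",
    "PcaResult",
    "PcaRobustness",
    "distribution_matrix",
    "assign_occurrence",
    "pca",
    "pca_robustness",
    "heatmap_export",
]

TIER_ORDER = ("alga", "bryophyte", "lycophyte", "angiosperm")
TIER_LABEL = {
    "alga": "ViridP",
    "bryophyte": "LandP",
    "lycophyte": "TracheoP",
    "angiosperm": "FlowerP",
}


@dataclass
class DistributionMatrix:
    """Nonnegative integer counts, families as rows, genomes as columns."""

    counts: pd.DataFrame
    tiers: Mapping[str, str]  # genome -> taxon tier

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise InvalidInputError("duplicate family or genome ids")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("counts must be nonnegative")
        missing = [g for g in self.counts.columns if g not in self.tiers]
        if missing:
            raise InvalidInputError(f"genomes without taxon tier: {missing}")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, tiers: Mapping[str, str]) -> "DistributionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, tiers)


@dataclass(frozen=True)
class OccurrenceLabel:
    family_id: str
    label: str  # ViridP / LandP / TracheoP / FlowerP
    starred: bool = False  # algal presence inferred from other algae


@dataclass
class PcaResult:
    scores: pd.DataFrame  # families x axes
    loadings: pd.DataFrame  # genomes x axes
    variance_pct: np.ndarray  # per axis, sums to 100 over all axes
    centering: dict


@dataclass
class PcaRobustness:
    full: PcaResult
    reduced: PcaResult
    removed_family: str
    rank_concordance: float


def distribution_matrix(inv) -> DistributionMatrix:
    """Count main-list members per (family, genome) from an inventory."""
    rows: dict[str, dict[str, int]] = {}
    genomes = list(inv.genomes)
    for out in inv.main:
        if out.family_id is None:
            continue
        genome = out.sequence_id.split("|")[0]
        rows.setdefault(out.family_id, {g: 0 for g in genomes})
        rows[out.family_id][genome] = rows[out.family_id].get(genome, 0) + 1
    fam_ids = sorted(rows)
    df = pd.DataFrame(
        [[rows[f].get(g, 0) for g in genomes] for f in fam_ids],
        index=fam_ids,
        columns=genomes,
        dtype=int,
    )
    return DistributionMatrix(df, dict(inv.tiers))


def assign_occurrence(
    m: DistributionMatrix,
    starred_overrides: Sequence[str] = (),
) -> list[OccurrenceLabel]:
    """Label every family by the deepest taxon tier it reaches.

    Present in the alga tier => ViridP; else in the bryophyte tier => LandP;
    else in the lycophyte tier => TracheoP; else FlowerP. "Present" means a
    count > 0 in at least one genome of the tier. Families in
    ``starred_overrides`` are forced to ViridP with the starred flag — the
    hook for presence established from algae outside the analysed set.
    """
    tier_cols = {t: [g for g in m.counts.columns if m.tiers[g] == t] for t in TIER_ORDER}
    labels = []
    starred = set(starred_overrides)
    for fam, row in m.counts.iterrows():
        if row.sum() == 0:
            raise EmptyFamilyError(f"family {fam} has an all-zero row")
        if fam in starred:
            labels.append(OccurrenceLabel(fam, "ViridP", True))
            continue
        for tier in TIER_ORDER:
            cols = tier_cols[tier]
            if cols and row[cols].sum() > 0:
                labels.append(OccurrenceLabel(fam, TIER_LABEL[tier]))
                break
    return labels


def pca(m: DistributionMatrix, center: bool = True, scale: bool = False) -> PcaResult:
    """Principal components of the count matrix, families as individuals.

    Plain SVD of the (column-centered, optionally unit-variance-scaled)
    matrix; axes ordered by decreasing variance; the sign of each axis is
    fixed so that the largest-magnitude loading entry is positive. Variance
    fractions are percentages over all axes and sum to 100.
    """
    X = m.counts.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise InvalidInputError("PCA needs at least 2 families and 2 genomes")
    mu = X.mean(axis=0)
    if center:
        X = X - mu
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise DegenerateVarianceError("a genome column has zero variance")
        X = X / sd
    if not np.any(X != X.mean()):
        raise DegenerateVarianceError("matrix is constant")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S.max() <= 1e-12:
        raise DegenerateVarianceError("matrix has no variance")
    # canonical sign: largest-|loading| entry of each axis is positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2
    var_pct = 100.0 * var / var.sum()
    axes = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=m.counts.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=m.counts.columns, columns=axes)
    return PcaResult(
        scores, loadings, var_pct,
        {"center": center, "scale": scale, "column_means": mu,
         "column_sd": sd},
    )


def pca_robustness(m: DistributionMatrix, center: bool = True,
                   scale: bool = False) -> PcaRobustness:
    """PCA with and without the most extreme family.

    The extreme individual is the family with the largest centered row norm.
    Concordance is the Spearman correlation of first-axis scores over the
    shared families.
    """
    if m.counts.shape[0] < 3:
        raise InvalidInputError("need at least 3 families")
    full = pca(m, center=center, scale=scale)
    X = m.counts.to_numpy(dtype=float)
    norms = np.linalg.norm(X - X.mean(axis=0), axis=1)
    removed = m.counts.index[int(np.argmax(norms))]
    reduced_m = DistributionMatrix(m.counts.drop(index=removed), m.tiers)
    reduced = pca(reduced_m, center=center, scale=scale)
    shared = reduced.scores.index
    rho = spearmanr(
        full.scores.loc[shared, "PC1"], reduced.scores["PC1"]
    ).statistic
    return PcaRobustness(full, reduced, str(removed), float(rho))


def heatmap_export(m: DistributionMatrix, prefix) -> list[str]:
    """Write the matrix as TSV plus a blue-to-red heat map (zeros in white).

    The TSV is the contract (byte-deterministic, round-trips exactly); the
    image is best-effort.
    """
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    m.to_tsv(tsv)
    written = [str(tsv)]
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        X = m.counts.to_numpy(dtype=float)
        masked = np.ma.masked_where(X == 0, X)
        cmap = plt.get_cmap("coolwarm").copy()
        cmap.set_bad("white")
        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * X.shape[1] + 2), max(4, 0.18 * X.shape[0] + 1))
        )
        im = ax.pcolormesh(masked, cmap=cmap)
        ax.set_xticks(np.arange(X.shape[1]) + 0.5, m.counts.columns, rotation=90)
        ax.set_yticks(np.arange(X.shape[0]) + 0.5, m.counts.index, fontsize=5)
        ax.invert_yaxis()
        fig.colorbar(im, ax=ax, label="members per genome")
        fig.tight_layout()
        png = prefix.with_suffix(".png")
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(str(png))
    except Exception:  # pragma: no cover - image is best-effort
        pass
    return written
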