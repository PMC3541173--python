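"""Published summary tables of the genome-wide plant SDR inventory.

Two in-text summaries of the published ten-genome survey are shipped as
reference points for consistency checks: the per-genome distribution of SDR
types, and the family classification (nomenclature family or
sequence-conservation cluster, occurrence class, average within-family
identity). Occurrence labels are stored as printed; starred entries mark
families whose algal occurrence was established from green algae outside
the analysed set. These tables are *reference data*, not pipeline output.
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TYPE_DISTRIBUTION",
    "FAMILY_CLASSIFICATION",
    "FamilyEntry",
    "genome_type_totals",
    "family_counts",
    "occurrence_counts",
]

#: per-genome SDR counts by type: (classical, divergent, extended,
#: atypical, unknown)
TYPE_DISTRIBUTION: dict[str, tuple[int, int, int, int, int]] = {
    "Arabidopsis": (90, 1, 72, 8, 7),
    "Poplar": (122, 4, 106, 16, 20),
    "Grapevine": (95, 2, 88, 14, 6),
    "Soybean": (145, 4, 138, 15, 13),
    "Rice": (110, 2, 95, 10, 10),
    "Maize": (97, 3, 113, 7, 10),
    "Sorghum": (106, 2, 114, 7, 8),
    "Selaginella": (64, 1, 55, 5, 17),
    "Physcomitrella": (59, 2, 55, 0, 10),
    "Chlamydomonas": (41, 1, 21, 1, 4),
}


@dataclass(frozen=True)
class FamilyEntry:
    representative_gene: str
    family_id: str | None  # None: cluster defined by sequence conservation only
    occurrence: str  # ViridP / LandP / TracheoP / FlowerP
    starred: bool
    avg_identity_pct: float


FAMILY_CLASSIFICATION: list[FamilyEntry] = [
    FamilyEntry("AT4G23420", "SDR7C", "ViridP", False, 49.4),
    FamilyEntry("AT1G67730", "SDR12C", "LandP", False, 48.4),
    FamilyEntry("AT3G12800", "SDR17C", "ViridP", False, 64.1),
    FamilyEntry("AT4G05530", "SDR25C", "ViridP", False, 67.7),
    FamilyEntry("AT3G03330", "SDR34C", "ViridP", False, 56.1),
    FamilyEntry("AT3G06060", "SDR35C", "ViridP", False, 47.9),
    FamilyEntry("AT4G09750", "SDR40C", "ViridP", True, 70.8),
    FamilyEntry("AT1G54870", "SDR57C", "ViridP", False, 58.0),
    FamilyEntry("AT5G06060", "SDR65C", "ViridP", False, 53.3),
    FamilyEntry("AT3G03980", "SDR68C", "TracheoP", False, 57.0),
    FamilyEntry("AT5G54190", "SDR73C", "ViridP", False, 74.5),
    FamilyEntry("AT3G50560", "SDR84C", "ViridP", False, 60.4),
    FamilyEntry("AT1G52340", "SDR110C", "LandP", False, 47.1),
    FamilyEntry("AT3G61220", "SDR114C", "ViridP", False, 45.4),
    FamilyEntry("AT5G50600", "SDR119C", "LandP", False, 44.4),
    FamilyEntry("AT3G55290", "SDR132C", "ViridP", False, 62.4),
    FamilyEntry("AT1G24360", "SDR152C", "ViridP", False, 68.3),
    FamilyEntry("AT1G10310", "SDR357C", "TracheoP", False, 70.0),
    FamilyEntry("AT5G10050", "SDR368C", "ViridP", False, 45.8),
    FamilyEntry("AT4G27760", "SDR369C", "ViridP", False, 57.2),
    FamilyEntry("AT2G05990", "SDR87D", "ViridP", False, 75.0),
    FamilyEntry("AT1G49670", None, "ViridP", False, 50.6),
    FamilyEntry("AT3G01980", None, "LandP", False, 57.8),
    FamilyEntry("AT4G13250", None, "ViridP", False, 48.1),
    FamilyEntry("AT4G20760", None, "ViridP", False, 61.8),
    FamilyEntry("AT5G04070", None, "LandP", False, 52.7),
    FamilyEntry("AT4G10960", "SDR1E", "ViridP", False, 55.4),
    FamilyEntry("AT1G78570", "SDR2E", "ViridP", False, 74.7),
    FamilyEntry("AT5G66280", "SDR3E", "LandP", False, 72.3),
    FamilyEntry("AT1G17890", "SDR4E", "LandP", False, 73.1),
    FamilyEntry("AT2G28760", "SDR6E", "ViridP", False, 69.7),
    FamilyEntry("AT2G20360", "SDR22E", "ViridP", False, 60.1),
    FamilyEntry("AT1G47290", "SDR31E", "ViridP", False, 48.2),
    FamilyEntry("AT2G33630", "SDR42E", "ViridP", True, 66.2),
    FamilyEntry("AT4G30440", "SDR50E", "ViridP", False, 61.3),
    FamilyEntry("AT4G33030", "SDR52E", "ViridP", False, 73.8),
    FamilyEntry("AT1G08200", "SDR67E", "LandP", False, 81.9),
    FamilyEntry("AT5G28840", "SDR93E", "ViridP", False, 87.4),
    FamilyEntry("AT5G42800", "SDR108E", "ViridP", False, 36.6),
    FamilyEntry("GRMZM2G086773", "SDR115E", "FlowerP", False, 55.0),
    FamilyEntry("AT5G22500", "SDR117E", "LandP", False, 46.8),
    FamilyEntry("AT4G24220", "SDR75U", "LandP", False, 53.4),
    FamilyEntry("AT4G35250", "SDR81U", "ViridP", False, 76.4),
    FamilyEntry("AT1G09340", "SDR83U", "ViridP", False, 50.7),
    FamilyEntry("AT5G18660", "SDR98U", "ViridP", False, 62.5),
    FamilyEntry("AT5G02240", "SDR358U", "ViridP", True, 68.9),
    FamilyEntry("AT1G32100", "SDR460A", "TracheoP", False, 45.3),
    FamilyEntry("AT4G33360", None, "LandP", False, 63.2),
    FamilyEntry("AT4G00560", None, "ViridP", False, 56.5),
]


def genome_type_totals() -> dict[str, int]:
    """Total SDRs per genome, recomputed by summing the per-type counts."""
    return {g: sum(v) for g, v in TYPE_DISTRIBUTION.items()}


def family_counts() -> tuple[int, int, int]:
    """(total families, families with a nomenclature HMM, sequence-only)."""
    total = len(FAMILY_CLASSIFICATION)
    with_hmm = sum(1 for f in FAMILY_CLASSIFICATION if f.family_id is not None)
    return total, with_hmm, total - with_hmm


def occurrence_counts() -> dict[str, int]:
    out: dict[str, int] = {}
    for f in FAMILY_CLASSIFICATION:
        out[f.occurrence] = out.get(f.occurrence, 0) + 1
    return out
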