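"""Shared study conditions for the numbered analysis scripts.

One synthetic cohort stands in for the ten published proteomes: ten SDR
families over the four taxon tiers (alga, moss, lycophyte, angiosperm),
three members per genome at 0.5 identity to each family ancestor, with two
families absent from the algae (land-plant families), one restricted to
the angiosperm tier, plus 20 decoys, 10% truncated loci and 10%
multi-model loci. Seeds are fixed so every script sees the same cohort.
"""
from pathlib import Path

from plantsdr.synthfam import DEFAULT_ROSTER, default_family_specs, make_genome_set

SEED = 2012
ROSTER = DEFAULT_ROSTER[:4]
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = RESULTS / "data"
ABSENT_TIERS = {
    "SYN03E": {"alga"},            # a land-plant family
    "SYN05U": {"alga", "bryophyte"},  # vascular-plant family
    "SYN08E": {"alga", "bryophyte", "lycophyte"},  # angiosperm-only family
}


def build_cohort():
    specs = default_family_specs(
        10, rng_seed=SEED, members_per_genome=3, target_identity=0.5,
        roster=ROSTER, absent_tiers=ABSENT_TIERS,
    )
    return make_genome_set(
        specs, decoy_count=20, truncation_rate=0.10, multimodel_rate=0.10,
        rng_seed=SEED + 1, roster=ROSTER,
    )
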