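import numpy as np
import pytest

from plantsdr.synthfam import DEFAULT_ROSTER, default_family_specs, make_genome_set
from plantsdr.workflow import evaluate_against_truth, run_inventory

#: study conditions of the end-to-end recovery check: 10 families over 4
#: genomes (one per taxon tier), 3 members per genome at 0.5 identity to the
#: family ancestor, 10% truncations, 10% multi-model loci, 20 decoys
E2E = dict(
    n_families=10,
    members_per_genome=3,
    target_identity=0.5,
    decoy_count=20,
    truncation_rate=0.10,
    multimodel_rate=0.10,
)


def build_e2e(seed: int):
    roster = DEFAULT_ROSTER[:4]
    specs = default_family_specs(
        E2E["n_families"],
        rng_seed=seed,
        members_per_genome=E2E["members_per_genome"],
        target_identity=E2E["target_identity"],
        roster=roster,
    )
    gs = make_genome_set(
        specs,
        decoy_count=E2E["decoy_count"],
        truncation_rate=E2E["truncation_rate"],
        multimodel_rate=E2E["multimodel_rate"],
        rng_seed=seed + 1,
        roster=roster,
    )
    inv, models = run_inventory(gs, rng_seed=seed + 2)
    report = evaluate_against_truth(inv, gs.truth, gs.all_sequences())
    return gs, inv, models, report


@pytest.fixture(scope="session")
def e2e_result():
    """One full pipeline run on the synthetic study conditions."""
    return build_e2e(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
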