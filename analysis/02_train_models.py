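"""Train and calibrate the three HMM tiers from the cohort's seed alignments.

Reads the seed alignments written by 01_simulate.py, trains family-, type-
and broad-tier profile HMMs, calibrates their inclusion cutoffs, and writes
the models in the package's plain-text profile format under results/models/.
"""
import json

from common import DATA_DIR, RESULTS, SEED

from plantsdr.profilehmm import SeedAlignment, write_profile
from plantsdr.workflow import train_model_set


def main():
    alns = {
        p.stem: SeedAlignment.from_file(p) for p in sorted(DATA_DIR.glob("*.afa"))
    }
    ms = train_model_set(alns, rng_seed=SEED + 2)
    outdir = RESULTS / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    for m in ms.pfam_models + ms.type_models + ms.family_models:
        write_profile(m, outdir / f"{m.model_id}.phmm")
    with open(outdir / "cutoffs.json", "w") as fh:
        json.dump(
            {
                "type_inclusion": ms.cutoffs.inclusion,
                "unknown_floors": ms.cutoffs.unknown_floor,
                "family_cutoffs": {
                    m.model_id: m.inclusion_cutoff for m in ms.family_models
                },
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    print(f"trained {len(ms.family_models)} family models, "
          f"{len(ms.type_models)} type models, {len(ms.pfam_models)} broad models")
    print("calibrated type cutoffs (bits):",
          {k: round(v, 1) for k, v in ms.cutoffs.inclusion.items()})
    print(f"profiles written to {outdir}")


if __name__ == "__main__":
    main()
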