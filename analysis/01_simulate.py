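"""Generate the synthetic cohort: proteomes, seed alignments, truth table.

Writes one amino-acid FASTA per genome (headers genome|locus|model), the
per-family seed alignments (aligned FASTA + Stockholm) and the complete
truth table under results/data/.
"""
from common import DATA_DIR, build_cohort


def main():
    gs = build_cohort()
    gs.write(DATA_DIR)
    decoys = sum(t.is_decoy for t in gs.truth)
    trunc = sum(t.truncated for t in gs.truth)
    print(f"cohort: {len(gs.proteins)} proteins over {len(gs.roster)} genomes")
    print(f"  families: {len(gs.specs)}  decoys: {decoys}  truncated loci: {trunc}")
    print(f"  wrote FASTA/seeds/truth to {DATA_DIR}")


if __name__ == "__main__":
    main()
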