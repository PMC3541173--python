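"""Family phylogeny: progressive alignment, NJ tree, 500-replicate bootstrap.

Takes the largest family of the classified inventory, aligns its main-list
members, computes Poisson-corrected distances and builds the
neighbor-joining tree with column-bootstrap supports; writes the Newick
tree and the alignment under results/phylo/.
"""
from common import RESULTS

from plantsdr.io import read_fasta
from plantsdr.pairalign import progressive_msa
from plantsdr.phylotree import bootstrap_support, write_newick


def main():
    inv_path = RESULTS / "inventory" / "main_inventory.tsv"
    members: dict[str, list[str]] = {}
    with open(inv_path) as fh:
        next(fh)
        for line in fh:
            g, l, m, verdict, sdr_type, fam = line.split("\t")[:6]
            if fam != "-":
                members.setdefault(fam, []).append(f"{g}|{l}|{m}")
    fam, ids = max(members.items(), key=lambda kv: len(kv[1]))
    seqs = {}
    for p in sorted((RESULTS / "data").glob("*.faa")):
        seqs.update(read_fasta(p))
    ids = sorted(i for i in ids if len(seqs[i]) >= 100)  # full-length members
    msa = progressive_msa([seqs[i] for i in ids], ids)
    tree = bootstrap_support(msa, replicates=500, rng_seed=500,
                             distance_kind="poisson")
    outdir = RESULTS / "phylo"
    outdir.mkdir(parents=True, exist_ok=True)
    msa.to_fasta(outdir / f"{fam}.afa")
    newick = write_newick(tree)
    (outdir / f"{fam}.nwk").write_text(newick + "\n")
    supports = [n.support for n in tree.root.walk()
                if n.support is not None]
    print(f"family {fam}: {len(ids)} full-length members, "
          f"alignment {msa.ncols} columns")
    print(f"bootstrap supports (500 replicates): "
          f"min {min(supports)}, median {sorted(supports)[len(supports)//2]}, "
          f"max {max(supports)}; {tree.skipped_replicates} replicates skipped")
    print(f"tree written to {outdir / (fam + '.nwk')}")


if __name__ == "__main__":
    main()
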