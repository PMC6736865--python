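"""Sequence diversity per species and locus, plus NJ cluster trees.

Haplotype counts, Nei's haplotype diversity Hd, and nucleotide diversity
pi for every species with at least two sequences at each locus; a
p-distance neighbor-joining tree of the two largest species as a
clustering aid. Writes diversity_by_species.tsv and one newick per locus.
"""

import argparse
from pathlib import Path

import pandas as pd

from melcore import pipeline_io, seqdiv

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

tm, _ = pipeline_io.read_trait_csv(args.data / "traits.csv")
rows = []
for locus in ("ITS", "matK"):
    aln = seqdiv.read_alignment(args.data / f"{locus}.fasta", locus_name=locus)
    for sp in tm.species_labels:
        ids = [a for a, s in zip(tm.accession_ids, tm.species) if s == sp]
        if len(ids) < 2:
            continue
        sub = aln.subset(ids)
        hs = seqdiv.haplotype_spectrum(sub)
        rows.append(dict(
            species=sp, locus=locus, n=sub.n, n_haplotypes=hs.n_haplotypes,
            hd=seqdiv.haplotype_diversity(hs), pi=seqdiv.nucleotide_diversity(sub),
        ))
    # NJ tree over the two dominant species, one tip per accession
    big2 = [sp for sp, _ in sorted(
        ((sp, tm.species.count(sp)) for sp in tm.species_labels),
        key=lambda kv: -kv[1])[:2]]
    ids = [a for a, s in zip(tm.accession_ids, tm.species) if s in big2]
    newick = seqdiv.nj_tree(aln.subset(ids))
    (args.out / f"nj_{locus}.nwk").write_text(newick + "\n")

df = pd.DataFrame(rows)
pipeline_io.write_tsv(df, args.out / "diversity_by_species.tsv")
print(df.round(5).to_string(index=False))
print(f"\nwrote {args.out}/diversity_by_species.tsv and nj_<locus>.nwk trees")
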