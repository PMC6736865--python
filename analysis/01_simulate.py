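"""Generate the synthetic study collection.

Emulates a gene-bank seed collection: 18 species of very unequal sizes
(621 accessions in total, dominated by two widely exchanged species),
five seed traits with strong species structure, and ITS- and matK-like
alignments. Writes traits.csv, one FASTA per locus, and the generator's
ground truth to results/data/.
"""

import argparse
import json
from pathlib import Path

from melcore import pipeline_io, seqdiv, synthdata

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
tm, alignments, truths = synthdata.simulate_collection(seed=args.seed)
pipeline_io.write_trait_csv(tm, args.out / "traits.csv")
for locus, aln in alignments.items():
    seqdiv.write_alignment(aln, args.out / f"{locus}.fasta")
truth_json = {
    name: {k: v for k, v in vars(t).items() if v is not None}
    for name, t in truths.items()
}
(args.out / "truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")

sizes = {sp: tm.species.count(sp) for sp in tm.species_labels}
print(f"collection: {tm.n} accessions, {len(sizes)} species")
print(f"two largest species: {sorted(sizes.items(), key=lambda kv: -kv[1])[:2]}")
print(f"true Pst per trait: "
      f"{ {k: round(v, 3) for k, v in truths['traits'].true_pst_per_trait.items()} }")
print(f"wrote {args.out}/traits.csv, ITS.fasta, matK.fasta, truth.json")
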