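"""Build core collections for the two dominant species.

Least-distance stepwise sampling with multiple clustering, in both the
random and the preferred variant, at six sampling proportions (5-30%).
Writes one core file (plus JSON provenance) per species x strategy x
proportion under results/cores/.
"""

import argparse
from pathlib import Path

from melcore import coreselect, pipeline_io

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/cores"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
tm, _ = pipeline_io.read_trait_csv(args.data / "traits.csv")
big2 = [sp for sp, _ in sorted(
    ((sp, tm.species.count(sp)) for sp in tm.species_labels),
    key=lambda kv: -kv[1])[:2]]

proportions = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
for sp in big2:
    sub = tm.filter_species(sp)
    for strategy in ("random", "preferred"):
        for p in proportions:
            core = coreselect.stepwise_core(
                sub, p, strategy,
                seed=args.seed if strategy == "random" else None,
            )
            name = f"core_{sp}_{strategy}_{int(p * 100)}.txt"
            pipeline_io.write_core_set(core, args.out / name)
            print(f"{sp} {strategy:9s} {int(p * 100):3d}%: "
                  f"{core.size:3d}/{sub.n} accessions, {core.rounds} rounds"
                  f"{', truncated' if core.truncated else ''}")
print(f"wrote cores to {args.out}")
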