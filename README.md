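# melcore

Germplasm diversity assessment and core-collection construction for
gene-bank curators and plant genetic-resource researchers.

A seed collection of a multi-species genus (the motivating case is the
forage legume *Melilotus*: ~18 species, hundreds of accessions dominated
by two widely cultivated ones) poses two recurring questions: how much
diversity does the collection hold, and which small subset — the *core
collection* — preserves it? melcore answers both from two standard data
types: a table of quantitative seed traits (length, width,
width-to-length ratio, circumference, 100-seed weight) and per-locus
multiple sequence alignments of barcoding loci (ITS, *mat*K).

## What it computes

**Diversity of the collection**

- coefficient of variation CV = s/x̄ per trait and species;
- Shannon diversity H′ = −Σ pᵢ ln pᵢ over binned phenotype classes
  (default: 10 classes on the standardized scale, open tails beyond ±2σ);
- one-way random-effects variance components (unbalanced design, n₀
  effective group size) and the phenotypic differentiation coefficient
  **Pst = σ²ₐ/(σ²ₐ + σ²w)**, the phenotypic analogue of Qst/Fst;
- haplotype diversity **Hd = n/(n−1)·(1 − Σ pᵢ²)** and nucleotide
  diversity **π** (mean pairwise differences per usable site, complete
  deletion of gap/ambiguity columns), plus a p-distance NJ tree utility.

**Core collections** by *least-distance stepwise sampling with multiple
clustering*: each round standardizes the retained accessions (statistics
frozen from the initial collection), builds a single-linkage dendrogram
on Euclidean distances, and removes one member of every lowest-level
two-accession subgroup — chosen at random (seeded) or *preferred*
(members holding a trait maximum or minimum are always kept). Cores are
evaluated against the initial collection by **MD%** (significant mean
differences), **VD%** (significant variance differences), **CR%**
(range coincidence) and **VR%** (CV ratio), and by an H′/Hd/π diversity
comparison. See `docs/methods.md` for the full procedure.

## Worked example

```python
from melcore import synthdata, traitstats, coreselect, coreeval

# a synthetic 18-species, 621-accession collection with known truth
tm, alignments, truths = synthdata.simulate_collection(seed=1)

summary = traitstats.trait_summary(tm)
print(summary["per_trait"].round(4).to_string(index=False))

albus = tm.filter_species("sp01")            # the dominant species, n=300
core = coreselect.stepwise_core(albus, 0.15, strategy="preferred")
rep = coreeval.evaluate_core(albus, core)
print(core.size, rep.md_percent, rep.cr_percent, round(rep.vr_percent, 4))
```

prints

```
              trait  shannon_h  among_species_cv  f_statistic  p_value    pst
        seed_length     2.0006            0.1619      30.4120      0.0 0.5318
         seed_width     2.0969            0.1414      42.6977      0.0 0.6169
 width_length_ratio     2.0625            0.1620      11.9671      0.0 0.2975
      circumference     2.0616            0.0969      89.2147      0.0 0.7731
hundred_seed_weight     1.8428            0.3910     146.4953      0.0 0.8489
45 0.0 100.0 145.9286
```

Every trait differs significantly among species; differentiation is
weakest for the shape ratio (Pst ≈ 0.30) and strongest for 100-seed
weight (Pst ≈ 0.85, tracking the generator's truth of 0.50–0.85 per
trait). The preferred 15% core keeps 45 of 300 accessions with no
significant mean shifts (MD% = 0), the full trait ranges (CR% = 100),
and a higher relative variability than the initial collection
(VR% ≈ 146) — duplicates were removed, extremes kept.

The same analysis as a scripted narrative lives in `analysis/`
(`01_simulate.py` → `05_evaluate_cores.py`, writing tables under
`results/`), and as a CLI:

```sh
melcore simulate --seed 1 --out-dir results/data
melcore build-core --traits results/data/traits.csv --species sp01 \
    --proportion 0.15 --strategy preferred --out core.txt
melcore evaluate --traits results/data/traits.csv --core core.txt
```

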