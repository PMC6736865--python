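# Methods

## Problem setting

A gene bank holds hundreds of accessions of a multi-species forage
legume genus. Curators want (a) a quantitative picture of the
collection's diversity — from seed morphology and from two barcode loci
(a nuclear ITS-like locus and a plastid matK-like locus) — and (b) a
*core collection*: a small accession subset that preserves that
diversity. melcore implements both stages and a synthetic-data generator
that makes every stage testable against known ground truth.

## Morphological diversity

Five quantitative seed traits per accession (length, width,
width-to-length ratio, circumference, 100-seed weight; units are carried
as opaque metadata and never converted). Statistics:

* **CV** = s/x̄ with the n−1 sample standard deviation.
* **Shannon H′** = −Σ pᵢ ln pᵢ over phenotype classes. Continuous traits
  must be binned; the binning convention used in germplasm surveys is
  rarely stated, so it is explicit and configurable here. Default
  ("sigma" method, 10 classes): classes are defined on standardized
  values, the lowest below mean − 2σ, the highest at or above mean + 2σ,
  and eight classes of width 0.5σ between. This makes H′ invariant to
  affine rescaling of the trait. An equal-width min–max binning is
  available (`method="equal"`).
* **Variance components / Pst.** One-way random-effects ANOVA with
  species as groups: σ²_within = MS_within, σ²_among =
  max(0, (MS_among − MS_within)/n₀), with the Sokal–Rohlf effective
  group size n₀ = (N − Σnᵢ²/N)/(k−1) because real collections are
  strongly unbalanced; a negative moment estimate clamps to zero. Then
  **Pst = σ²_among/(σ²_among + σ²_within)**, the phenotypic analogue of
  Qst/Fst. F = MS_among/MS_within is referred to F(k−1, N−k).

Pst is a phenotypic statistic: it conflates genetic differentiation with
common-environment effects, and the package makes no attempt to
disentangle them.

## Sequence diversity

Input is a trimmed, pre-aligned FASTA per locus (the package performs no
alignment). All estimators first apply **complete deletion**: any column
containing a character outside {A,C,G,T} in any row is removed for all
rows, the convention of standard polymorphism software, which keeps
values comparable between a collection and its subsets.

* **Haplotypes** are equivalence classes of rows over the usable
  columns, labelled H1, H2, … by first occurrence (deterministic).
* **Haplotype diversity** Hd = n/(n−1) · (1 − Σ pᵢ²) (Nei's unbiased
  gene diversity).
* **Nucleotide diversity** π = mean pairwise difference count over all
  C(n,2) pairs, per usable site. It is computed both pairwise and as the
  sum of unbiased per-site heterozygosities; the two are algebraically
  identical under complete deletion and the code asserts their agreement
  at 1e−12 on every call.
* **NJ tree**: neighbor joining on p-distances (negative branches
  clamped to zero), a cluster-visualization aid only — explicitly not a
  model-based phylogeny.

## Core selection: least-distance stepwise sampling

Traits are standardized with statistics **frozen from the initial
collection**; later rounds reuse them, so the metric does not drift as
the retained set shrinks (re-standardizing each round is the main
alternative; the frozen choice keeps "distance" meaning the same thing
in every round). Each round:

1. single-linkage (nearest-distance) clustering of the retained
   accessions on standardized Euclidean distances;
2. every dendrogram node whose two children are both leaves is a
   *lowest-level subgroup* of two accessions; singletons pass through;
3. one member of each pair is removed — uniformly at random (seeded) for
   the **random** strategy; for the **preferred** strategy a member
   holding a current-collection maximum or minimum of any trait is kept,
   both are kept if both hold extremes, and when neither does the member
   farther from the centroid (larger mean |z|) is kept, ties broken by
   lexicographic ID.

The target size is round-half-up(p·N), floored at one. A round that
would undershoot is processed in ascending merge-height order and
stopped exactly at the target, so the most similar pairs are thinned
first. If the preferred rules block all removals (every pair
both-extreme), forced truncation takes over: globally closest pairs are
thinned first, still preferring to keep extreme holders; such cores are
flagged `truncated`, and only they can lose a trait extreme (CR% < 100).
The preferred strategy is otherwise fully deterministic and retains
every per-trait extreme, so CR% = 100 by construction.

## Evaluation

Against the initial collection, over m evaluated traits (default: the
width-to-length ratio, circumference and 100-seed weight; configurable
to all five):

* **MD%** / **VD%** — percentage of traits with a significant
  core-vs-initial mean difference (two-sample pooled-variance t-test;
  Welch by flag) / variance difference (two-sided F-test), at α = 0.05.
  Both take values only in {0, 100/m, …, 100}. No multiple-testing
  correction is applied (m is small and the convention of such reports
  applies none).
* **CR%** — mean per-trait core-to-initial range ratio × 100 (≤ 100).
* **VR%** — mean per-trait core-to-initial CV ratio × 100; > 100 means
  the core is relatively more variable, the expected signature of
  removing near-duplicates.
* A diversity comparison emits H′ per trait and Hd/π per locus for the
  core and initial subsets; loci are never pooled.

## Synthetic generator

Traits: species mean ~ Normal(μ_t, σ²_among,t) drawn once, accession
value ~ Normal(species mean, σ²_within,t), so true Pst is known exactly.
Defaults emulate the study conditions: 18 species with sizes
(300, 125, 60, 40, 30, 15, 10, 8, 6, 5, 4, 4, 3, 3, 3, 2, 2, 1)
— 621 accessions dominated by two species — and per-trait true Pst
(0.75, 0.75, 0.50, 0.78, 0.85): weakest structure for the shape ratio,
strongest (≈0.85) for 100-seed weight, the ordering seen in seed
surveys. Trait units are abstract; global means (10, 8, 6, 20, 5) keep
CVs well-defined.

Sequences: each species base differs from a shared ancestor at a fixed
number of sites (ITS-like locus: 600 bp, 15 sites, 3 haplotypes/species;
matK-like: 700 bp, 8 sites, 2 haplotypes — the plastid locus is the less
variable one); within a species, haplotype 1 is the base and each later
haplotype substitutes 2 sites, disjoint across haplotypes where the
locus allows (reuse triggers a logged warning). Accessions draw
haplotypes from a per-species frequency vector (default geometric,
normalized 0.5^k weights). The recorded truth is *realized*: Hd at the
drawn counts, π from the known pairwise haplotype differences — an
independent code path from the alignment-column estimators, which the
tests require to agree exactly.

What the generator does **not** emulate: measurement error,
trait–haplotype correlation (haplotypes are drawn independently of
traits, so a core selected on traits has unbiased, not elevated,
sequence diversity — real collections with duplicated accessions show an
increase), mutation-model realism (no rate matrices, indels or
coalescent structure), missing data, or the H′ gain in cores sometimes
reported for real collections (with sigma-binned near-normal traits,
small-sample class occupancy pulls H′ slightly down). Passing tests
therefore demonstrate correctness of the estimators and sampler
contracts, not those empirical effects.

## Numerical choices and degenerate inputs

* Round-half-up for the core target; floor of one accession.
* σ²_among clamps at 0; Pst on constant data raises an error rather
  than returning 0/0.
* CV undefined at zero mean (error); a zero-variance trait blocks
  standardization with an error naming the trait; zero-range or zero-CV
  traits are excluded from evaluation with a warning and m decremented.
* Haplotype labels and pair processing order are deterministic; the
  random strategy consumes a `numpy` Generator seeded explicitly, so
  identical configuration + seed reproduces every output byte for byte.
* Reports print floats to 4 decimals.

## Problem sizes in the test and acceptance runs

The packaged checks run at desk scale, chosen as the smallest sizes at
which each property is meaningful: oracle equivalence on 100 random
alignments (n ≤ 20, L ≤ 200) and 50 clustering instances (n ≤ 30); Pst
recovery over 200 replicates of 18 species × 20 accessions; sampler
contracts on collections of 40/100/300 accessions across the six
proportions; the VR% tendency over 20 seeds on a 300-accession
collection. The whole suite completes in well under a minute.
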