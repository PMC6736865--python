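"""Synthetic germplasm collections with known ground truth.

Emulates the structure of a gene-bank seed collection of a multi-species
forage legume genus: ~18 species of very unequal sizes, five quantitative
seed traits with species structure (controllable true Pst), and two
barcode-locus alignments built from species-structured haplotype pools
(controllable haplotype frequencies and divergence). Every generator
returns a :class:`SyntheticTruth` so downstream estimators can be checked
against realized, not merely nominal, quantities.

The trait model is a plain one-way random-effects draw: species s gets a
mean ``Normal(mu_t, sigma2_among_t)`` once, accessions get
``Normal(species mean, sigma2_within_t)``; thus the true differentiation
is ``Pst_t = sigma2_among_t/(sigma2_among_t + sigma2_within_t)`` exactly.
Haplotypes are literal site substitutions from a species base sequence —
no mutation-model realism (no rate matrices, no indels) is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from melcore.containers import DEFAULT_TRAIT_NAMES, Alignment, TraitMatrix
from melcore.errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Default species sizes: 18 species, total 621 accessions, dominated by
#: a handful of species as real forage collections are.
DEFAULT_SPECIES_SIZES = (
    300, 125, 60, 40, 30, 15, 10, 8, 6, 5, 4, 4, 3, 3, 3, 2, 2, 1
)

#: Default per-trait global means (abstract units) and variance
#: components. The among/within split gives true Pst of
#: (0.75, 0.75, 0.50, 0.78, 0.85): strong species structure for size
#: traits, the weakest for the shape ratio, the strongest for seed
#: weight — the ordering typical of seed-morphology surveys.
DEFAULT_TRAIT_MEANS = (10.0, 8.0, 6.0, 20.0, 5.0)
DEFAULT_SIGMA2_AMONG = (3.0, 3.0, 1.0, 3.545454545454545, 5.666666666666666)
DEFAULT_SIGMA2_WITHIN = (1.0, 1.0, 1.0, 1.0, 1.0)

_NUC = np.array(list("ACGT"), dtype="U1")


def species_label(i: int) -> str:
    return f"sp{i + 1:02d}"


def _accession_ids(sizes) -> tuple[list[str], list[str]]:
    ids, species = [], []
    for s, size in enumerate(sizes):
        for j in range(size):
            ids.append(f"{species_label(s)}-{j + 1:04d}")
            species.append(species_label(s))
    return ids, species


def _as_per_trait(value, n_traits: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_traits, arr[0])
    if arr.size != n_traits:
        raise ConfigurationError(f"{name}: expected 1 or {n_traits} values, got {arr.size}")
    return arr


@dataclass
class TraitSimConfig:
    """Configuration of the quantitative-trait simulator."""

    n_species: int = 18
    accessions_per_species: tuple[int, ...] = DEFAULT_SPECIES_SIZES
    n_traits: int = 5
    sigma2_among: object = DEFAULT_SIGMA2_AMONG
    sigma2_within: object = DEFAULT_SIGMA2_WITHIN
    trait_means: object = DEFAULT_TRAIT_MEANS
    trait_names: tuple[str, ...] = DEFAULT_TRAIT_NAMES
    seed: int = 0

    def validated(self) -> "TraitSimConfig":
        if self.n_species < 1:
            raise ConfigurationError("n_species: must be >= 1")
        if len(self.accessions_per_species) != self.n_species:
            raise ConfigurationError(
                "accessions_per_species: length "
                f"{len(self.accessions_per_species)} != n_species {self.n_species}"
            )
        if any(c < 1 for c in self.accessions_per_species):
            raise ConfigurationError("accessions_per_species: all counts must be >= 1")
        if len(self.trait_names) != self.n_traits:
            raise ConfigurationError("trait_names: length must equal n_traits")
        for name in ("sigma2_among", "sigma2_within"):
            arr = _as_per_trait(getattr(self, name), self.n_traits, name)
            if np.any(arr < 0):
                raise ConfigurationError(f"{name}: variances must be >= 0")
        _as_per_trait(self.trait_means, self.n_traits, "trait_means")
        return self


@dataclass
class SeqSimConfig:
    """Configuration of the barcode-locus alignment simulator."""

    n_species: int = 18
    accessions_per_species: tuple[int, ...] = DEFAULT_SPECIES_SIZES
    locus_length: int = 600
    n_haplotypes_per_species: int = 3
    mutations_per_haplotype: int = 2
    haplotype_freqs: list | None = None  # per-species vectors; default geometric
    between_species_divergence: int = 15
    locus_name: str = "locus"
    seed: int = 0

    def resolved_freqs(self) -> list[np.ndarray]:
        if self.haplotype_freqs is None:
            w = 0.5 ** np.arange(self.n_haplotypes_per_species)
            return [w / w.sum() for _ in range(self.n_species)]
        return [np.asarray(f, dtype=float) for f in self.haplotype_freqs]

    def validated(self) -> "SeqSimConfig":
        if self.n_species < 1 or self.locus_length < 1:
            raise ConfigurationError("n_species and locus_length must be >= 1")
        if len(self.accessions_per_species) != self.n_species:
            raise ConfigurationError(
                "accessions_per_species: length must equal n_species"
            )
        if any(c < 1 for c in self.accessions_per_species):
            raise ConfigurationError("accessions_per_species: all counts must be >= 1")
        if self.n_haplotypes_per_species < 1:
            raise ConfigurationError("n_haplotypes_per_species: must be >= 1")
        if self.mutations_per_haplotype >= self.locus_length:
            raise ConfigurationError(
                "mutations_per_haplotype: must be < locus_length"
            )
        if self.between_species_divergence >= self.locus_length:
            raise ConfigurationError(
                "between_species_divergence: must be < locus_length"
            )
        freqs = self.resolved_freqs()
        if len(freqs) != self.n_species:
            raise ConfigurationError("haplotype_freqs: one vector per species required")
        for f in freqs:
            if f.size != self.n_haplotypes_per_species:
                raise ConfigurationError(
                    "haplotype_freqs: vector length must equal n_haplotypes_per_species"
                )
            if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
                raise ConfigurationError("haplotype_freqs: vectors must sum to 1")
        return self


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators.

    Trait fields are populated by :func:`simulate_trait_table`, sequence
    fields by :func:`simulate_alignment`; unused fields stay None. The
    sequence expectations are *realized-count* values: Hd is Nei's
    estimator evaluated at the haplotype counts actually drawn, and pi
    comes from the known pairwise haplotype differences — an independent
    code path from the alignment-column estimators.
    """

    true_pst_per_trait: dict[str, float] | None = None
    true_species_means: dict[str, dict[str, float]] | None = None
    true_haplotype_table: dict[str, str] | None = None
    expected_hd_per_species: dict[str, float] | None = None
    expected_pi_per_species: dict[str, float] | None = None
    haplotype_counts: dict[str, dict[str, int]] | None = field(default=None, repr=False)


def simulate_trait_table(cfg: TraitSimConfig) -> tuple[TraitMatrix, SyntheticTruth]:
    """Draw a species-structured accession-by-trait table.

    Deterministic for a fixed config and seed. True Pst per trait is
    sigma2_among/(sigma2_among + sigma2_within), 0 when both are zero.
    """
    cfg = cfg.validated()
    rng = np.random.default_rng(cfg.seed)
    s2a = _as_per_trait(cfg.sigma2_among, cfg.n_traits, "sigma2_among")
    s2w = _as_per_trait(cfg.sigma2_within, cfg.n_traits, "sigma2_within")
    mu = _as_per_trait(cfg.trait_means, cfg.n_traits, "trait_means")

    species_means = mu + rng.standard_normal((cfg.n_species, cfg.n_traits)) * np.sqrt(s2a)
    ids, species = _accession_ids(cfg.accessions_per_species)
    values = np.empty((len(ids), cfg.n_traits))
    row = 0
    for s, size in enumerate(cfg.accessions_per_species):
        values[row:row + size] = (
            species_means[s]
            + rng.standard_normal((size, cfg.n_traits)) * np.sqrt(s2w)
        )
        row += size

    denom = s2a + s2w
    true_pst = {
        t: (float(s2a[j] / denom[j]) if denom[j] > 0 else 0.0)
        for j, t in enumerate(cfg.trait_names)
    }
    truth = SyntheticTruth(
        true_pst_per_trait=true_pst,
        true_species_means={
            species_label(s): {
                t: float(species_means[s, j]) for j, t in enumerate(cfg.trait_names)
            }
            for s in range(cfg.n_species)
        },
    )
    tm = TraitMatrix(ids, species, values, list(cfg.trait_names))
    return tm, truth


def _mutate(seq: np.ndarray, sites: np.ndarray, rng) -> dict[int, str]:
    """Pick a different base at each site; return site -> new base."""
    out = {}
    for s in sites:
        alternatives = _NUC[_NUC != seq[s]]
        out[int(s)] = str(rng.choice(alternatives))
    return out


def simulate_alignment(cfg: SeqSimConfig) -> tuple[Alignment, SyntheticTruth]:
    """Draw one locus alignment from species-structured haplotype pools.

    Each species descends from a common ancestor sequence via
    ``between_species_divergence`` substitutions; haplotype 1 is the
    species base, later haplotypes carry ``mutations_per_haplotype``
    substitutions at sites disjoint across the species' haplotypes where
    the locus is long enough (with a logged warning otherwise). Each
    accession samples one haplotype from its species' frequency vector.
    """
    cfg = cfg.validated()
    rng = np.random.default_rng(cfg.seed)
    freqs = cfg.resolved_freqs()
    ancestor = rng.choice(_NUC, size=cfg.locus_length)

    ids, species = _accession_ids(cfg.accessions_per_species)
    sequences: list[str] = []
    hap_table: dict[str, str] = {}
    expected_hd: dict[str, float] = {}
    expected_pi: dict[str, float] = {}
    hap_counts_out: dict[str, dict[str, int]] = {}

    row = 0
    for s, size in enumerate(cfg.accessions_per_species):
        label = species_label(s)
        base = ancestor.copy()
        div_sites = rng.choice(cfg.locus_length, size=cfg.between_species_divergence,
                               replace=False)
        for site, char in _mutate(base, div_sites, rng).items():
            base[site] = char

        # per-haplotype substitution maps, disjoint sites where possible
        available = list(range(cfg.locus_length))
        rng.shuffle(available)
        hap_subs: list[dict[int, str]] = [{}]  # haplotype 1 == base
        for _h in range(1, cfg.n_haplotypes_per_species):
            if len(available) >= cfg.mutations_per_haplotype:
                sites = np.array([available.pop() for _ in range(cfg.mutations_per_haplotype)])
            else:
                logger.warning(
                    "%s/%s: locus too short for disjoint haplotype sites; reusing",
                    cfg.locus_name, label,
                )
                sites = rng.choice(cfg.locus_length, size=cfg.mutations_per_haplotype,
                                   replace=False)
            hap_subs.append(_mutate(base, sites, rng))

        hap_seqs = []
        for subs in hap_subs:
            seq = base.copy()
            for site, char in subs.items():
                seq[site] = char
            hap_seqs.append("".join(seq))

        draws = rng.choice(cfg.n_haplotypes_per_species, size=size, p=freqs[s])
        counts = np.bincount(draws, minlength=cfg.n_haplotypes_per_species)
        for j in range(size):
            acc = ids[row + j]
            hap_table[acc] = f"{label}:H{draws[j] + 1}"
            sequences.append(hap_seqs[draws[j]])
        row += size
        hap_counts_out[label] = {
            f"H{h + 1}": int(c) for h, c in enumerate(counts) if c > 0
        }

        # realized-count expectations, independent of the column estimators
        n = size
        if n >= 2:
            p = counts / n
            expected_hd[label] = float((n / (n - 1)) * (1.0 - (p**2).sum()))
            total_diff = 0.0
            for i in range(cfg.n_haplotypes_per_species):
                for j in range(i + 1, cfg.n_haplotypes_per_species):
                    d = _hap_distance(hap_subs[i], hap_subs[j])
                    total_diff += counts[i] * counts[j] * d
            npairs = n * (n - 1) / 2
            expected_pi[label] = float(total_diff / npairs / cfg.locus_length)
        else:
            expected_hd[label] = 0.0
            expected_pi[label] = 0.0

    aln = Alignment(ids, sequences, cfg.locus_name)
    truth = SyntheticTruth(
        true_haplotype_table=hap_table,
        expected_hd_per_species=expected_hd,
        expected_pi_per_species=expected_pi,
        haplotype_counts=hap_counts_out,
    )
    return aln, truth


def _hap_distance(subs_a: dict[int, str], subs_b: dict[int, str]) -> int:
    """Sites where two substitution maps give different characters."""
    d = 0
    for site in set(subs_a) | set(subs_b):
        if subs_a.get(site) != subs_b.get(site):
            d += 1
    return d


def simulate_collection(
    seed: int = 0,
    trait_cfg: TraitSimConfig | None = None,
    loci: dict[str, SeqSimConfig] | None = None,
):
    """Full study bundle: trait table plus ITS- and matK-like alignments.

    Convenience wrapper used by the pipeline and the example analyses;
    sub-seeds are derived deterministically from ``seed``. Returns
    ``(TraitMatrix, {locus: Alignment}, {name: SyntheticTruth})``.
    """
    trait_cfg = trait_cfg or TraitSimConfig(seed=seed)
    if loci is None:
        shared = dict(
            n_species=trait_cfg.n_species,
            accessions_per_species=trait_cfg.accessions_per_species,
        )
        loci = {
            "ITS": SeqSimConfig(locus_name="ITS", locus_length=600,
                                n_haplotypes_per_species=3,
                                mutations_per_haplotype=2,
                                between_species_divergence=15,
                                seed=(seed * 3 + 1) % 2**31, **shared),
            "matK": SeqSimConfig(locus_name="matK", locus_length=700,
                                 n_haplotypes_per_species=2,
                                 mutations_per_haplotype=2,
                                 between_species_divergence=8,
                                 seed=(seed * 3 + 2) % 2**31, **shared),
        }
    tm, trait_truth = simulate_trait_table(trait_cfg)
    alignments, truths = {}, {"traits": trait_truth}
    for name, cfg in loci.items():
        aln, truth = simulate_alignment(cfg)
        alignments[name] = aln
        truths[name] = truth
    return tm, alignments, truths
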