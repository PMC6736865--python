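"""Core in-memory containers: trait tables, alignments, haplotype spectra,
cluster trees and core sets.

All containers are lightweight frozen-ish dataclasses over numpy/pandas
structures; validation happens at construction so downstream code can
assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from melcore.errors import FormatError

#: Canonical seed-trait column order used by the synthetic generator and
#: the example analyses. Units are carried as opaque metadata and never
#: converted.
DEFAULT_TRAIT_NAMES = (
    "seed_length",
    "seed_width",
    "width_length_ratio",
    "circumference",
    "hundred_seed_weight",
)

_ACGT = frozenset("ACGT")


@dataclass
class TraitMatrix:
    """Accession-by-trait table with a species partition.

    Parameters
    ----------
    accession_ids : sequence of str
        Unique accession labels, one per row.
    species : sequence of str
        Species label per accession (the "population" of Pst).
    values : (n_accessions, n_traits) float array
        Quantitative trait values; must be finite.
    trait_names : sequence of str
        Column labels; units, if any, are the caller's metadata.
    """

    accession_ids: list[str]
    species: list[str]
    values: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.species = [str(s) for s in self.species]
        self.values = np.asarray(self.values, dtype=float)
        self.trait_names = [str(t) for t in self.trait_names]
        n = len(self.accession_ids)
        if len(set(self.accession_ids)) != n:
            dupes = sorted({a for a in self.accession_ids if self.accession_ids.count(a) > 1})
            raise FormatError(f"duplicate accession IDs: {dupes}")
        if len(self.species) != n:
            raise FormatError("species labels and accession IDs differ in length")
        if self.values.shape != (n, len(self.trait_names)):
            raise FormatError(
                f"trait matrix shape {self.values.shape} does not match "
                f"{n} accessions x {len(self.trait_names)} traits"
            )
        if n and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite trait value at accession "
                f"{self.accession_ids[bad[0]]!r}, trait {self.trait_names[bad[1]]!r}"
            )
        if n and not self.species:
            raise FormatError("at least one species label required")
        self._index = {a: i for i, a in enumerate(self.accession_ids)}

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    @property
    def species_labels(self) -> list[str]:
        """Distinct species labels in order of first occurrence."""
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)

    def trait(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]

    def rows(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self._index[a] for a in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "TraitMatrix":
        """Row subset preserving the order of `ids`."""
        idx = self.rows(ids)
        return TraitMatrix(
            [self.accession_ids[i] for i in idx],
            [self.species[i] for i in idx],
            self.values[idx],
            list(self.trait_names),
        )

    def filter_species(self, label: str) -> "TraitMatrix":
        ids = [a for a, s in zip(self.accession_ids, self.species) if s == label]
        return self.subset(ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "species", self.species)
        df.insert(0, "accession_id", self.accession_ids)
        return df


@dataclass
class Alignment:
    """Equal-length sequence matrix for one locus, keyed by accession ID.

    Rows are uppercase strings over the DNA alphabet plus gap and IUPAC
    ambiguity characters; validation rejects ragged rows and duplicate IDs.
    """

    accession_ids: list[str]
    sequences: list[str]
    locus_name: str = "locus"

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.sequences = [str(s).upper() for s in self.sequences]
        if len(set(self.accession_ids)) != len(self.accession_ids):
            dupes = sorted(
                {a for a in self.accession_ids if self.accession_ids.count(a) > 1}
            )
            raise FormatError(f"duplicate sequence IDs: {dupes}")
        if len(self.sequences) != len(self.accession_ids):
            raise FormatError("IDs and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        """(n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, ids: Sequence[str]) -> "Alignment":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise FormatError(f"IDs absent from alignment {self.locus_name!r}: {missing}")
        rows = [index[a] for a in ids]
        return Alignment(
            [self.accession_ids[i] for i in rows],
            [self.sequences[i] for i in rows],
            self.locus_name,
        )


@dataclass
class HaplotypeSpectrum:
    """Distinct-sequence classes with counts.

    Labels are assigned ``H1, H2, ...`` in order of first occurrence in the
    source alignment, so the spectrum is deterministic across runs.
    """

    haplotype_labels: list[str]
    counts: list[int]
    member_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts):
            raise FormatError("haplotype counts must be positive")
        if len(self.haplotype_labels) != len(self.counts):
            raise FormatError("labels and counts differ in length")
        if self.member_map and len(self.member_map) != sum(self.counts):
            raise FormatError("member_map size does not match total count")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)


@dataclass
class ClusterTree:
    """Agglomerative dendrogram as a merge list.

    ``merges[k] = (node_a, node_b, height)`` creates internal node
    ``n_leaves + k``. Leaves are ``0..n_leaves-1`` and index rows of the
    clustered matrix. Single linkage guarantees nondecreasing heights.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise FormatError(
                f"{self.n_leaves} leaves require {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )
        heights = [h for _, _, h in self.merges]
        if any(h < 0 for h in heights):
            raise FormatError("negative merge height")
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise FormatError("merge heights must be nondecreasing")


@dataclass
class CoreSet:
    """A selected accession subset plus sampling provenance."""

    accession_ids: list[str]
    strategy: str
    proportion: float
    seed: int | None
    rounds: int
    truncated: bool = False
    stopped_mid_round: bool = False

    def __post_init__(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise FormatError("duplicate accession IDs in core set")
        if self.strategy not in ("random", "preferred"):
            raise FormatError(f"unknown strategy {self.strategy!r}")

    @property
    def size(self) -> int:
        return len(self.accession_ids)
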