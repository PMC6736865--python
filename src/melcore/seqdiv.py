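"""Sequence diversity from multiple sequence alignments.

Haplotype spectrum, Nei's haplotype diversity Hd, nucleotide diversity
pi, and a neighbor-joining tree utility on p-distances. Sites containing
anything but A/C/G/T in any sequence (gaps, Ns, IUPAC ambiguity codes)
are removed before any computation — the "complete deletion" convention
of standard polymorphism software, which keeps Hd and pi comparable
across subsets of the same alignment.
"""

from __future__ import annotations

import logging

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj

from melcore.containers import Alignment, HaplotypeSpectrum
from melcore.errors import FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

_ACGT = np.array(list("ACGT"), dtype="U1")


def read_alignment(path, locus_name: str | None = None) -> Alignment:
    """Load an aligned FASTA file into an :class:`Alignment`.

    Lowercase bases are normalized to uppercase; ragged rows and
    duplicate IDs are rejected with a :class:`FormatError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(
        [r.id for r in records],
        [str(r.seq) for r in records],
        locus_name or path.stem,
    )


def write_alignment(a: Alignment, path) -> None:
    """Write an alignment as FASTA, one record per accession."""
    records = [
        SeqRecord(Seq(s), id=acc, description="")
        for acc, s in zip(a.accession_ids, a.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def usable_sites(a: Alignment) -> np.ndarray:
    """Indices of columns containing only A/C/G/T in every row.

    Complete deletion: a gap or ambiguity character in any single row
    removes the column for all rows. Returns a sorted integer index
    array; empty (with a logged warning) when no column survives.
    """
    m = a.matrix()
    clean = np.isin(m, _ACGT).all(axis=0)
    idx = np.flatnonzero(clean)
    if idx.size == 0:
        logger.warning("alignment %s: no usable sites after complete deletion", a.locus_name)
    return idx


def haplotype_spectrum(a: Alignment) -> HaplotypeSpectrum:
    """Group sequences into haplotypes over the usable sites.

    Haplotypes are equivalence classes of rows restricted to the usable
    columns, labelled H1, H2, ... in order of first occurrence. If no
    usable site exists, full rows are classed instead (with a warning),
    so the spectrum degrades gracefully rather than collapsing to one
    class.
    """
    idx = usable_sites(a)
    if idx.size:
        keys = ["".join(row) for row in a.matrix()[:, idx]]
    else:
        logger.warning(
            "alignment %s: classing on full rows (no usable sites)", a.locus_name
        )
        keys = list(a.sequences)
    label_of: dict[str, str] = {}
    member_map: dict[str, str] = {}
    counts: dict[str, int] = {}
    for acc, key in zip(a.accession_ids, keys):
        if key not in label_of:
            label_of[key] = f"H{len(label_of) + 1}"
            counts[label_of[key]] = 0
        lab = label_of[key]
        counts[lab] += 1
        member_map[acc] = lab
    labels = list(counts)
    return HaplotypeSpectrum(labels, [counts[l] for l in labels], member_map)


def haplotype_diversity(hs: HaplotypeSpectrum) -> float:
    """Nei's unbiased haplotype (gene) diversity.

    Hd = n/(n-1) * (1 - sum p_i^2): the probability that two sequences
    drawn without replacement belong to different haplotypes.
    """
    n = hs.n
    if n < 2:
        raise InsufficientDataError(f"haplotype diversity needs n>=2, got {n}")
    p = np.asarray(hs.counts, dtype=float) / n
    return float((n / (n - 1)) * (1.0 - (p**2).sum()))


def nucleotide_diversity(a: Alignment) -> float:
    """Nucleotide diversity pi in substitutions per usable site.

    pi = mean pairwise difference count over all C(n,2) sequence pairs,
    divided by the number of usable sites. Computed two ways — pairwise
    and as the sum of unbiased per-site heterozygosities — and checked
    for agreement; the identity holds exactly for complete deletion.
    """
    if a.n < 2:
        raise InsufficientDataError(f"pi needs n>=2 sequences, got {a.n}")
    idx = usable_sites(a)
    if idx.size == 0:
        raise InsufficientDataError("pi undefined: no usable sites")
    m = a.matrix()[:, idx]
    n, L = m.shape
    npairs = n * (n - 1) / 2
    total = 0
    for i in range(n):
        total += (m[i + 1:] != m[i]).sum()
    pi_pairwise = total / npairs / L

    site_het = 0.0
    for base in _ACGT:
        c = (m == base).sum(axis=0)
        site_het += (c * (n - c)).sum()
    pi_sitewise = site_het / 2 / npairs / L

    assert abs(pi_pairwise - pi_sitewise) < 1e-12, "pairwise/sitewise pi mismatch"
    return float(pi_pairwise)


def p_distance_matrix(a: Alignment) -> np.ndarray:
    """Pairwise proportion of differing usable sites between rows."""
    idx = usable_sites(a)
    if idx.size == 0:
        raise InsufficientDataError("p-distances undefined: no usable sites")
    m = a.matrix()[:, idx]
    n = a.n
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = (m[i + 1:] != m[i]).mean(axis=1)
    return d + d.T


def nj_tree(a: Alignment) -> str:
    """Neighbor-joining tree on p-distances, as a newick string.

    A cluster-visualization aid, not a model-based phylogeny: distances
    are raw mismatch proportions over usable sites and negative branch
    lengths are clamped to zero.
    """
    if a.n < 3:
        raise InsufficientDataError(f"NJ needs >=3 taxa, got {a.n}")
    dm = DistanceMatrix(p_distance_matrix(a), ids=a.accession_ids)
    tree = nj(dm, neg_as_zero=True)
    return str(tree).strip()
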