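"""Sequence diversity: alignment I/O, haplotyping, Hd, pi, NJ trees."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melcore import seqdiv
from melcore.containers import Alignment
from melcore.errors import FormatError, InsufficientDataError
from oracles import brute_hd, brute_haplotype_counts, brute_pi, random_alignment


class TestReadAlignment:
    def test_round_trip_and_uppercase(self, tmp_path):
        p = tmp_path / "toy.fasta"
        p.write_text(">s1\nacgt-\n>s2\nACGTA\n")
        a = seqdiv.read_alignment(p)
        assert a.n == 2 and a.length == 5
        assert a.sequences[0] == "ACGT-"
        assert a.locus_name == "toy"

    def test_ragged_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">s1\nACGTA\n>s2\nACGTAC\n")
        with pytest.raises(FormatError, match="ragged"):
            seqdiv.read_alignment(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">s1\nACGT\n>s1\nACGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            seqdiv.read_alignment(p)

    def test_write_read_identity(self, tmp_path, small_alignment):
        p = tmp_path / "out.fasta"
        seqdiv.write_alignment(small_alignment, p)
        back = seqdiv.read_alignment(p, locus_name=small_alignment.locus_name)
        assert back.sequences == small_alignment.sequences
        assert back.accession_ids == small_alignment.accession_ids


class TestUsableSites:
    def test_clean_alignment_keeps_all(self, small_alignment):
        assert len(seqdiv.usable_sites(small_alignment)) == 10

    def test_complete_deletion_of_gap_column(self):
        a = Alignment(["a", "b"], ["AC-T", "ACGT"])
        assert list(seqdiv.usable_sites(a)) == [0, 1, 3]

    def test_ambiguity_column_removed(self):
        a = Alignment(["a", "b"], ["ANRT", "ACGT"])
        assert list(seqdiv.usable_sites(a)) == [0, 3]


class TestHaplotypeSpectrum:
    def test_monomorphic(self):
        a = Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        hs = seqdiv.haplotype_spectrum(a)
        assert hs.counts == [4] and hs.haplotype_labels == ["H1"]

    def test_direct_classing_with_first_occurrence_labels(self):
        a = Alignment(["a", "b", "c"], ["AAAA", "AAAA", "AATA"])
        hs = seqdiv.haplotype_spectrum(a)
        assert dict(zip(hs.haplotype_labels, hs.counts)) == {"H1": 2, "H2": 1}
        assert hs.member_map == {"a": "H1", "b": "H1", "c": "H2"}

    def test_difference_inside_gap_column_ignored(self):
        a = Alignment(["a", "b"], ["AC-A", "ACTA"])  # column 2 has a gap
        hs = seqdiv.haplotype_spectrum(a)
        assert hs.n_haplotypes == 1


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([4], 0.0),
            ([2, 2], (4 / 3) * 0.5),
            ([3, 1, 1], 0.7),
        ],
    )
    def test_formula(self, counts, expected):
        from melcore.containers import HaplotypeSpectrum

        hs = HaplotypeSpectrum([f"H{i}" for i in range(len(counts))], counts)
        assert seqdiv.haplotype_diversity(hs) == pytest.approx(expected)

    def test_needs_two_sequences(self):
        from melcore.containers import HaplotypeSpectrum

        with pytest.raises(InsufficientDataError):
            seqdiv.haplotype_diversity(HaplotypeSpectrum(["H1"], [1]))


class TestNucleotideDiversity:
    def test_identical_rows_zero(self):
        a = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        assert seqdiv.nucleotide_diversity(a) == 0.0

    def test_single_pair(self):
        a = Alignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTAA"])
        assert seqdiv.nucleotide_diversity(a) == pytest.approx(0.1)

    def test_three_rows_brute_force(self):
        s = "ACGTACGTAC"
        s2 = "ACGTACGTGG"
        a = Alignment(["a", "b", "c"], [s, s, s2])
        assert seqdiv.nucleotide_diversity(a) == pytest.approx((0 + 2 + 2) / 3 / 10)

    @given(data=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_pairwise_oracle(self, data):
        rng = np.random.default_rng(data)
        n = int(rng.integers(2, 15))
        length = int(rng.integers(20, 120))
        seqs = random_alignment(rng, n, length)
        a = Alignment([f"s{i}" for i in range(n)], seqs)
        if len(seqdiv.usable_sites(a)) == 0:
            return
        assert seqdiv.nucleotide_diversity(a) == pytest.approx(brute_pi(seqs), abs=1e-12)
        hs = seqdiv.haplotype_spectrum(a)
        assert seqdiv.haplotype_diversity(hs) == pytest.approx(
            brute_hd(brute_haplotype_counts(seqs)), abs=1e-12
        )

    def test_row_order_and_gap_column_invariance(self, small_alignment):
        pi0 = seqdiv.nucleotide_diversity(small_alignment)
        hd0 = seqdiv.haplotype_diversity(seqdiv.haplotype_spectrum(small_alignment))
        perm = [3, 0, 4, 1, 2]
        shuffled = Alignment(
            [small_alignment.accession_ids[i] for i in perm],
            [small_alignment.sequences[i] + "-" for i in perm],
        )
        assert seqdiv.nucleotide_diversity(shuffled) == pytest.approx(pi0, abs=1e-15)
        assert seqdiv.haplotype_diversity(
            seqdiv.haplotype_spectrum(shuffled)
        ) == pytest.approx(hd0, abs=1e-15)


class TestNjTree:
    def _additive_quartet(self) -> Alignment:
        # disjoint substitution sets making p-distances exactly additive
        L = 100
        base = list("A" * L)

        def mutate(sites):
            s = base.copy()
            for i in sites:
                s[i] = "T"
            return "".join(s)

        a = mutate([0])                       # 1 private site
        b = mutate([1, 2])                    # 2 private sites
        internal = [10, 11, 12, 13, 14]       # 5 shared sites for c, d
        c = mutate(internal + [20])
        d = mutate(internal + [21, 22, 23])
        return Alignment(["a", "b", "c", "d"], [a, b, c, d])

    def test_recovers_additive_distances(self):
        import io

        from skbio import TreeNode

        aln = self._additive_quartet()
        newick = seqdiv.nj_tree(aln)
        tree = TreeNode.read(io.StringIO(newick))
        got = tree.tip_tip_distances()
        expected = seqdiv.p_distance_matrix(aln)
        ids = aln.accession_ids
        for i in range(4):
            for j in range(i + 1, 4):
                assert got[ids[i], ids[j]] == pytest.approx(expected[i, j], abs=1e-10)

    def test_three_taxa(self):
        a = Alignment(["a", "b", "c"], ["AAAA", "AAAT", "AATT"])
        newick = seqdiv.nj_tree(a)
        assert newick.count(",") == 2 and newick.endswith(";")

    def test_identical_sequences_zero_branches(self):
        import io

        from skbio import TreeNode

        a = Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        tree = TreeNode.read(io.StringIO(seqdiv.nj_tree(a)))
        for node in tree.traverse():
            assert not node.length or node.length == 0.0

    def test_too_few_taxa(self):
        a = Alignment(["a", "b"], ["ACGT", "ACGA"])
        with pytest.raises(InsufficientDataError):
            seqdiv.nj_tree(a)
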