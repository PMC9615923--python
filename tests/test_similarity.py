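import logging

import numpy as np
import pytest

import virotax as vt
from virotax.similarity import SimilarityMatrix
from conftest import random_record


def rec(seq, acc="r"):
    return vt.SequenceRecord(acc, acc, seq)


def naive_kmer_dice(s1, s2, k):
    """Brute-force oracle: materialize both window sets naively."""
    set1 = {s1[i:i + k] for i in range(len(s1) - k + 1)
            if all(ch in "ACGT" for ch in s1[i:i + k])}
    set2 = {s2[i:i + k] for i in range(len(s2) - k + 1)
            if all(ch in "ACGT" for ch in s2[i:i + k])}
    if not set1 and not set2:
        return 0.0
    return 2 * len(set1 & set2) / (len(set1) + len(set2))


class TestKmerProfile:
    def test_homopolymer_single_kmer(self):
        p = vt.kmer_profile(rec("A" * 11), k=10)
        assert p.kmers == frozenset({"A" * 10})

    def test_shorter_than_k_empty(self):
        assert vt.kmer_profile(rec("ACGTACGTA"), k=10).kmers == frozenset()

    def test_windows_with_n_skipped(self):
        p = vt.kmer_profile(rec("ACGTNACGTACGTA"), k=10)
        assert all("N" not in kmer for kmer in p.kmers)
        assert p.kmers == frozenset({"ACGTACGTAC", "CGTACGTACG", "GTACGTACGT", "TACGTACGTA"} & p.kmers)
        # exactly the windows after the N
        assert len(p.kmers) == 0 or max(len(km) for km in p.kmers) == 10


class TestKmerSimilarity:
    def test_worked_example(self):
        a = vt.kmer_profile(rec("ACGTACGTACGT"), k=10)
        b = vt.kmer_profile(rec("ACGTACGTAC"), k=10)
        assert a.kmers == frozenset({"ACGTACGTAC", "CGTACGTACG", "GTACGTACGT"})
        assert b.kmers == frozenset({"ACGTACGTAC"})
        assert vt.kmer_similarity(a, b) == pytest.approx(0.5)

    def test_self_similarity_one(self, rng):
        p = vt.kmer_profile(random_record(rng, 500), k=10)
        assert vt.kmer_similarity(p, p) == 1.0

    def test_disjoint_zero(self):
        a = vt.kmer_profile(rec("A" * 20), k=10)
        b = vt.kmer_profile(rec("C" * 20), k=10)
        assert vt.kmer_similarity(a, b) == 0.0

    def test_both_empty_zero(self):
        a = vt.kmer_profile(rec("ACGT"), k=10)
        assert vt.kmer_similarity(a, a) == 0.0

    def test_mismatched_k_rejected(self):
        a = vt.kmer_profile(rec("ACGTACGTACGT"), k=10)
        b = vt.kmer_profile(rec("ACGTACGTACGT"), k=9)
        with pytest.raises(ValueError):
            vt.kmer_similarity(a, b)

    def test_matches_naive_oracle_and_symmetric(self, rng):
        for _ in range(40):
            r1 = random_record(rng, int(rng.integers(5, 2000)))
            r2 = random_record(rng, int(rng.integers(5, 2000)))
            a, b = vt.kmer_profile(r1, 10), vt.kmer_profile(r2, 10)
            sim = vt.kmer_similarity(a, b)
            assert sim == vt.kmer_similarity(b, a)
            assert sim == naive_kmer_dice(r1.residues, r2.residues, 10)
            assert 0 <= sim <= 1


class TestSixFrameFragments:
    def test_minimal_frame_one_fragment(self):
        frags = vt.six_frame_fragments(rec("ATGAAATAA"), min_fragment_aa=2)
        assert "MK" in frags

    def test_revcomp_gives_same_multiset(self, rng):
        from Bio.Seq import reverse_complement

        r = random_record(rng, 600)
        f1 = sorted(vt.six_frame_fragments(r))
        f2 = sorted(vt.six_frame_fragments(rec(reverse_complement(r.residues))))
        assert f1 == f2

    def test_ambiguous_codon_translates_to_x(self):
        frags = vt.six_frame_fragments(rec("ATGNNNAAAGGGCCCTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGG"), min_fragment_aa=5)
        assert any("X" in f for f in frags)

    def test_all_stop_frame_contributes_nothing(self):
        # frame +1 of this sequence is TAA TAA TAA TAA: all stops, so it
        # yields no fragment; the other five frames translate cleanly
        frags = vt.six_frame_fragments(rec("TAATAATAATAA"), min_fragment_aa=1)
        assert sorted(frags) == sorted(["NNN", "III", "LLLL", "YYY", "III"])
        assert all("*" not in f for f in frags)


class TestProteinMaxIdentity:
    def test_self_is_100(self):
        coding = rec("ATG" + "GCTTGGAAGCATCGT" * 12 + "TAA")
        assert vt.protein_max_identity(coding, coding) == 100.0

    def test_symmetric(self, rng):
        r1, r2 = random_record(rng, 500, "a"), random_record(rng, 500, "b")
        assert vt.protein_max_identity(r1, r2) == pytest.approx(
            vt.protein_max_identity(r2, r1)
        )

    def test_no_fragments_gives_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = vt.protein_max_identity(rec("ACGTAA"), rec("ACGTAA"))
        assert out == 0.0
        assert "fragments" in caplog.text

    def test_random_noncoding_pair_bounded(self, rng):
        r1, r2 = random_record(rng, 1000, "a"), random_record(rng, 1000, "b")
        ident = vt.protein_max_identity(r1, r2)
        assert 0 <= ident <= 100

    def test_synonymous_recode_conserves_protein_not_kmers(self, rng):
        from virotax.simulate import _build_segment

        seq, spans = _build_segment(rng, 1000, 0.5, 4.0, (150, 210))
        original = rec(seq, "orig")
        recoded = vt.synonymous_recode(original, spans, rng)
        assert vt.protein_max_identity(original, recoded) == 100.0
        sim = vt.kmer_similarity(vt.kmer_profile(original), vt.kmer_profile(recoded))
        assert sim < 0.5


def tiny_assemblies(rng, n=4, length=300):
    asms = []
    for i in range(n):
        r = random_record(rng, length, f"acc{i}")
        ann = vt.TaxonomyAnnotation(
            accession=f"acc{i}", species=f"sp{i}", genus=f"g{i % 2}",
            family=f"f{i % 2}", order="o",
        )
        asms.append(vt.VirusAssembly(f"sp{i}", ann, (r,)))
    return asms


class TestSimilarityMatrix:
    def test_shape_diagonal_symmetry(self, rng):
        m = vt.similarity_matrix(tiny_assemblies(rng), "nucleotide-kmer")
        assert m.values.shape == (4, 4)
        assert (np.diag(m.values) == 1.0).all()
        assert np.allclose(m.values, m.values.T)

    def test_duplicate_genome_maximal_offdiagonal(self, rng):
        asms = tiny_assemblies(rng, n=3)
        dup = vt.VirusAssembly("sp_dup", asms[0].taxonomy, asms[0].segments)
        m = vt.similarity_matrix(asms + [dup], "nucleotide-kmer")
        i, j = m.labels.index("sp0"), m.labels.index("sp_dup")
        assert m.values[i, j] == 1.0

    def test_permutation_conjugates_matrix(self, rng):
        asms = tiny_assemblies(rng)
        m1 = vt.similarity_matrix(asms, "nucleotide-kmer")
        m2 = vt.similarity_matrix(asms[::-1], "nucleotide-kmer")
        perm = [m2.labels.index(lab) for lab in m1.labels]
        assert np.allclose(m1.values, m2.values[np.ix_(perm, perm)])

    def test_protein_matrix_contract(self, rng):
        m = vt.similarity_matrix(tiny_assemblies(rng, n=3), "protein-identity")
        assert (np.diag(m.values) == 100.0).all()
        assert ((m.values >= 0) & (m.values <= 100)).all()

    def test_fewer_than_two_rejected(self, rng):
        with pytest.raises(ValueError):
            vt.similarity_matrix(tiny_assemblies(rng, n=4)[:1], "nucleotide-kmer")


class TestTaxonomyOrder:
    def _matrix_and_anns(self, rng, families):
        asms = []
        for i, fam in enumerate(families):
            r = random_record(rng, 200, f"acc{i}")
            ann = vt.TaxonomyAnnotation(
                accession=f"acc{i}", species=f"sp{i}", genus=f"g_{fam}",
                family=fam, order="o",
            )
            asms.append(vt.VirusAssembly(f"sp{i}", ann, (r,)))
        m = vt.similarity_matrix(asms, "nucleotide-kmer")
        return m, {a.species: a.taxonomy for a in asms}

    def test_sorted_input_unchanged(self, rng):
        m, anns = self._matrix_and_anns(rng, ["famA", "famA", "famB", "famB"])
        out = vt.taxonomy_order(m, anns)
        assert out.labels == m.labels
        assert np.allclose(out.values, m.values)

    def test_interleaved_families_become_contiguous(self, rng):
        m, anns = self._matrix_and_anns(rng, ["famB", "famA", "famB", "famA"])
        out = vt.taxonomy_order(m, anns)
        fams = [anns[lab].family for lab in out.labels]
        assert fams == sorted(fams)
        # conjugation preserves values
        perm = [m.labels.index(lab) for lab in out.labels]
        assert np.allclose(out.values, m.values[np.ix_(perm, perm)])

    def test_idempotent_and_reversal_invariant(self, rng):
        m, anns = self._matrix_and_anns(rng, ["famB", "famA", "famB", "famA"])
        once = vt.taxonomy_order(m, anns)
        twice = vt.taxonomy_order(once, anns)
        assert once.labels == twice.labels

    def test_unannotated_label_rejected(self, rng):
        m, anns = self._matrix_and_anns(rng, ["famA", "famB", "famA", "famB"])
        anns.pop("sp2")
        with pytest.raises(ValueError, match="sp2"):
            vt.taxonomy_order(m, anns)


class TestClusteringContrast:
    def test_block_matrix_maximal(self):
        v = np.zeros((8, 8))
        v[:4, :4] = 1.0
        v[4:, 4:] = 1.0
        np.fill_diagonal(v, 1.0)
        labels = [f"v{i}" for i in range(8)]
        m = SimilarityMatrix(labels, v, "nucleotide-kmer")
        groups = {lab: ("A" if i < 4 else "B") for i, lab in enumerate(labels)}
        contrast, p = vt.clustering_contrast(m, groups, seed=1)
        assert contrast == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_matrix_zero(self):
        v = np.full((6, 6), 0.5)
        labels = [f"v{i}" for i in range(6)]
        m = SimilarityMatrix(labels, v, "nucleotide-kmer")
        groups = {lab: f"g{i % 2}" for i, lab in enumerate(labels)}
        contrast, _ = vt.clustering_contrast(m, groups, seed=1)
        assert contrast == pytest.approx(0.0)

    def test_random_matrix_not_significant(self):
        rng = np.random.default_rng(1)
        n = 20
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        labels = [f"v{i}" for i in range(n)]
        m = SimilarityMatrix(labels, v, "nucleotide-kmer")
        groups = {lab: f"g{i % 4}" for i, lab in enumerate(labels)}
        contrast, p = vt.clustering_contrast(m, groups, seed=1)
        assert abs(contrast) < 0.1
        assert p > 0.05

    def test_degenerate_grouping_rejected(self):
        v = np.eye(4)
        labels = [f"v{i}" for i in range(4)]
        m = SimilarityMatrix(labels, v, "nucleotide-kmer")
        with pytest.raises(ValueError):
            vt.clustering_contrast(m, {lab: "same" for lab in labels}, seed=1)
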