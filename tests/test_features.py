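import numpy as np
import pytest

from conftest import random_sequence
from oracles import canonical_classes, count_kmers_bruteforce

from metacon import errors
from metacon.io import ContigRecord, ContigSet, CoverageMatrix
from metacon.features import (
    CompositionMatrix,
    NucleotideModel,
    add_pseudocounts,
    assemble_features,
    count_canonical_kmers,
    kmer_class_index,
    kmer_probability,
    normalize_columns,
    normalize_coverage,
    nucleotide_model,
    relative_composition,
    split_by_length,
    standardize_composition,
)


class TestCanonicalKmerCounts:
    def test_class_count_formula(self):
        # V = (4^k + 4^(k/2)) / 2 canonical classes for even k
        for k in (2, 4, 6):
            reps, _, pal = kmer_class_index(k)
            assert len(reps) == (4**k + 4 ** (k // 2)) // 2
            assert pal.sum() == 4 ** (k // 2)
            assert list(reps) == sorted(reps)

    def test_hand_enumerated_example(self):
        cs = ContigSet([ContigRecord("c", "AACGTT")])
        Z = count_canonical_kmers(cs, k=2)
        counts = dict(zip(Z.kmer_index, Z.counts[0]))
        assert counts["AA"] == 2  # AA once + TT once
        assert counts["AC"] == 2  # AC once + GT once
        assert counts["CG"] == 1  # palindromic, once per occurrence
        assert sum(counts.values()) == 5  # one per window

    def test_homopolymer(self):
        cs = ContigSet([ContigRecord("c", "AAAA")])
        Z = count_canonical_kmers(cs, k=2)
        assert dict(zip(Z.kmer_index, Z.counts[0]))["AA"] == 3

    @pytest.mark.parametrize("k", [2, 4])
    def test_matches_bruteforce_oracle_on_random_sequences(self, rng, k):
        contigs = ContigSet(
            [
                ContigRecord(f"c{i}", random_sequence(rng, int(rng.integers(50, 800)),
                                                      n_rate=0.02))
                for i in range(25)
            ]
        )
        Z = count_canonical_kmers(contigs, k=k)
        assert tuple(Z.kmer_index) == tuple(canonical_classes(k))
        for c, rec in enumerate(contigs):
            expected = count_kmers_bruteforce(rec.sequence, k)
            got = dict(zip(Z.kmer_index, Z.counts[c]))
            assert got == expected

    def test_window_total_for_n_free_sequence(self, rng):
        seq = random_sequence(rng, 500)
        cs = ContigSet([ContigRecord("c", seq)])
        Z = count_canonical_kmers(cs, k=4)
        assert Z.counts.sum() == len(seq) - 3

    def test_contig_shorter_than_k_gets_zero_row(self):
        cs = ContigSet([ContigRecord("c", "ACG")])
        Z = count_canonical_kmers(cs, k=4)
        assert Z.counts.sum() == 0

    def test_odd_k_rejected(self, tiny_contigs):
        with pytest.raises(ValueError):
            count_canonical_kmers(tiny_contigs, k=3)


class TestPseudocounts:
    def test_values_and_inputs_untouched(self, tiny_contigs, tiny_coverage):
        Z = count_canonical_kmers(tiny_contigs, k=2)
        z0 = Z.counts.copy()
        y0 = tiny_coverage.values.copy()
        Zp, Yp = add_pseudocounts(Z, tiny_coverage)
        np.testing.assert_array_equal(Zp.counts, z0 + 1)
        np.testing.assert_allclose(Yp.values, y0 + 0.01)
        np.testing.assert_array_equal(Z.counts, z0)
        np.testing.assert_allclose(tiny_coverage.values, y0)


class TestCoverageNormalization:
    def test_forced_example(self):
        Yp = CoverageMatrix(np.array([[1.0, 3.0], [3.0, 1.0]]), ["a", "b"], ["c1", "c2"])
        Q = normalize_coverage(Yp)
        np.testing.assert_allclose(Q, [[0.25, 0.75], [0.75, 0.25]])

    def test_single_sample_gives_column_of_ones(self):
        Yp = CoverageMatrix(np.array([[0.5], [2.0], [7.0]]), ["a"], list("xyz"))
        np.testing.assert_allclose(normalize_coverage(Yp), 1.0)

    def test_rows_sum_to_one(self, rng):
        Yp = CoverageMatrix(rng.uniform(0.01, 9, size=(10, 4)),
                            [f"s{i}" for i in range(4)],
                            [f"c{i}" for i in range(10)])
        Q = normalize_coverage(Yp)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_per_sample_rescaling(self, rng):
        vals = rng.uniform(0.01, 9, size=(8, 3))
        ids_s, ids_c = ["a", "b", "c"], [f"c{i}" for i in range(8)]
        Q1 = normalize_coverage(CoverageMatrix(vals, ids_s, ids_c))
        scaled = vals * np.array([3.0, 0.2, 17.0])
        Q2 = normalize_coverage(CoverageMatrix(scaled, ids_s, ids_c))
        np.testing.assert_allclose(Q1, Q2, atol=1e-12)

    def test_rejects_nonpositive(self):
        Yp = CoverageMatrix(np.array([[0.0, 1.0]]), ["a", "b"], ["c"])
        with pytest.raises(ValueError):
            normalize_coverage(Yp)


class TestNucleotideModel:
    def test_unsmoothed(self):
        m = nucleotide_model(ContigRecord("c", "AACG"), smooth=False)
        assert m.probs == {"A": 0.5, "C": 0.25, "G": 0.25, "T": 0.0}

    def test_smoothed_add_one(self):
        m = nucleotide_model(ContigRecord("c", "AACG"))
        assert m.probs == {"A": 3 / 8, "C": 2 / 8, "G": 2 / 8, "T": 1 / 8}

    def test_n_excluded_from_both_sides(self):
        a = nucleotide_model(ContigRecord("c", "AANNCG"))
        b = nucleotide_model(ContigRecord("c", "AACG"))
        assert a.probs == b.probs

    def test_all_n_raises(self):
        with pytest.raises(errors.NoInformativeBasesError):
            nucleotide_model(ContigRecord("c", "NNNN"))


class TestKmerProbability:
    uniform = NucleotideModel({b: 0.25 for b in "ACGT"}, smoothed=True)

    def test_strict_is_plain_product(self):
        assert kmer_probability(self.uniform, "AA", mode="strict") == pytest.approx(1 / 16)

    def test_pair_doubles_nonpalindromes(self):
        assert kmer_probability(self.uniform, "AA", mode="pair") == pytest.approx(1 / 8)

    def test_pair_keeps_palindromes_single(self):
        assert kmer_probability(self.uniform, "AT", mode="pair") == pytest.approx(1 / 16)


class TestStandardize:
    def _uniform_contig(self):
        # 25 of each base so that add-one smoothing keeps p = 1/4 exactly
        return ContigRecord("c", "ACGT" * 25)

    def test_count_equal_to_mean_gives_zero(self):
        # L=80 makes mu = (2/16)*80 = 10 an integer for class AA/TT
        contigs = ContigSet([ContigRecord("c", "ACGT" * 20)])
        reps, _, _ = kmer_class_index(2)
        counts = np.zeros((1, len(reps)), dtype=np.int64)
        idx = reps.index("AA")
        counts[0, idx] = 10
        Z = CompositionMatrix(counts, 2, reps)
        std = standardize_composition(Z, contigs, mode="pair")
        assert std.zscores[0, idx] == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_oracle_for_pair_mode(self):
        # uniform model, L=100, class AA/TT: mu = (2/16)*100 = 12.5,
        # sigma^2 = (2/16)(14/16)*100 = 10.9375; X=10 gives the z-score below
        contigs = ContigSet([self._uniform_contig()])
        reps, _, _ = kmer_class_index(2)
        counts = np.zeros((1, len(reps)), dtype=np.int64)
        idx = reps.index("AA")
        counts[0, idx] = 10
        Z = CompositionMatrix(counts, 2, reps)
        std = standardize_composition(Z, contigs, mode="pair")
        assert std.zscores[0, idx] == pytest.approx((10 - 12.5) / np.sqrt(10.9375))

    def test_strict_mode_statistic_exceeds_pair_mode(self, rng):
        # pooled counts standardized with the single-strand probability are
        # systematically inflated; the pair correction recenters them
        contigs = ContigSet(
            [ContigRecord(f"c{i}", random_sequence(rng, 2000)) for i in range(60)]
        )
        Z = count_canonical_kmers(contigs, k=4)
        pair = standardize_composition(Z, contigs, mode="pair").zscores.mean()
        strict = standardize_composition(Z, contigs, mode="strict").zscores.mean()
        assert strict > pair
        assert strict > 0.5
        assert abs(pair) < 0.2

    def test_zero_variance_only_without_smoothing(self):
        contigs = ContigSet([ContigRecord("c", "AAAA")])
        Z = count_canonical_kmers(contigs, k=2)
        standardize_composition(Z, contigs, smooth=True)  # fine
        with pytest.raises(errors.ZeroVarianceError):
            standardize_composition(Z, contigs, smooth=False)


class TestNormalizeColumns:
    def test_abs_mode_preserves_signs_and_unit_abs_sum(self):
        H = normalize_columns(np.array([[1.0], [1.0], [2.0]]), mode="abs")
        np.testing.assert_allclose(H[:, 0], [0.25, 0.25, 0.5])
        H = normalize_columns(np.array([[3.0], [-1.0]]), mode="abs")
        np.testing.assert_allclose(H[:, 0], [0.75, -0.25])

    def test_strict_mode_zero_denominator_becomes_zero_column(self):
        with pytest.warns(RuntimeWarning):
            H = normalize_columns(np.array([[1.0], [-1.0]]), mode="strict")
        np.testing.assert_array_equal(H[:, 0], [0.0, 0.0])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            normalize_columns(np.array([[np.nan], [1.0]]))


class TestAssembleFeatures:
    def test_concatenation_and_roles(self, rng):
        Q = rng.random((2, 3))
        H = rng.random((2, 5))
        F = assemble_features(Q, H)
        assert F.values.shape == (2, 8)
        assert F.column_roles == (3, 5)
        np.testing.assert_array_equal(F.values[:, :3], Q)

    def test_row_mismatch_and_nan_rejected(self, rng):
        with pytest.raises(errors.DimensionMismatchError):
            assemble_features(rng.random((2, 3)), rng.random((3, 3)))
        bad = rng.random((2, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            assemble_features(bad, rng.random((2, 3)))


class TestSplitByLength:
    def _set(self, lengths):
        return ContigSet(
            [ContigRecord(f"c{i}", "A" * L) for i, L in enumerate(lengths)]
        )

    def test_fixed_threshold(self):
        long_idx, short_idx = split_by_length(self._set([1000, 3000]), 2000)
        assert list(long_idx) == [1]
        assert list(short_idx) == [0]

    def test_no_short_contigs_is_fine(self):
        long_idx, short_idx = split_by_length(self._set([2000, 5000]), 2000)
        assert short_idx.size == 0 and long_idx.size == 2

    def test_all_short_raises(self):
        with pytest.raises(errors.NoLongContigsError):
            split_by_length(self._set([100, 200]), 2000)

    def test_quantile_mode_matches_sort_oracle(self, rng):
        lengths = [int(x) for x in rng.integers(500, 20000, size=100)]
        cs = self._set(lengths)
        long_idx, short_idx = split_by_length(cs, mode="quantile", short_fraction=0.2)
        assert short_idx.size == 20
        order = sorted(range(100), key=lambda i: (lengths[i], i))
        assert set(short_idx) == set(order[:20])
        assert set(long_idx) | set(short_idx) == set(range(100))

    def test_quantile_ties_broken_by_input_order(self):
        cs = self._set([100, 100, 100, 100, 5000])
        long_idx, short_idx = split_by_length(cs, mode="quantile", short_fraction=0.4)
        assert list(short_idx) == [0, 1]


def test_relative_composition_rows_sum_to_one(tiny_contigs, tiny_coverage):
    Z = count_canonical_kmers(tiny_contigs, k=2)
    Zp, _ = add_pseudocounts(Z, tiny_coverage)
    R = relative_composition(Zp)
    np.testing.assert_allclose(R.sum(axis=1), 1.0)
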