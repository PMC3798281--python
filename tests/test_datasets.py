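"""Randomized/scrambled dataset generation and composition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aprstat.datasets import (
    F495_COMPOSITION,
    UNIFORM_COMPOSITION,
    compare_propensity_distributions,
    composition_chi_square,
    compute_composition,
    generate_composition_matched,
    generate_uniform_random,
    kmeans_composition_split,
    scramble_sequence,
)
from aprstat.records import AMINO_ACIDS, SequenceRecord

sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=80)


class TestGenerators:
    def test_shapes_and_alphabet(self):
        seqs = generate_uniform_random(50, 100, seed=0)
        assert len(seqs) == 50
        assert all(len(s) == 100 for s in seqs)
        assert all(set(s.residues) <= set(AMINO_ACIDS) for s in seqs)

    def test_single_residue_boundary(self):
        (s,) = generate_uniform_random(1, 1, seed=3)
        assert len(s) == 1

    @pytest.mark.parametrize("n,length", [(0, 10), (5, 0), (-1, 5)])
    def test_rejects_non_positive(self, n, length):
        with pytest.raises(ValueError):
            generate_uniform_random(n, length, seed=0)

    def test_uniform_composition_law_of_large_numbers(self):
        # pooled composition of 2000 x 100 residues within +/-1% of 5%
        seqs = generate_uniform_random(2000, 100, seed=42)
        comp = compute_composition(seqs)
        assert all(abs(f - 0.05) < 0.01 for f in comp.values())

    def test_matched_composition_recovered(self):
        # 10^6 draws: each pooled frequency within +/-0.5% of the target
        seqs = generate_composition_matched(10_000, 100, F495_COMPOSITION,
                                            seed=7)
        comp = compute_composition(seqs)
        for aa, f in F495_COMPOSITION.items():
            assert abs(comp[aa] - f) < 0.005

    def test_degenerate_composition_homopolymer(self):
        comp = {aa: 0.0 for aa in AMINO_ACIDS}
        comp["W"] = 1.0
        seqs = generate_composition_matched(3, 25, comp, seed=0)
        assert all(s.residues == "W" * 25 for s in seqs)

    def test_invalid_composition_rejected(self):
        bad = {aa: 0.05 for aa in AMINO_ACIDS}
        bad["A"] = 0.10  # sums to 1.05
        with pytest.raises(ValueError):
            generate_composition_matched(2, 10, bad, seed=0)

    def test_seed_reproducibility(self):
        a = generate_uniform_random(20, 60, seed=9)
        b = generate_uniform_random(20, 60, seed=9)
        assert [s.residues for s in a] == [s.residues for s in b]
        c = generate_composition_matched(20, 60, F495_COMPOSITION, seed=9)
        d = generate_composition_matched(20, 60, F495_COMPOSITION, seed=9)
        assert [s.residues for s in c] == [s.residues for s in d]


class TestScramble:
    def test_homopolymer_fixed_point(self):
        parent = SequenceRecord("p", "AAAA")
        for s in scramble_sequence(parent, 5, seed=0):
            assert s.residues == "AAAA"

    def test_hundred_copies(self):
        parent = SequenceRecord("p", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        out = scramble_sequence(parent, 100, seed=1)
        assert len(out) == 100
        assert all(sorted(s.residues) == sorted(parent.residues) for s in out)

    @settings(deadline=None, max_examples=50)
    @given(seq=sequences, seed=st.integers(0, 2**31 - 1))
    def test_multiset_and_length_preserved(self, seq, seed):
        parent = SequenceRecord("p", seq)
        for s in scramble_sequence(parent, 2, seed=seed):
            assert len(s) == len(parent)
            assert sorted(s.residues) == sorted(seq)

    def test_uniform_permutation_empirically(self):
        # the rejection procedure should produce each of the 6 permutations
        # of a 3-distinct-residue parent with ~equal frequency
        parent = SequenceRecord("p", "ACD")
        out = scramble_sequence(parent, 6000, seed=5)
        counts = {}
        for s in out:
            counts[s.residues] = counts.get(s.residues, 0) + 1
        assert len(counts) == 6
        chi2 = sum((c - 1000) ** 2 / 1000 for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=5)

    def test_scramble_preserves_composition_profile(self):
        parent = SequenceRecord("p", "ACDEFGHIKLMNPQRSTVWY" * 3)
        out = scramble_sequence(parent, 10, seed=2)
        assert compute_composition(out) == compute_composition([parent])


class TestComposition:
    def test_two_sequence_counting(self):
        comp = compute_composition([SequenceRecord("a", "AA"),
                                    SequenceRecord("b", "CC")])
        assert comp["A"] == 0.5 and comp["C"] == 0.5
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_counting_oracle(self):
        # 3 A, 2 C, 1 D from hand-built records
        comp = compute_composition([SequenceRecord("a", "AAC"),
                                    SequenceRecord("b", "ACD")])
        assert comp["A"] == pytest.approx(3 / 6)
        assert comp["C"] == pytest.approx(2 / 6)
        assert comp["D"] == pytest.approx(1 / 6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_composition([])


class TestChiSquare:
    def test_natural_vs_uniform_prints_160_84(self):
        chi2 = composition_chi_square(F495_COMPOSITION, UNIFORM_COMPOSITION)
        assert chi2 == pytest.approx(160.84, abs=0.005)

    def test_identical_profiles_zero(self):
        assert composition_chi_square(F495_COMPOSITION, F495_COMPOSITION) == 0

    def test_two_category_hand_arithmetic(self):
        a = {aa: 0.0 for aa in AMINO_ACIDS}
        b = dict(a)
        a.update(A=0.6, C=0.4)
        b.update(A=0.5, C=0.5)
        assert composition_chi_square(a, b) == pytest.approx(40.0)

    def test_goodness_of_fit_is_asymmetric(self):
        ab = composition_chi_square(F495_COMPOSITION, UNIFORM_COMPOSITION)
        ba = composition_chi_square(UNIFORM_COMPOSITION, F495_COMPOSITION)
        assert ab != ba
        assert ab >= 0 and ba >= 0

    def test_observed_mass_on_zero_expected_rejected(self):
        e = {aa: 0.0 for aa in AMINO_ACIDS}
        e.update(A=0.5, C=0.5)
        with pytest.raises(ValueError):
            composition_chi_square(UNIFORM_COMPOSITION, e)


class TestKMeansSplit:
    @staticmethod
    def _enriched(base_aa, seed, n=25, length=600):
        comp = dict(F495_COMPOSITION)
        comp[base_aa] = 0.12
        total = sum(comp.values())
        comp = {k: v / total for k, v in comp.items()}
        return generate_composition_matched(n, length, comp, seed,
                                            id_prefix=base_aa)

    def test_planted_partition_recovered(self):
        lys = self._enriched("K", seed=1)
        ala = self._enriched("A", seed=2)
        split = kmeans_composition_split(lys + ala, k=2, seed=0)
        groups = [set(ids) for ids in split.values()]
        truth = [{s.id for s in lys}, {s.id for s in ala}]
        assert groups in ([truth[0], truth[1]], [truth[1], truth[0]])

    def test_k1_single_cluster(self, small_seqs):
        split = kmeans_composition_split(small_seqs, k=1)
        assert split == {0: [s.id for s in small_seqs]}

    def test_duplicates_share_cluster(self):
        seqs = [SequenceRecord(f"d{i}", "AC" * 30) for i in range(4)]
        seqs += [SequenceRecord(f"k{i}", "KR" * 30) for i in range(4)]
        split = kmeans_composition_split(seqs, k=2, seed=0)
        for ids in split.values():
            kinds = {i[0] for i in ids}
            assert len(kinds) == 1

    def test_k_exceeding_n_rejected(self, small_seqs):
        with pytest.raises(ValueError):
            kmeans_composition_split(small_seqs, k=5)


class TestTTest:
    def test_identical_samples_zero_t(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, p = compare_propensity_distributions(a, list(a))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_identical_degenerate(self):
        t, p = compare_propensity_distributions([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_power_at_unit_effect(self):
        # N(0,1) vs N(1,1), n=200: significant in every one of 50 replicates
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(50):
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            _, p = compare_propensity_distributions(a, b)
            hits += p < 0.05
        assert hits >= 50 * 0.99

    def test_welch_closed_form_oracle(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.7, 2.0, 17)
        t, p = compare_propensity_distributions(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_propensity_distributions([1.0], [1.0, 2.0])
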