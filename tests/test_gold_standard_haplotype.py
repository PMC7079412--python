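"""Haplotype assignment, truth replacement, error-rate titration and
diversity reduction."""
import numpy as np
import pytest

from ecbench import (
    Haplotype,
    Read,
    assign_read,
    build_truth_set,
    dataset_error_rate,
    hamming_fraction,
    make_error_free,
    reduce_haplotype_diversity,
    titrate_error_rate,
)
from ecbench.gold_standard_haplotype import aligned_hamming_fraction
from ecbench.read_simulator import simulate_haplotype_mixture
from ecbench._seq import random_sequence, reverse_complement


def brute_force_assignment(read_seq, haplotypes):
    """All-offsets, both-strands mismatch scan; returns the minimal
    (mismatches, hap_index, offset, strand) tuple."""
    best = None
    for hi, hap in enumerate(haplotypes):
        for strand, seq in ((0, read_seq), (1, reverse_complement(read_seq))):
            for off in range(len(hap.sequence) - len(read_seq) + 1):
                window = hap.sequence[off:off + len(read_seq)]
                mm = sum(a != b for a, b in zip(seq, window))
                key = (mm, hi, off, strand)
                if best is None or key < best:
                    best = key
    return best


class TestAssignment:
    def test_exact_substring_wins(self, rng):
        h1 = Haplotype("h1", random_sequence(500, rng))
        h2 = Haplotype("h2", random_sequence(500, rng))
        read = Read("r", h1.sequence[100:200])
        asg = assign_read(read, [h1, h2])
        assert asg.haplotype == "h1"
        assert asg.offset == 100
        assert asg.mismatches == 0
        assert asg.strand == "+"

    def test_tie_goes_to_first_haplotype(self, rng):
        seq = random_sequence(300, rng)
        h1 = Haplotype("first", seq)
        h2 = Haplotype("second", seq)
        asg = assign_read(Read("r", seq[50:150]), [h1, h2])
        assert asg.haplotype == "first"

    def test_reverse_strand_detected(self, rng):
        hap = Haplotype("h", random_sequence(400, rng))
        read = Read("r", reverse_complement(hap.sequence[120:220]))
        asg = assign_read(read, [hap])
        assert asg.strand == "-" and asg.offset == 120 and asg.mismatches == 0

    def test_unrelated_read_is_unmapped(self, rng):
        haps = [Haplotype(f"h{i}", random_sequence(1000, rng)) for i in range(3)]
        read = Read("r", random_sequence(100, rng))
        best = brute_force_assignment(read.sequence, haps)
        assert best[0] / 100 > 0.1  # brute-force confirms no close placement
        assert assign_read(read, haps, max_mismatch_frac=0.1) is None

    def test_agrees_with_brute_force_scan(self, rng):
        haps = [Haplotype(f"h{i}", random_sequence(800, rng)) for i in range(2)]
        for _ in range(25):
            hi = int(rng.integers(0, 2))
            off = int(rng.integers(0, 800 - 80 + 1))
            seq = list(haps[hi].sequence[off:off + 80])
            for p in rng.choice(80, size=4, replace=False):
                seq[p] = "ACGT"[(("ACGT".index(seq[p])) + 1) % 4]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            asg = assign_read(Read("r", seq), haps, max_mismatch_frac=1.0)
            mm, bhi, boff, bstrand = brute_force_assignment(seq, haps)
            assert asg.mismatches == mm
            assert asg.haplotype == haps[bhi].name
            assert asg.offset == boff
            assert asg.strand == ("+" if bstrand == 0 else "-")


class TestTruthReplacement:
    def test_true_read_is_haplotype_window(self, rng):
        hap = Haplotype("h", random_sequence(600, rng))
        seq = list(hap.sequence[200:300])
        for p in (3, 40, 77):
            seq[p] = "ACGT"[("ACGT".index(seq[p]) + 2) % 4]
        read = Read("r", "".join(seq))
        asg = assign_read(read, [hap])
        true = make_error_free(read, asg, [hap])
        assert true.sequence == hap.sequence[200:300]
        assert sum(a != b for a, b in zip(read.sequence, true.sequence)) == 3
        assert true.name == "r"

    def test_zero_mismatch_read_unchanged(self, rng):
        hap = Haplotype("h", random_sequence(300, rng))
        read = Read("r", hap.sequence[10:110])
        asg = assign_read(read, [hap])
        assert make_error_free(read, asg, [hap]).sequence == read.sequence

    def test_minus_strand_truth_is_reverse_complement(self, rng):
        hap = Haplotype("h", random_sequence(400, rng))
        window = hap.sequence[50:150]
        read = Read("r", reverse_complement(window))
        asg = assign_read(read, [hap])
        true = make_error_free(read, asg, [hap])
        # independent reverse complement
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert true.sequence == "".join(comp[b] for b in reversed(window))


class TestTitration:
    def _fixture(self, seed=31, n_reads=100, err=0.01):
        _, reads, origins = simulate_haplotype_mixture(
            hap_len=2000, divergence=0.01, n_reads=n_reads, read_len=100,
            err_rate=err, seed=seed,
        )
        true = [Read(r.name, o.true_sequence) for r, o in zip(reads, origins)]
        return reads, true

    def test_target_zero_full_correction(self):
        raw, true = self._fixture()
        out = titrate_error_rate(raw, true, 0.0, np.random.default_rng(1))
        assert [r.sequence for r in out] == [t.sequence for t in true]

    def test_target_equal_current_is_noop(self):
        raw, true = self._fixture()
        current = dataset_error_rate(raw, true)
        out = titrate_error_rate(raw, true, current, np.random.default_rng(1))
        assert [r.sequence for r in out] == [r.sequence for r in raw]

    def test_exact_residual_error_count(self):
        raw, true = self._fixture(n_reads=1000)
        total = sum(len(r) for r in raw)
        target = 0.005
        out = titrate_error_rate(raw, true, target, np.random.default_rng(2))
        residual = sum(
            sum(a != b for a, b in zip(r.sequence, t.sequence))
            for r, t in zip(out, true)
        )
        assert residual == round(target * total)

    def test_never_touches_correct_bases_or_creates_errors(self):
        raw, true = self._fixture()
        out = titrate_error_rate(raw, true, 0.002, np.random.default_rng(3))
        for before, after, t in zip(raw, out, true):
            for b, a, tb in zip(before.sequence, after.sequence, t.sequence):
                if b == tb:
                    assert a == b  # correct base untouched
                else:
                    assert a in (b, tb)  # error either kept or reverted

    def test_target_above_current_rejected(self):
        raw, true = self._fixture(err=0.001)
        with pytest.raises(ValueError, match="exceeds"):
            titrate_error_rate(raw, true, 0.5, np.random.default_rng(4))


class TestDiversityReduction:
    def _fixture(self, seed=41):
        haps, reads, origins = simulate_haplotype_mixture(
            hap_len=3000, divergence=0.01, n_reads=120, read_len=100,
            err_rate=0.02, seed=seed,
        )
        hap_a = Haplotype(*haps[0])
        hap_b = Haplotype(*haps[1])
        kept, truth, assignments, _ = build_truth_set(
            reads, [hap_a, hap_b], max_mismatch_frac=0.2
        )
        return hap_a, hap_b, list(zip(kept, assignments)), truth

    def test_hits_requested_hamming_exactly(self):
        hap_a, hap_b, pairs, _ = self._fixture()
        L = len(hap_b.sequence)
        target = 0.005
        new_b, _ = reduce_haplotype_diversity(
            hap_a, hap_b, target, pairs, np.random.default_rng(5)
        )
        observed = hamming_fraction(hap_a.sequence, new_b.sequence)
        assert observed == round(target * L) / L

    def test_target_equal_current_is_noop(self):
        hap_a, hap_b, pairs, _ = self._fixture()
        current = hamming_fraction(hap_a.sequence, hap_b.sequence)
        new_b, new_reads = reduce_haplotype_diversity(
            hap_a, hap_b, current, pairs, np.random.default_rng(6)
        )
        assert new_b.sequence == hap_b.sequence
        assert [r.sequence for r in new_reads] == [r.sequence for r, _ in pairs]

    def test_per_read_error_counts_preserved(self):
        hap_a, hap_b, pairs, _ = self._fixture()
        haps_old = {"hapA": hap_a, "hapB": hap_b}
        new_b, new_reads = reduce_haplotype_diversity(
            hap_a, hap_b, 0.004, pairs, np.random.default_rng(7)
        )
        haps_new = {"hapA": hap_a, "hapB": new_b}

        def errors(read, asg, haps):
            truth = make_error_free(read, asg, list(haps.values()))
            return sum(a != b for a, b in zip(read.sequence, truth.sequence))

        for (read, asg), new_read in zip(pairs, new_reads):
            assert errors(read, asg, haps_old) == errors(new_read, asg, haps_new)

    def test_errors_reintroduced_not_fixed(self):
        # a read base that was an error before an edited column must still
        # differ from the new truth at that column afterwards
        hap_a, hap_b, pairs, _ = self._fixture()
        new_b, new_reads = reduce_haplotype_diversity(
            hap_a, hap_b, 0.0, pairs, np.random.default_rng(8)
        )
        assert new_b.sequence == hap_a.sequence
        for (read, asg), new_read in zip(pairs, new_reads):
            if asg.haplotype != "hapB":
                continue
            old_truth = make_error_free(read, asg, [hap_a, hap_b])
            new_truth = make_error_free(new_read, asg, [hap_a, new_b])
            for i, (b_old, t_old) in enumerate(zip(read.sequence, old_truth.sequence)):
                if b_old != t_old:
                    assert new_read.sequence[i] != new_truth.sequence[i]

    def test_unequal_lengths_rejected(self, rng):
        a = Haplotype("a", random_sequence(100, rng))
        b = Haplotype("b", random_sequence(99, rng))
        with pytest.raises(ValueError, match="equal length"):
            reduce_haplotype_diversity(a, b, 0.0, [], np.random.default_rng(9))


class TestHamming:
    def test_identical(self):
        assert hamming_fraction("ACGT", "ACGT") == 0.0

    def test_one_of_four(self):
        assert hamming_fraction("ACGT", "ACGA") == 0.25

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming_fraction("ACGT", "ACG")

    def test_random_pair_near_three_quarters(self, rng):
        n = 10_000
        a = random_sequence(n, rng)
        b = random_sequence(n, rng)
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(hamming_fraction(a, b) - 0.75) <= 4 * sigma

    def test_aligned_hamming_excludes_gap_columns(self):
        a = "ACGTACGTACGT"
        b = "ACGTCGTACGT"  # one deletion, otherwise identical
        assert aligned_hamming_fraction(a, b) == 0.0
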