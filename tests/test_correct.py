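import numpy as np
import pytest

from conftest import em_system

from rekmer.correct import (
    correct_read,
    correct_reads,
    kmer_position_posterior,
    posterior_matrix,
    read_base_posterior,
)
from rekmer.em import run_em
from rekmer.io import Read, decode_kmer


class TestKmerPositionPosterior:
    def test_self_only_neighborhood_is_point_mass(self):
        spectrum, rows = em_system(["ACGTT"], 5, 0.01)
        T = spectrum.Y.astype(float)
        post = kmer_position_posterior(0, 0, spectrum, T, rows)
        assert post.tolist() == [1.0, 0.0, 0.0, 0.0]  # observed base A

    def test_two_kmer_hand_arithmetic(self):
        # observed AAC (T=1) with neighbor AAA (T=500), uniform p_e = 0.01:
        # at position 3 the posterior strongly favors A
        spectrum, rows = em_system(["AAA", "AAC"], 3, 0.01)
        idx = {decode_kmer(int(c), 3): i for i, c in enumerate(spectrum.codes)}
        T = np.zeros(2)
        T[idx["AAA"]], T[idx["AAC"]] = 500.0, 1.0
        # per-source normalized weights, restricted to the two observed kmers
        raw_self = 0.99**3
        raw_sub = (0.01 / 3) * 0.99**2
        w_aaa_to_aac = raw_sub / (raw_self + raw_sub)
        w_aac_to_aac = raw_self / (raw_self + raw_sub)
        num_a = 500.0 * w_aaa_to_aac
        num_c = 1.0 * w_aac_to_aac
        post = kmer_position_posterior(idx["AAC"], 2, spectrum, T, rows)
        assert post[0] == pytest.approx(num_a / (num_a + num_c), rel=1e-12)
        assert post[1] == pytest.approx(num_c / (num_a + num_c), rel=1e-12)
        assert post[0] > 0.6

    def test_posteriors_sum_to_one(self, rng):
        from conftest import random_reads

        spectrum, rows = em_system(random_reads(rng, 40, 12), 5, 0.02)
        T = spectrum.Y.astype(float)
        P, _ = posterior_matrix(spectrum, T, rows)
        np.testing.assert_allclose(P.sum(axis=2), 1.0, atol=1e-9)

    def test_zero_mass_falls_back_to_observed_base(self):
        spectrum, rows = em_system(["ACGTT"], 5, 0.01)
        post = kmer_position_posterior(0, 1, spectrum, np.zeros(1), rows)
        assert post.tolist() == [0.0, 1.0, 0.0, 0.0]  # observed base C


class TestReadBasePosterior:
    def test_read_end_equals_single_window(self):
        spectrum, rows = em_system(["ACGTA", "ACGTC"], 3, 0.01)
        T = spectrum.Y.astype(float)
        read = Read("r", "ACGTA")
        # position 0 is covered only by the first window
        l0 = int(spectrum.index_of(np.array([spectrum.codes[0]]))[0])
        from rekmer.spectrum import window_codes
        from rekmer.io import reads_to_matrix

        codes = window_codes(reads_to_matrix([read]), 3)[0]
        first = int(spectrum.index_of(codes[:1])[0])
        expected = kmer_position_posterior(first, 0, spectrum, T, rows)
        np.testing.assert_allclose(
            read_base_posterior(read, 0, spectrum, T, rows), expected, atol=1e-12
        )

    def test_interior_position_averages_windows(self):
        spectrum, rows = em_system(["ACGTA", "AGGTA", "ACGTT"], 3, 0.02)
        T = spectrum.Y.astype(float) + np.arange(spectrum.n)  # break symmetry
        read = Read("r", "ACGTA")
        from rekmer.spectrum import window_codes
        from rekmer.io import reads_to_matrix

        codes = window_codes(reads_to_matrix([read]), 3)[0]
        # position 2 is covered by windows starting at 0, 1, 2 (t = 2, 1, 0)
        expected = np.zeros(4)
        for j, t in [(0, 2), (1, 1), (2, 0)]:
            l = int(spectrum.index_of(codes[j : j + 1])[0])
            expected += kmer_position_posterior(l, t, spectrum, T, rows)
        expected /= 3
        np.testing.assert_allclose(
            read_base_posterior(read, 2, spectrum, T, rows), expected, atol=1e-12
        )

    def test_short_read_errors(self):
        spectrum, rows = em_system(["ACGTA"], 3, 0.01)
        with pytest.raises(ValueError):
            read_base_posterior(Read("r", "AC"), 0, spectrum, spectrum.Y.astype(float), rows)


class TestCorrectRead:
    def test_error_free_unique_kmers_untouched(self):
        spectrum, rows = em_system(["ACGTACGTAA"], 4, 0.005)
        T = spectrum.Y.astype(float)
        out, records = correct_read(Read("r", "ACGTACGTAA"), spectrum, T, rows)
        assert out.seq == "ACGTACGTAA"
        assert records == []

    def test_tie_retains_observed_base(self):
        # two kmers, symmetric weights and equal T: position 2 posterior ties
        spectrum, rows = em_system(["AAA", "AAC"], 3, 0.01)
        T = np.array([1.0, 1.0])
        out, records = correct_read(Read("r", "AAC"), spectrum, T, rows)
        # positions 0,1 favor A already; position 2: exact tie -> keep C
        assert out.seq == "AAC"
        assert records == []

    def test_planted_substitution_in_repeat_context_recovered(self):
        """One misread copy among 500 repeats is corrected back."""
        true = "ACGTTGCACGGAT"  # 13 bp
        mutant = true[:6] + "A" + true[7:]
        reads = [Read(f"r{i}", true) for i in range(500)] + [Read("mut", mutant)]
        spectrum, rows = em_system([r.seq for r in reads], 13, 0.01)
        est = run_em(spectrum, rows)
        corrected, records = correct_reads(reads, spectrum, est.T, rows, liberal_M=np.inf)
        assert corrected[-1].seq == true
        assert [(r.read_id, r.position, r.from_base, r.to_base) for r in records] == [
            ("mut", 6, "A", "C")
        ]


class TestCorrectReads:
    def test_liberal_threshold_limits(self):
        reads = [Read("a", "AAAAA"), Read("b", "AAACA")]
        spectrum, rows = em_system([r.seq for r in reads], 4, 0.01)
        T = spectrum.Y.astype(float)
        out, records = correct_reads(reads, spectrum, T, rows, liberal_M=0.0)
        assert [r.seq for r in out] == [r.seq for r in reads]
        assert records == []

    def test_prefilter_equals_full_run_on_entering_reads(self):
        rng = np.random.default_rng(5)
        genome = "".join(rng.choice(list("ACGT"), size=300))
        reads = []
        for i in range(150):
            s = int(rng.integers(0, 300 - 20))
            seq = list(genome[s : s + 20])
            if rng.random() < 0.3:
                j = int(rng.integers(0, 20))
                seq[j] = "ACGT"[(("ACGT".index(seq[j])) + 1) % 4]
            reads.append(Read(f"r{i}", "".join(seq)))
        spectrum, rows = em_system([r.seq for r in reads], 9, 0.01)
        est = run_em(spectrum, rows)
        M = 3.0
        filtered, _ = correct_reads(reads, spectrum, est.T, rows, liberal_M=M)
        full, _ = correct_reads(reads, spectrum, est.T, rows, liberal_M=np.inf)
        from rekmer.spectrum import window_codes
        from rekmer.io import reads_to_matrix

        codes = window_codes(reads_to_matrix(reads), 9)
        enters = (est.T[spectrum.index_of(codes.ravel()).reshape(codes.shape)] < M).any(1)
        for i, entered in enumerate(enters):
            if entered:
                assert filtered[i].seq == full[i].seq
            else:
                assert filtered[i].seq == reads[i].seq

    def test_output_ids_and_lengths_preserved(self):
        reads = [Read("a", "AAAAAA"), Read("b", "AAAAAC")]
        spectrum, rows = em_system([r.seq for r in reads], 5, 0.02)
        out, _ = correct_reads(reads, spectrum, spectrum.Y.astype(float), rows, np.inf)
        assert [(r.id, len(r.seq)) for r in out] == [("a", 6), ("b", 6)]
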