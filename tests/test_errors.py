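import itertools

import numpy as np
import pytest

from rekmer.errors import (
    PositionalErrorModel,
    ReadErrorProfile,
    UniformErrorModel,
    estimate_positional_rates,
    estimate_read_profile,
    load_error_table,
    load_packaged_profile,
    positional_misread_prob,
    save_error_table,
    uniform_misread_prob,
)
from rekmer.io import encode_kmer


def stochastic_q(rng, k, max_err=0.05):
    """Random positional tables with dominant diagonals."""
    q = np.empty((k, 4, 4))
    for i in range(k):
        for a in range(4):
            off = rng.uniform(0, max_err / 3, 3)
            row = np.insert(off, a, 1.0 - off.sum())
            q[i, a] = row
    return q


class TestUniformModel:
    def test_worked_arithmetic(self):
        m = UniformErrorModel(0.006)
        aaa, aac = encode_kmer("AAA"), encode_kmer("AAC")
        assert uniform_misread_prob(aaa, aaa, m, 3) == pytest.approx(0.982107784)
        assert uniform_misread_prob(aaa, aac, m, 3) == pytest.approx(0.001976072)
        # symmetry
        assert m.misread_prob(aac, aaa, 3) == m.misread_prob(aaa, aac, 3)

    def test_zero_rate_limits(self):
        m = UniformErrorModel(0.0)
        assert m.misread_prob(encode_kmer("ACG"), encode_kmer("ACG"), 3) == 1.0
        assert m.misread_prob(encode_kmer("ACG"), encode_kmer("ACT"), 3) == 0.0

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            UniformErrorModel(0.75)
        with pytest.raises(ValueError):
            UniformErrorModel(-0.1)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_full_ball_normalization(self, k):
        """Misread probabilities over all 4^k targets sum to 1."""
        m = UniformErrorModel(0.01)
        src = encode_kmer("A" * k)
        targets = np.arange(4**k, dtype=np.int64)
        assert m.misread_prob(np.full(4**k, src), targets, k).sum() == pytest.approx(1.0)


class TestPositionalModel:
    def test_published_position11_row(self):
        q = load_packaged_profile("ecoli_pos11")
        # published substitution estimates at kmer position 11 (1-based)
        np.testing.assert_allclose(q[10, 0], [0.9896, 0.0063, 0.0018, 0.0023])
        model = PositionalErrorModel(q[10][None])  # single-position model
        assert positional_misread_prob(
            encode_kmer("A"), encode_kmer("C"), model
        ) == pytest.approx(0.0063)

    def test_identity_model_probability_one(self):
        q = np.zeros((3, 4, 4))
        q[:, range(4), range(4)] = 1.0
        model = PositionalErrorModel(q)
        code = encode_kmer("ACG")
        assert model.misread_prob(code, code) == 1.0

    def test_k2_product_vs_hand(self, rng):
        q = stochastic_q(rng, 2)
        model = PositionalErrorModel(q)
        # AC -> GT: q_1(A,G) * q_2(C,T)
        expected = q[0, 0, 2] * q[1, 1, 3]
        assert model.misread_prob(encode_kmer("AC"), encode_kmer("GT")) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_full_ball_normalization(self, k, rng):
        model = PositionalErrorModel(stochastic_q(rng, k))
        src = encode_kmer("C" * k)
        targets = np.arange(4**k, dtype=np.int64)
        assert model.misread_prob(np.full(4**k, src), targets).sum() == pytest.approx(1.0)

    def test_uniform_equals_flat_positional(self, rng):
        """Positional model with diagonal 1-p collapses to the uniform model."""
        p = 0.013
        uni = UniformErrorModel(p)
        pos = uni.as_positional(7)
        src = rng.integers(0, 4**7, 30).astype(np.int64)
        tgt = rng.integers(0, 4**7, 30).astype(np.int64)
        np.testing.assert_allclose(
            uni.misread_prob(src, tgt, 7), pos.misread_prob(src, tgt), atol=1e-12
        )

    def test_not_symmetric_in_general(self):
        q = load_packaged_profile("ecoli_pos11")
        model = PositionalErrorModel(q[10][None])
        a, c = encode_kmer("A"), encode_kmer("C")
        assert model.misread_prob(a, c) != model.misread_prob(c, a)


class TestEstimation:
    def test_hand_count_k1(self):
        model = estimate_positional_rates([("AA", "AC")], k=1)
        assert model.q[0, 0, 0] == pytest.approx(0.5)
        assert model.q[0, 0, 1] == pytest.approx(0.5)

    def test_error_free_gives_identity(self):
        model = estimate_positional_rates([("ACGT", "ACGT"), ("GGTT", "GGTT")], k=2)
        for i in range(2):
            np.testing.assert_allclose(model.q[i], np.eye(4))

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            estimate_positional_rates([], k=3)
        with pytest.raises(ValueError):
            estimate_read_profile([], L=3)

    def test_positional_recovery(self, rng):
        """Re-estimating from simulated alignments recovers the tables."""
        k = 4
        q = stochastic_q(rng, k, max_err=0.06)
        n = 100_000 // k
        ref = rng.integers(0, 4, (n, k))
        u = rng.random((n, k))
        cum = np.cumsum(q, axis=2)
        read = np.empty_like(ref)
        for i in range(k):
            read[:, i] = (u[:, i, None] > cum[i, ref[:, i]]).sum(axis=1)
        bases = "ACGT"
        pairs = [
            ("".join(bases[b] for b in r), "".join(bases[b] for b in s))
            for r, s in zip(ref, read)
        ]
        est = estimate_positional_rates(pairs, k=k)
        assert np.abs(est.q - q).max() < 0.01

    def test_read_profile_hand_count(self):
        # one substitution at read position 5 among 10 reads, ref base A there
        ref = "CCCCCACC"
        reads = [ref] * 9 + ["CCCCCGCC"]
        prof = estimate_read_profile([(ref, r) for r in reads], L=8)
        assert prof.M[5, 0, 2] == pytest.approx(0.1)
        assert prof.M[5, 0, 0] == pytest.approx(0.9)
        np.testing.assert_allclose(prof.M[0], np.eye(4))

    def test_kmer_windowing_weights_interior_positions(self):
        """A substitution mid-read hits several kmer positions once each."""
        # L=3, k=2: read position 1 occurs at kmer positions 0 and 1
        model = estimate_positional_rates([("AAA", "ATA")], k=2)
        # windows: (AA, AT) at start 0, (AA, TA) at start 1
        assert model.q[1, 0, 3] == pytest.approx(0.5)  # pos 1: A->T once of two
        assert model.q[0, 0, 3] == pytest.approx(0.5)


class TestSerialization:
    def test_table_roundtrip(self, tmp_path, rng):
        q = stochastic_q(rng, 3)
        save_error_table(tmp_path / "q.tsv", q)
        np.testing.assert_allclose(load_error_table(tmp_path / "q.tsv"), q, atol=1e-9)
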