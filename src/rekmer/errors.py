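"""Substitution (misread) error models for kmers and reads.

Two models are supported.  The uniform model assumes errors strike every
site independently at a constant per-base rate ``p_e``, giving the
symmetric misread probability

    p_e(x_m -> x_l) = (p_e/3)^d * (1 - p_e)^(k-d),   d = Hamming(x_m, x_l).

The positional model lets the substitution pattern vary along the kmer:
``q_i(a, b)`` is the probability that true base ``a`` at kmer position
``i`` is read as ``b`` (each row sums to 1), and the kmer misread
probability is the product over positions.  These probabilities are no
longer symmetric.  Insertions and deletions are outside the model: on the
Illumina-style platforms it targets they are rare relative to
substitutions.

Both model classes expose ``misread_prob(src, tgt, k)`` on vectorized
2-bit kmer codes; the free functions mirror that API one pair at a time.

A read-position profile (``ReadErrorProfile``) is the same object indexed
by position in the full-length read instead of the kmer; the simulator
consumes it, and :func:`estimate_read_profile` trains it from alignments.
Note the kmer-position model is a genuine approximation of the
read-position process — a base at read position ``j`` appears at up to
``k`` different kmer positions — so even a profile trained on the very
reads being corrected is not an exact description of their errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import BASES, encode_bases

logger = logging.getLogger(__name__)

_ROW_TOL = 1e-9


def _hamming_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamming distance between 2-bit-encoded kmers (vectorized)."""
    x = np.bitwise_xor(a, b).astype(np.uint64)
    # collapse each 2-bit base field to its low bit, then popcount
    y = (x | (x >> np.uint64(1))) & np.uint64(0x5555555555555555)
    return np.bitwise_count(y).astype(np.int64)


@dataclass(frozen=True)
class UniformErrorModel:
    """Constant per-base substitution rate; each wrong base equally likely."""

    p_e: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_e < 0.75):
            raise ValueError("p_e must lie in [0, 0.75)")

    def misread_prob(self, src, tgt, k: int) -> np.ndarray | float:
        src_a = np.asarray(src, dtype=np.int64)
        tgt_a = np.asarray(tgt, dtype=np.int64)
        d = _hamming_codes(src_a, tgt_a)
        out = (self.p_e / 3.0) ** d * (1.0 - self.p_e) ** (k - d)
        return out if out.ndim else float(out)

    def as_positional(self, k: int) -> "PositionalErrorModel":
        """Equivalent positional model: every q_i has diagonal 1-p_e."""
        q = np.full((k, 4, 4), self.p_e / 3.0)
        for b in range(4):
            q[:, b, b] = 1.0 - self.p_e
        return PositionalErrorModel(q)


@dataclass(frozen=True)
class PositionalErrorModel:
    """Position-specific 4x4 substitution tables along the kmer.

    ``q[i, a, b]`` = P(true base a at kmer position i read as b).
    """

    q: np.ndarray  # (k, 4, 4)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 3 or q.shape[1:] != (4, 4):
            raise ValueError("q must have shape (k, 4, 4)")
        if (q < 0).any():
            raise ValueError("q entries must be non-negative")
        if np.abs(q.sum(axis=2) - 1.0).max() > _ROW_TOL:
            raise ValueError("each row of each q_i must sum to 1")
        diag = q[:, range(4), range(4)]
        if (diag <= 0.5).any():
            # sequencing should be mostly correct; tiny training sets can
            # legitimately produce extreme rows, so warn rather than refuse
            logger.warning(
                "positional model has %d diagonal entr(ies) <= 0.5",
                int((diag <= 0.5).sum()),
            )
        object.__setattr__(self, "q", q)

    @property
    def k(self) -> int:
        return self.q.shape[0]

    def misread_prob(self, src, tgt, k: int | None = None) -> np.ndarray | float:
        k = self.k if k is None else k
        if k != self.k:
            raise ValueError(f"model is for k={self.k}, got k={k}")
        src_a = np.asarray(src, dtype=np.int64)
        tgt_a = np.asarray(tgt, dtype=np.int64)
        out = np.ones(np.broadcast(src_a, tgt_a).shape, dtype=float)
        for i in range(k):
            shift = 2 * (k - 1 - i)
            sb = (src_a >> shift) & 3
            tb = (tgt_a >> shift) & 3
            out *= self.q[i, sb, tb]
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ReadErrorProfile:
    """Per-read-position misread matrices M_1..M_L (simulator input)."""

    M: np.ndarray  # (L, 4, 4)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 3 or M.shape[1:] != (4, 4):
            raise ValueError("M must have shape (L, 4, 4)")
        if np.abs(M.sum(axis=2) - 1.0).max() > _ROW_TOL:
            raise ValueError("each row of each M_i must sum to 1")
        object.__setattr__(self, "M", M)

    @property
    def L(self) -> int:
        return self.M.shape[0]

    @property
    def mean_error_rate(self) -> float:
        diag = self.M[:, range(4), range(4)]
        return float(1.0 - diag.mean())


def uniform_misread_prob(src, tgt, model: UniformErrorModel, k: int):
    return model.misread_prob(src, tgt, k)


def positional_misread_prob(src, tgt, model: PositionalErrorModel):
    return model.misread_prob(src, tgt)


# ---------------------------------------------------------------------------
# training from alignments
# ---------------------------------------------------------------------------


def _alignment_matrices(alignments: Iterable[tuple[str, str]]):
    pairs = list(alignments)
    if not pairs:
        raise ValueError("empty alignment table")
    by_len: dict[int, list[tuple[str, str]]] = {}
    for ref, read in pairs:
        if len(ref) != len(read):
            raise ValueError("aligned ref/read lengths differ (substitutions only)")
        by_len.setdefault(len(ref), []).append((ref, read))
    for L, grp in by_len.items():
        ref_m = np.vstack([encode_bases(r) for r, _ in grp])
        read_m = np.vstack([encode_bases(s) for _, s in grp])
        yield L, ref_m, read_m


def _normalize_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Turn (P, 4, 4) substitution counts into stochastic matrices.

    Zero-denominator rows default to the identity row.
    """
    counts = counts + pseudocount
    denom = counts.sum(axis=2, keepdims=True)
    q = np.where(denom > 0, counts / np.where(denom > 0, denom, 1.0), 0.0)
    for i in range(counts.shape[0]):
        for a in range(4):
            if denom[i, a, 0] == 0:
                q[i, a] = 0.0
                q[i, a, a] = 1.0
    return q


def estimate_positional_rates(
    alignments: Iterable[tuple[str, str]], k: int, pseudocount: float = 0.0
) -> PositionalErrorModel:
    """ML estimate of the kmer-position tables q_i from aligned pairs.

    Each aligned read of length L is decomposed into its L-k+1 kmer
    windows; a base at read position j contributes a (ref->read) count at
    kmer position i for every window placing it at position i — i.e. the
    same nucleotide contributes to up to k distinct kmers.
    """
    counts = np.zeros((k, 4, 4))
    for L, ref_m, read_m in _alignment_matrices(alignments):
        if L < k:
            raise ValueError(f"aligned length {L} shorter than k={k}")
        n_win = L - k + 1
        idx = ref_m * 4 + read_m  # (n, L) in 0..15
        for i in range(k):
            # read positions that can sit at kmer position i: [i, i + n_win)
            col = idx[:, i : i + n_win]
            counts[i] += np.bincount(col.ravel(), minlength=16).reshape(4, 4)
    return PositionalErrorModel(_normalize_counts(counts, pseudocount))


def estimate_read_profile(
    alignments: Iterable[tuple[str, str]], L: int, pseudocount: float = 0.0
) -> ReadErrorProfile:
    """ML estimate of per-read-position misread matrices M_i."""
    counts = np.zeros((L, 4, 4))
    for length, ref_m, read_m in _alignment_matrices(alignments):
        if length != L:
            raise ValueError(f"aligned length {length} != L={L}")
        idx = ref_m * 4 + read_m
        for i in range(L):
            counts[i] += np.bincount(idx[:, i], minlength=16).reshape(4, 4)
    return ReadErrorProfile(_normalize_counts(counts, pseudocount))


# ---------------------------------------------------------------------------
# serialization (shared TSV layout for q_i tables and read profiles)
# ---------------------------------------------------------------------------


def save_error_table(path: str | Path, mats: np.ndarray) -> None:
    """Write (P, 4, 4) tables as TSV: position, true base, p(A) p(C) p(G) p(T)."""
    mats = np.asarray(mats)
    with open(path, "w") as fh:
        fh.write("position\tbase\tA\tC\tG\tT\n")
        for i in range(mats.shape[0]):
            for a in range(4):
                probs = "\t".join(f"{p:.10g}" for p in mats[i, a])
                fh.write(f"{i}\t{BASES[a]}\t{probs}\n")


def load_error_table(path: str | Path) -> np.ndarray:
    rows: dict[tuple[int, int], list[float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("position"):
            raise ValueError(f"{path}: missing error-table header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pos, base = int(parts[0]), BASES.index(parts[1])
            rows[(pos, base)] = [float(x) for x in parts[2:6]]
    P = max(p for p, _ in rows) + 1
    mats = np.zeros((P, 4, 4))
    for (pos, base), probs in rows.items():
        mats[pos, base] = probs
    return mats


def read_alignment_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a (ref_substring, read_seq[, strand]) TSV alignment table."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append((parts[0].strip().upper(), parts[1].strip().upper()))
    return out


def load_packaged_profile(name: str) -> np.ndarray:
    """Load one of the bundled illustrative q-tables (see ``rekmer/data``).

    Available names: ``ecoli_pos11``, ``adp1_pos11``.  Only kmer position
    11 (1-based) of each table comes from published Illumina substitution
    estimates; all other positions are identity rows, which makes the
    tables synthetic stand-ins suitable for demonstrations and unit tests,
    not for inference on real data.
    """
    fname = {
        "ecoli_pos11": "q_ecoli_pos11_synthetic.tsv",
        "adp1_pos11": "q_adp1_pos11_synthetic.tsv",
    }[name]
    ref = resources.files("rekmer.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return load_error_table(p)
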