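"""kmer spectrum counting and Hamming-ball misread neighborhoods.

The spectrum of a read set is the multiset of all length-k windows of all
reads; only observed kmers (count >= 1) are stored, as sorted 2-bit codes
with their counts Y_l.  The neighborhood structure restricts the full
4^k x 4^k misread matrix to pairs of *observed* kmers within Hamming
distance ``d_max`` and renormalizes.

Normalization contract: for each SOURCE kmer x_m, the stored weights
w(m -> l) over all observed targets x_l in its ball sum to 1.  This is the
truncated-and-renormalized row of the misread matrix that lists all ways
x_m can be (mis)read, restricted to outcomes actually seen in the data;
unobserved kmers are excluded from the denominator as well (they carry
little mass — were they common in the genome, they would have been
observed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Read, decode_kmer, encode_kmer, group_by_length, reads_to_matrix

MAX_K = 32


@dataclass
class KmerSpectrum:
    """Observed kmers (sorted unique 2-bit codes) with counts Y."""

    k: int
    codes: np.ndarray  # (n,) int64, sorted unique
    Y: np.ndarray  # (n,) int64, all >= 1
    total_attempts: int  # sum over reads of (len - k + 1)

    def __post_init__(self) -> None:
        if self.Y.sum() != self.total_attempts:
            raise ValueError("counts do not sum to the total window count")

    @property
    def n(self) -> int:
        return self.codes.size

    def index_of(self, query: np.ndarray) -> np.ndarray:
        """Spectrum index of each query code; -1 where unobserved."""
        query = np.asarray(query, dtype=np.int64)
        pos = np.searchsorted(self.codes, query)
        pos_c = np.clip(pos, 0, self.n - 1)
        hit = self.codes[pos_c] == query
        return np.where(hit, pos_c, -1)

    def kmer_strings(self) -> list[str]:
        return [decode_kmer(int(c), self.k) for c in self.codes]

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tcount\n")
            for s, y in zip(self.kmer_strings(), self.Y):
                fh.write(f"{s}\t{int(y)}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "KmerSpectrum":
        kmers, counts = [], []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                s, y = line.split("\t")
                kmers.append(encode_kmer(s))
                counts.append(int(y))
        codes = np.asarray(kmers, dtype=np.int64)
        Y = np.asarray(counts, dtype=np.int64)
        order = np.argsort(codes)
        k = len(s)
        return cls(k=k, codes=codes[order], Y=Y[order], total_attempts=int(Y.sum()))


def window_codes(matrix: np.ndarray, k: int) -> np.ndarray:
    """2-bit codes of every length-k window of each row of a base matrix."""
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(matrix, k, axis=1)
    return windows.astype(np.int64) @ powers


def build_spectrum(reads: Sequence[Read | str], k: int) -> KmerSpectrum:
    """Count every length-k window of every read."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    seqs = [r.seq if isinstance(r, Read) else r for r in reads]
    if seqs and min(len(s) for s in seqs) < k:
        raise ValueError("k exceeds the shortest read length")
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(len(s), []).append(i)
    chunks = []
    total = 0
    for L, idx in groups.items():
        mat = reads_to_matrix([seqs[i] for i in idx])
        codes = window_codes(mat, k).ravel()
        total += codes.size
        chunks.append(codes)
    if not chunks:
        return KmerSpectrum(k=k, codes=np.empty(0, np.int64), Y=np.empty(0, np.int64), total_attempts=0)
    uniq, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerSpectrum(k=k, codes=uniq, Y=counts.astype(np.int64), total_attempts=total)


def _substitute_position(codes: np.ndarray, k: int, i: int) -> np.ndarray:
    """All 3 single-base substitutions of position i, shape (3, n)."""
    shift = 2 * (k - 1 - i)
    mask = np.int64(3) << shift
    cur = (codes >> shift) & 3
    out = []
    for delta in (1, 2, 3):  # XOR on the 2-bit field enumerates the other bases
        nb = cur ^ delta
        out.append((codes & ~mask) | (nb << shift))
    return np.stack(out)


def hamming_ball(code: int, d_max: int, k: int) -> np.ndarray:
    """All kmer codes within Hamming distance d_max of ``code`` (center included)."""
    if d_max not in (0, 1, 2):
        raise ValueError("d_max must be 0, 1 or 2")
    center = np.asarray([code], dtype=np.int64)
    parts = [center]
    if d_max >= 1:
        for i in range(k):
            parts.append(_substitute_position(center, k, i).ravel())
    if d_max >= 2:
        for i, j in combinations(range(k), 2):
            step1 = _substitute_position(center, k, i).ravel()
            parts.append(_substitute_position(step1, k, j).ravel())
    return np.concatenate(parts)


@dataclass
class NeighborRows:
    """Sparse observed-kmer misread structure in COO/CSR-by-target form.

    ``src``, ``tgt`` index into the spectrum; ``w`` holds the per-source
    normalized misread weight w(src -> tgt).  Pairs are sorted by target
    and ``indptr`` gives the CSR slices per target (the EM E-step and the
    corrector both iterate over targets).  Every kmer's row includes the
    self pair.
    """

    n: int
    d_max: int
    src: np.ndarray  # (nnz,) int64
    tgt: np.ndarray  # (nnz,) int64
    w: np.ndarray  # (nnz,) float64, per-source normalized
    indptr: np.ndarray  # (n + 1,) int64, slices by target

    def row(self, l: int) -> tuple[np.ndarray, np.ndarray]:
        """(source indices, weights) of the neighborhood of target l."""
        a, b = self.indptr[l], self.indptr[l + 1]
        return self.src[a:b], self.w[a:b]

    def source_weight_sums(self) -> np.ndarray:
        return np.bincount(self.src, weights=self.w, minlength=self.n)


def build_neighbor_rows(spectrum: KmerSpectrum, model, d_max: int) -> NeighborRows:
    """Restrict the misread matrix to observed kmers within ``d_max``.

    Raw weights are model misread probabilities p_e(x_m -> x_l); they are
    then normalized so each observed source's outgoing weights sum to 1.
    """
    if spectrum.n == 0:
        raise ValueError("empty spectrum")
    if d_max not in (0, 1, 2):
        raise ValueError("d_max must be 0, 1 or 2")
    k = spectrum.k
    codes = spectrum.codes
    n = spectrum.n

    tgt_parts = [np.arange(n, dtype=np.int64)]
    src_parts = [np.arange(n, dtype=np.int64)]

    def add_candidates(cand: np.ndarray, centers: np.ndarray) -> None:
        idx = spectrum.index_of(cand)
        hit = idx >= 0
        # pair (source = candidate within the ball of center, target = center)
        src_parts.append(idx[hit])
        tgt_parts.append(centers[hit])

    centers = np.arange(n, dtype=np.int64)
    if d_max >= 1:
        for i in range(k):
            for cand in _substitute_position(codes, k, i):
                add_candidates(cand, centers)
    if d_max >= 2:
        for i, j in combinations(range(k), 2):
            for cand1 in _substitute_position(codes, k, i):
                for cand in _substitute_position(cand1, k, j):
                    add_candidates(cand, centers)

    src = np.concatenate(src_parts)
    tgt = np.concatenate(tgt_parts)
    w = np.asarray(model.misread_prob(codes[src], codes[tgt], k), dtype=float)

    sums = np.bincount(src, weights=w, minlength=n)
    if (sums <= 0).any():
        bad = int(np.argmin(sums))
        raise ValueError(
            f"source kmer {decode_kmer(int(codes[bad]), k)} has zero outgoing "
            "misread mass; the error model assigns it probability 0"
        )
    w = w / sums[src]

    order = np.argsort(tgt, kind="stable")
    src, tgt, w = src[order], tgt[order], w[order]
    counts = np.bincount(tgt, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return NeighborRows(n=n, d_max=d_max, src=src, tgt=tgt, w=w, indptr=indptr)
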