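"""Posterior-based correction of erroneous bases in reads.

For an observed kmer x_l, the probability that the true base at kmer
position t was b — before any misread — follows from Bayes' rule over the
candidate source kmers in x_l's neighborhood, weighting each source x_m
by its estimated attempt count T_m (standing in for its unknown genomic
frequency) times the misread probability:

    p_t(b | x_l) = sum_{m in N_l, x_m[t] = b} T_m w(m->l)
                   / sum_{m in N_l} T_m w(m->l)

A base at read position i is covered by up to k overlapping windows,
which carry non-independent information, so the window posteriors are
simply averaged to give p_i(b).  If argmax_b p_i(b) differs from the
observed base, the base is declared misread and rewritten to the argmax
(ties retain the observed base).  Correction is a single pass computed
from the original read's windows; corrections are not fed back into the
posteriors, and T is not re-estimated afterwards.

To limit computation, only reads likely to contain at least one erroneous
kmer — those with any window T below a liberal threshold — enter
correction; all other reads pass through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BASES, Read, reads_to_matrix
from .spectrum import KmerSpectrum, NeighborRows, window_codes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionRecord:
    """One rewritten base: read id, position, observed and new base."""

    read_id: str
    position: int
    from_base: str
    to_base: str


def posterior_matrix(
    spectrum: KmerSpectrum, T: np.ndarray, rows: NeighborRows
) -> tuple[np.ndarray, np.ndarray]:
    """Per-kmer per-position base posteriors, shape (n, k, 4).

    Returns (P, fallback) where ``fallback`` marks kmers whose whole
    neighborhood carries zero attempt mass; their posterior defaults to a
    point mass on the kmer's own bases (no evidence to change anything).
    """
    k, n = spectrum.k, spectrum.n
    val = T[rows.src] * rows.w
    denom = np.bincount(rows.tgt, weights=val, minlength=n)
    P = np.zeros((n, k, 4))
    for t in range(k):
        shift = 2 * (k - 1 - t)
        b = (spectrum.codes[rows.src] >> shift) & 3
        P[:, t, :] = np.bincount(rows.tgt * 4 + b, weights=val, minlength=n * 4).reshape(n, 4)
    fallback = denom <= 0
    if fallback.any():
        logger.info(
            "%d kmer(s) with zero neighborhood attempt mass; keeping observed bases",
            int(fallback.sum()),
        )
        for t in range(k):
            shift = 2 * (k - 1 - t)
            own = (spectrum.codes[fallback] >> shift) & 3
            P[fallback, t, :] = 0.0
            P[np.flatnonzero(fallback), t, own] = 1.0
    P[~fallback] /= denom[~fallback, None, None]
    return P, fallback


def kmer_position_posterior(
    l: int, t: int, spectrum: KmerSpectrum, T: np.ndarray, rows: NeighborRows
) -> np.ndarray:
    """Posterior over the true base at kmer position t of observed kmer l."""
    src, w = rows.row(l)
    val = T[src] * w
    denom = val.sum()
    shift = 2 * (spectrum.k - 1 - t)
    if denom <= 0:
        out = np.zeros(4)
        out[(int(spectrum.codes[l]) >> shift) & 3] = 1.0
        return out
    b = (spectrum.codes[src] >> shift) & 3
    return np.bincount(b, weights=val, minlength=4) / denom


def _read_posteriors(
    base_matrix: np.ndarray,
    spectrum: KmerSpectrum,
    P: np.ndarray,
    codes: np.ndarray | None = None,
) -> np.ndarray:
    """Averaged per-position posteriors for equal-length reads, (n, L, 4)."""
    n, L = base_matrix.shape
    k = spectrum.k
    if codes is None:
        codes = window_codes(base_matrix, k)
    idx = spectrum.index_of(codes.ravel()).reshape(codes.shape)
    n_win = L - k + 1
    acc = np.zeros((n, L, 4))
    cnt = np.zeros(L)
    known = idx >= 0
    # windows absent from the spectrum contribute a point mass on the
    # observed bases (no evidence either way)
    for j in range(n_win):
        win_post = np.empty((n, k, 4))
        kj = known[:, j]
        win_post[kj] = P[idx[kj, j]]
        if (~kj).any():
            own = base_matrix[~kj, j : j + k]
            onehot = np.zeros((own.shape[0], k, 4))
            np.put_along_axis(onehot, own[:, :, None], 1.0, axis=2)
            win_post[~kj] = onehot
        acc[:, j : j + k] += win_post
        cnt[j : j + k] += 1
    return acc / cnt[None, :, None]


def read_base_posterior(
    read: Read,
    i: int,
    spectrum: KmerSpectrum,
    T: np.ndarray,
    rows: NeighborRows,
) -> np.ndarray:
    """Posterior over the true base at read position i (mean over windows)."""
    if len(read.seq) < spectrum.k:
        raise ValueError("read shorter than k")
    P, _ = posterior_matrix(spectrum, T, rows)
    mat = reads_to_matrix([read])
    return _read_posteriors(mat, spectrum, P)[0, i]


def _apply_argmax(
    base_matrix: np.ndarray, post: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rewrite bases where the posterior argmax beats the observed base."""
    n, L = base_matrix.shape
    obs_prob = np.take_along_axis(post, base_matrix[:, :, None].astype(np.intp), axis=2)[:, :, 0]
    best = post.argmax(axis=2)
    maxv = post.max(axis=2)
    # a tie with the observed base retains the observed base
    change = maxv > obs_prob + 0.0
    corrected = np.where(change, best, base_matrix).astype(np.uint8)
    return corrected, change


def correct_read(
    read: Read,
    spectrum: KmerSpectrum,
    T: np.ndarray,
    rows: NeighborRows,
) -> tuple[Read, list[CorrectionRecord]]:
    """Single-pass correction of one read (posteriors from the original read)."""
    out, records = correct_reads([read], spectrum, T, rows, liberal_M=np.inf)
    return out[0], records


def correct_reads(
    reads: Sequence[Read],
    spectrum: KmerSpectrum,
    T: np.ndarray,
    rows: NeighborRows,
    liberal_M: float,
    batch_size: int = 4096,
) -> tuple[list[Read], list[CorrectionRecord]]:
    """Correct reads containing at least one kmer with T below ``liberal_M``.

    Reads failing the liberal pre-filter pass through unchanged.  Output
    reads keep their ids and lengths; every change is returned as a
    CorrectionRecord.
    """
    from .io import decode_bases, group_by_length

    out: list[Read] = list(reads)
    records: list[CorrectionRecord] = []
    P, _ = posterior_matrix(spectrum, T, rows)
    k = spectrum.k
    for L, indices in group_by_length(list(reads)).items():
        if L < k:
            raise ValueError(f"read length {L} shorter than k={k}")
        for lo in range(0, len(indices), batch_size):
            batch_idx = indices[lo : lo + batch_size]
            mat = reads_to_matrix([reads[i] for i in batch_idx])
            codes = window_codes(mat, k)
            sidx = spectrum.index_of(codes.ravel()).reshape(codes.shape)
            Tw = np.where(sidx >= 0, T[np.clip(sidx, 0, None)], 0.0)
            enter = (Tw < liberal_M).any(axis=1)
            if not enter.any():
                continue
            sel = np.flatnonzero(enter)
            post = _read_posteriors(mat[sel], spectrum, P, codes=codes[sel])
            corrected, change = _apply_argmax(mat[sel], post)
            for row_i, global_i in enumerate(np.asarray(batch_idx)[sel]):
                r = reads[global_i]
                if change[row_i].any():
                    new_seq = decode_bases(corrected[row_i])
                    out[global_i] = Read(id=r.id, seq=new_seq)
                    for pos in np.flatnonzero(change[row_i]):
                        records.append(
                            CorrectionRecord(
                                read_id=r.id,
                                position=int(pos),
                                from_base=BASES[mat[sel[row_i], pos]],
                                to_base=BASES[corrected[row_i, pos]],
                            )
                        )
    return out, records


def save_records_tsv(path, records: Sequence[CorrectionRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tpos\tfrom\tto\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.position}\t{r.from_base}\t{r.to_base}\n")
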