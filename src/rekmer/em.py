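"""EM estimation of expected read attempts per kmer.

The observed kmer counts Y = (Y_1, ..., Y_n) are modeled as a multinomial
draw whose cell probabilities mix over each kmer's misread neighborhood:
a window of the genome holding kmer x_m is read as x_l with probability
w(m -> l), so the expected count of x_l pools contributions from every
neighbor.  The quantity estimated here is T_m, the expected number of
*attempts* to read x_m — error-free plus misread — which is proportional
to x_m's genomic frequency.  A truly-absent kmer (zero genomic
occurrences) should see its T driven toward 0 even when its observed Y is
large, because its count is explained by misreads of its high-frequency
neighbors; this is precisely what frequency thresholds on Y get wrong in
repeat-rich genomes.

Working directly on the T scale (rather than the multinomial cell
probabilities s = T / total) leaves the E-step unchanged and shifts the
log likelihood by a constant, so the updates are:

    E-step:  E[Y_lm] = Y_l * T_m w(m->l) / sum_{m'} T_{m'} w(m'->l)
    M-step:  T_m     = sum_l E[Y_lm]

with l running over observed kmers and m over the neighborhood of l.
Total mass is conserved (sum T = sum Y after every M-step) and the log
likelihood  l(T | Y) = sum_l Y_l log(sum_m T_m w(m->l))  is non-decreasing.

Everything is deterministic: initialization is T = Y and the iteration
order is the sorted kmer-code order.  Arithmetic is plain double
precision in linear space — neighborhood sums are short and well scaled,
and an exact-zero denominator under a positive count is reported as a
degeneracy rather than papered over.  A T_m that reaches exactly 0 stays
0 (absorbing under the updates); downstream detection treats T = 0 as the
strongest possible evidence that the kmer is erroneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import decode_kmer
from .spectrum import KmerSpectrum, NeighborRows


class DegeneracyError(ArithmeticError):
    """A kmer with positive count received zero neighborhood mass."""


@dataclass
class AttemptEstimates:
    """EM output: expected attempts T per observed kmer, with diagnostics."""

    T: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


def _denominators(Y: np.ndarray, T: np.ndarray, rows: NeighborRows, k: int) -> np.ndarray:
    flow = T[rows.src] * rows.w
    denom = np.bincount(rows.tgt, weights=flow, minlength=rows.n)
    bad = (denom <= 0) & (Y > 0)
    if bad.any():
        l = int(np.argmax(bad))
        raise DegeneracyError(
            f"kmer index {l} has Y={int(Y[l])} but zero neighborhood mass"
        )
    return denom


def e_step(Y: np.ndarray, T: np.ndarray, rows: NeighborRows) -> np.ndarray:
    """Expected hidden counts E[Y_lm], one per stored (src, tgt) pair.

    For each target l the responsibilities over its neighborhood sum to
    Y_l exactly.
    """
    denom = _denominators(Y, T, rows, rows.n)
    safe = np.where(denom > 0, denom, 1.0)
    return Y[rows.tgt] * (T[rows.src] * rows.w) / safe[rows.tgt]


def m_step(responsibilities: np.ndarray, rows: NeighborRows) -> np.ndarray:
    """Reassign each target's count mass to its candidate sources."""
    return np.bincount(rows.src, weights=responsibilities, minlength=rows.n)


def log_likelihood(Y: np.ndarray, T: np.ndarray, rows: NeighborRows) -> float:
    """Observed-data log likelihood up to an additive constant."""
    denom = _denominators(Y, T, rows, rows.n)
    pos = Y > 0
    return float(np.sum(Y[pos] * np.log(denom[pos])))


def run_em(
    spectrum: KmerSpectrum,
    rows: NeighborRows,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> AttemptEstimates:
    """Maximize the mixture likelihood, starting from T = Y.

    Stops when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations; the full trace is reported.
    """
    if rows.n != spectrum.n:
        raise ValueError("neighborhood built from a different spectrum")
    Y = spectrum.Y.astype(float)
    T = Y.copy()
    trace = [log_likelihood(Y, T, rows)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resp = e_step(Y, T, rows)
        T = np.maximum(m_step(resp, rows), 0.0)
        ll = log_likelihood(Y, T, rows)
        if not np.isfinite(ll):
            raise DegeneracyError(f"non-finite log likelihood at iteration {it}")
        trace.append(ll)
        if abs(ll - trace[-2]) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    return AttemptEstimates(T=T, loglik_trace=trace, n_iterations=it, converged=converged)


def save_attempts_tsv(path, spectrum: KmerSpectrum, est: AttemptEstimates) -> None:
    """Serialize (kmer, Y, T) for downstream detection and correction."""
    with open(path, "w") as fh:
        fh.write("kmer\tY\tT\n")
        for c, y, t in zip(spectrum.codes, spectrum.Y, est.T):
            fh.write(f"{decode_kmer(int(c), spectrum.k)}\t{int(y)}\t{t:.8g}\n")


def load_attempts_tsv(path) -> tuple[KmerSpectrum, np.ndarray]:
    """Inverse of :func:`save_attempts_tsv` (codes re-sorted if needed)."""
    from .io import encode_kmer

    kmers, Ys, Ts = [], [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            s, y, t = line.split("\t")
            kmers.append(encode_kmer(s))
            Ys.append(int(y))
            Ts.append(float(t))
    codes = np.asarray(kmers, dtype=np.int64)
    order = np.argsort(codes)
    Y = np.asarray(Ys, dtype=np.int64)[order]
    T = np.asarray(Ts, dtype=float)[order]
    spec = KmerSpectrum(k=len(s), codes=codes[order], Y=Y, total_attempts=int(Y.sum()))
    return spec, T
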