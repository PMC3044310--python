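"""Shared fixtures and independent oracles used across the test modules."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from rekmer.io import BASES, Read, decode_kmer
from rekmer.errors import UniformErrorModel
from rekmer.spectrum import build_neighbor_rows, build_spectrum


def random_reads(rng: np.random.Generator, n: int, L: int) -> list[Read]:
    return [
        Read(id=f"r{i}", seq="".join(rng.choice(list(BASES), size=L)))
        for i in range(n)
    ]


def hamming_str(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_ball(kmer: str, d_max: int) -> set[str]:
    """Exhaustive Hamming ball over the full alphabet (oracle, k <= 5)."""
    k = len(kmer)
    return {
        "".join(c)
        for c in itertools.product(BASES, repeat=k)
        if hamming_str("".join(c), kmer) <= d_max
    }


def em_system(reads: list[str] | list[Read], k: int, p_e: float, d_max: int = 1):
    """Spectrum + neighborhood under a uniform model, for EM tests."""
    spectrum = build_spectrum(reads, k)
    rows = build_neighbor_rows(spectrum, UniformErrorModel(p_e), d_max)
    return spectrum, rows


def brute_force_max_likelihood(Y: np.ndarray, rows, n_starts: int = 8):
    """Maximize the mixture log likelihood directly (oracle for EM).

    Parameterizes T = (sum Y) * softmax(z) — total mass is conserved at
    any EM fixed point — and polishes from several deterministic starts
    with Nelder-Mead.  Independent of the EM update equations.
    """
    from scipy.optimize import minimize

    Y = np.asarray(Y, dtype=float)
    total = Y.sum()
    n = Y.size

    def neg_ll(z):
        z = z - z.max()
        T = total * np.exp(z) / np.exp(z).sum()
        flow = T[rows.src] * rows.w
        denom = np.bincount(rows.tgt, weights=flow, minlength=n)
        if (denom[Y > 0] <= 0).any():
            return 1e18
        return -float(np.sum(Y[Y > 0] * np.log(denom[Y > 0])))

    rng = np.random.default_rng(0)
    best = None
    starts = [np.log(np.maximum(Y, 1e-3) / total)]
    starts += [rng.normal(0, 2, n) for _ in range(n_starts - 1)]
    for z0 in starts:
        res = minimize(neg_ll, z0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    z = best.x - best.x.max()
    T = total * np.exp(z) / np.exp(z).sum()
    return T, -best.fun


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
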