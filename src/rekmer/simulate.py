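"""Repeat-structured genome and short-read simulation with full ground truth.

Synthetic genomes are iid background sequence at a chosen base composition
(defaults mimic a maize-like composition, A 28% / C 23% / G 22% / T 27%)
with repeat families embedded: each family is one randomly drawn unit
copied ``multiplicity`` times into non-overlapping random slots.  Reads are
uniformly positioned fixed-length substrings passed base-by-base through a
substitution model — either a constant per-base rate or per-read-position
4x4 misread matrices.  Indels, quality strings, GC-coverage bias and
paired ends are deliberately out of scope.

Ground truth emitted alongside the reads: each read's genome start
coordinate and per-base error flags, plus the exhaustive genomic
occurrence count alpha_l of every kmer (alpha_l = 0 identifies kmer types
whose every observation is a misread).

The bundled presets scale the published 1 Mb / 80x benchmark recipes to
1/10 genome size for desk-scale runs.  Repeat unit lengths are scaled
down while copy numbers are kept: the statistical signature that makes
repeat-rich error detection hard is the per-satellite misread count
(proportional to copy number x coverage), and scaling copy numbers down
would erase it, leaving a trivially easy problem that no longer resembles
the original.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ReadErrorProfile, UniformErrorModel
from .io import BASES, Genome, Read, decode_bases, encode_bases, reads_to_matrix
from .spectrum import window_codes

MAIZE_BASE_FREQS = (0.28, 0.23, 0.22, 0.27)  # A, C, G, T


class RepeatSpec(NamedTuple):
    """One repeat family: unit length (bases) and copy number."""

    unit_length: int
    multiplicity: int


@dataclass
class SimTruth:
    """Per-read and per-kmer ground truth for a simulated read set."""

    starts: np.ndarray  # (n_reads,) genome start coordinate, 0-based
    error_flags: np.ndarray  # (n_reads, L) bool, True where base was misread
    genome_kmer_codes: np.ndarray  # sorted distinct genomic kmer codes
    genome_kmer_counts: np.ndarray  # alpha for each code
    k: int

    def alpha_of(self, codes: np.ndarray) -> np.ndarray:
        """Genomic occurrence count for arbitrary kmer codes (0 if absent)."""
        codes = np.asarray(codes, dtype=np.int64)
        pos = np.searchsorted(self.genome_kmer_codes, codes)
        pos_c = np.clip(pos, 0, max(len(self.genome_kmer_codes) - 1, 0))
        hit = (
            self.genome_kmer_codes[pos_c] == codes
            if len(self.genome_kmer_codes)
            else np.zeros(codes.shape, bool)
        )
        return np.where(hit, self.genome_kmer_counts[pos_c], 0)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_genome(
    length: int,
    base_freqs: Sequence[float] = MAIZE_BASE_FREQS,
    repeats: Sequence[RepeatSpec] = (),
    seed=0,
    id: str = "sim",
) -> Genome:
    """iid background sequence with non-overlapping repeat copies embedded.

    Repeat units are drawn from the same base composition as the
    background.  Placement distributes the free (non-repeat) space
    randomly among the slots between a random interleaving of all copies,
    so any feasible recipe (total repeat span <= length) always packs.
    """
    rng = _as_rng(seed)
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-6 or (freqs < 0).any():
        raise ValueError("base_freqs must be a 4-simplex (A, C, G, T)")
    repeats = [RepeatSpec(*r) for r in repeats]
    span = sum(r.unit_length * r.multiplicity for r in repeats)
    if span > length:
        raise ValueError(f"repeat span {span} exceeds genome length {length}")

    units = [rng.choice(4, size=r.unit_length, p=freqs).astype(np.uint8) for r in repeats]
    copies = [fam for fam, r in enumerate(repeats) for _ in range(r.multiplicity)]
    order = rng.permutation(len(copies))
    free = length - span
    gaps = rng.multinomial(free, np.full(len(copies) + 1, 1.0 / (len(copies) + 1)))

    parts: list[np.ndarray] = []
    annotation: list[tuple[int, int, int]] = []
    pos = 0
    for slot, copy_idx in enumerate(order):
        g = int(gaps[slot])
        if g:
            parts.append(rng.choice(4, size=g, p=freqs).astype(np.uint8))
            pos += g
        fam = copies[copy_idx]
        unit = units[fam]
        parts.append(unit)
        annotation.append((pos, pos + len(unit), fam))
        pos += len(unit)
    g = int(gaps[-1])
    if g:
        parts.append(rng.choice(4, size=g, p=freqs).astype(np.uint8))
    seq = decode_bases(np.concatenate(parts) if parts else np.empty(0, np.uint8))
    assert len(seq) == length
    return Genome(id=id, seq=seq, repeat_annotation=annotation)


def repeat_fraction(genome: Genome) -> float:
    span = sum(e - s for s, e, _ in genome.repeat_annotation)
    return span / len(genome.seq)


def _apply_errors(
    true_bases: np.ndarray, model, rng: np.random.Generator
) -> np.ndarray:
    """Pass an (n, L) true-base matrix through the substitution model."""
    n, L = true_bases.shape
    out = true_bases.copy()
    if isinstance(model, UniformErrorModel):
        err = rng.random((n, L)) < model.p_e
        # wrong base uniform among the other three, via 2-bit XOR with 1..3
        delta = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        out[err] = out[err] ^ delta
        return out
    if isinstance(model, ReadErrorProfile):
        if model.L != L:
            raise ValueError(f"profile is for L={model.L}, reads have L={L}")
        u = rng.random((n, L))
        cum = np.cumsum(model.M, axis=2)  # (L, 4, 4)
        for i in range(L):
            c = cum[i, true_bases[:, i]]  # (n, 4)
            out[:, i] = (u[:, i, None] > c).sum(axis=1)
        return out
    raise TypeError(f"unsupported error model {type(model).__name__}")


def simulate_reads(
    genome: Genome,
    n_reads: int,
    L: int,
    model,
    seed=0,
    k: int = 13,
    id_prefix: str = "read",
) -> tuple[list[Read], SimTruth]:
    """Sample uniformly positioned L-substrings and apply the error model.

    Coverage is C = n_reads * L / |G|.  Truth kmer occurrences are
    tabulated at the given ``k``.
    """
    rng = _as_rng(seed)
    gbases = encode_bases(genome.seq)
    if L > len(gbases):
        raise ValueError("read length exceeds genome length")
    starts = rng.integers(0, len(gbases) - L + 1, size=n_reads)
    true_bases = gbases[starts[:, None] + np.arange(L)]
    read_bases = _apply_errors(true_bases, model, rng)
    flags = read_bases != true_bases

    joined = decode_bases(read_bases.ravel())
    reads = [
        Read(id=f"{id_prefix}{i}", seq=joined[i * L : (i + 1) * L])
        for i in range(n_reads)
    ]
    codes, counts = true_occurrences(genome, k)
    truth = SimTruth(
        starts=starts.astype(np.int64),
        error_flags=flags,
        genome_kmer_codes=codes,
        genome_kmer_counts=counts,
        k=k,
    )
    return reads, truth


def true_occurrences(genome: Genome, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive genomic kmer counts alpha; sum equals |G| - k + 1."""
    gb = encode_bases(genome.seq)[None, :]
    codes = window_codes(gb, k).ravel()
    uniq, counts = np.unique(codes, return_counts=True)
    return uniq, counts.astype(np.int64)


# ---------------------------------------------------------------------------
# presets: published benchmark recipes and their 1/10-scale versions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    genome_length: int
    repeats: tuple[RepeatSpec, ...]
    coverage: float
    read_length: int
    base_freqs: tuple[float, float, float, float] = MAIZE_BASE_FREQS

    @property
    def n_reads(self) -> int:
        return int(round(self.coverage * self.genome_length / self.read_length))


PRESETS: dict[str, Preset] = {
    # quick-start recipe for smoke tests and examples (seconds to run)
    "tiny": Preset(10_000, (RepeatSpec(50, 20),), 30.0, 36),
    # 1 Mb benchmark recipes: 20% / 50% / 80% repeat span at 80x, 36 bp
    "D1": Preset(1_000_000, (RepeatSpec(1000, 200),), 80.0, 36),
    "D2": Preset(1_000_000, (RepeatSpec(500, 400), RepeatSpec(1500, 200)), 80.0, 36),
    "D3": Preset(
        1_000_000,
        (RepeatSpec(500, 400), RepeatSpec(1500, 200), RepeatSpec(3000, 100)),
        80.0,
        36,
    ),
    # 1/10-scale versions: unit lengths /10, copy numbers preserved
    "D1-small": Preset(100_000, (RepeatSpec(100, 200),), 80.0, 36),
    "D2-small": Preset(100_000, (RepeatSpec(50, 400), RepeatSpec(150, 200)), 80.0, 36),
    "D3-small": Preset(
        100_000,
        (RepeatSpec(50, 400), RepeatSpec(150, 200), RepeatSpec(300, 100)),
        80.0,
        36,
    ),
}


def simulate_preset(
    name: str, model, seed=0, k: int = 13
) -> tuple[Genome, list[Read], SimTruth]:
    """Generate genome + reads + truth for a named preset recipe."""
    p = PRESETS[name]
    rng = _as_rng(seed)
    genome = generate_genome(
        p.genome_length, p.base_freqs, p.repeats, seed=rng, id=name
    )
    reads, truth = simulate_reads(genome, p.n_reads, p.read_length, model, seed=rng, k=k)
    return genome, reads, truth


def save_read_truth_tsv(path, reads: Sequence[Read], truth: SimTruth) -> None:
    """read_id, start, comma-list of erroneous base positions."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart\terror_positions\n")
        for r, s, flags in zip(reads, truth.starts, truth.error_flags):
            pos = ",".join(str(i) for i in np.flatnonzero(flags))
            fh.write(f"{r.id}\t{int(s)}\t{pos}\n")


def save_kmer_truth_tsv(path, truth: SimTruth) -> None:
    """kmer, alpha for every genomic kmer."""
    from .io import decode_kmer

    with open(path, "w") as fh:
        fh.write("kmer\talpha\n")
        for c, a in zip(truth.genome_kmer_codes, truth.genome_kmer_counts):
            fh.write(f"{decode_kmer(int(c), truth.k)}\t{int(a)}\n")
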