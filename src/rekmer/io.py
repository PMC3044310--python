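"""Sequence containers, FASTA/FASTQ I/O and the 2-bit nucleotide encoding.

All coordinates anywhere in the package are 0-based, half-open.  Reads are
kept exactly as given on the forward strand; no reverse-complement
canonicalization is applied (a simulated read is a genome substring read
left to right, so canonicalization would only blur the misread structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i


class ParseError(ValueError):
    """Raised when a FASTA/FASTQ file is structurally malformed."""


@dataclass
class Read:
    """A single short read; ``seq`` contains only A/C/G/T after sanitization."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Genome:
    """A reference sequence with optional repeat annotation.

    ``repeat_annotation`` lists ``(start, end, family)`` half-open intervals;
    intervals of one family all have the same length by construction.
    """

    id: str
    seq: str
    repeat_annotation: list[tuple[int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


def encode_bases(seq: str) -> np.ndarray:
    """Map an A/C/G/T string to a uint8 array of codes 0..3."""
    arr = _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


_CODE_TO_BYTE = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def decode_bases(codes: np.ndarray) -> str:
    return _CODE_TO_BYTE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def encode_kmer(kmer: str) -> int:
    """2-bit encode a kmer string (A=0, C=1, G=2, T=3, big-endian)."""
    code = 0
    for b in encode_bases(kmer):
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(BASES[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def _is_acgt(seq: str) -> bool:
    return not (set(seq.upper()) - set(BASES))


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a FASTQ file into Reads.

    Bases are uppercased; records containing any non-ACGT character are
    dropped and the number of dropped records is logged as a warning.
    """
    reads: list[Read] = []
    dropped = 0
    n_rec = 0
    try:
        with open(path) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                n_rec += 1
                seq = seq.upper()
                if not _is_acgt(seq):
                    dropped += 1
                    continue
                reads.append(Read(id=title.split()[0], seq=seq))
    except ValueError as exc:
        raise ParseError(
            f"malformed FASTQ record near line {4 * n_rec + 1} of {path}: {exc}"
        ) from exc
    if dropped:
        logger.warning("dropped %d read(s) containing non-ACGT characters", dropped)
    return reads


def read_fasta(path: str | Path) -> list[Genome]:
    """Parse a (multi-)FASTA file, one Genome per contig.

    Non-ACGT characters are stripped from genome sequences (so kmer counts
    are never contaminated by ambiguity codes).
    """
    genomes: list[Genome] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}: FASTA must start with '>' header")
        fh.seek(0)
        for title, seq in SimpleFastaParser(fh):
            seq = seq.upper()
            if not _is_acgt(seq):
                kept = "".join(c for c in seq if c in BASES)
                logger.warning(
                    "contig %s: stripped %d non-ACGT character(s)",
                    title.split()[0] if title else "?",
                    len(seq) - len(kept),
                )
                seq = kept
            genomes.append(Genome(id=title.split()[0] if title else "", seq=seq))
    if not genomes and Path(path).stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records found (missing header?)")
    return genomes


def write_fasta(path: str | Path, genomes: Iterable[Genome], width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def write_fastq(
    path: str | Path, reads: Iterable[Read], quality_char: str = "I"
) -> None:
    """Write reads as FASTQ with a constant placeholder quality."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")


def reads_to_matrix(reads: Sequence[Read | str]) -> np.ndarray:
    """Stack fixed-length reads into an (n, L) uint8 code matrix.

    Raises if lengths differ; variable-length collections must be grouped
    by length first (see :func:`group_by_length`).
    """
    seqs = [r.seq if isinstance(r, Read) else r for r in reads]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("reads_to_matrix requires equal-length reads")
    joined = "".join(seqs)
    return _BASE_TO_CODE[
        np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    ].reshape(len(seqs), L)


def group_by_length(reads: Sequence[Read]) -> dict[int, list[int]]:
    """Indices of reads grouped by read length (insertion order preserved)."""
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        groups.setdefault(len(r.seq), []).append(i)
    return groups
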