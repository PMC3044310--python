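"""Threshold-based erroneous-kmer detection and threshold sweeps.

A kmer is called erroneous when its statistic falls strictly below the
threshold M; the statistic is either the EM-estimated attempt count T
(repeat-aware) or the raw observed count Y (the classical frequency
baseline).  Against simulator truth a call on a kmer with at least one
genomic occurrence is a false positive, and a missed kmer with zero
genomic occurrences is a false negative; their sum WP = FP + FN is the
figure of merit, swept over a threshold grid (the sweep traces a U-shape:
too low a threshold misses errors, too high condemns clean kmers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import SimTruth
from .spectrum import KmerSpectrum


@dataclass(frozen=True)
class DetectionResult:
    """Confusion summary at one threshold (kmer-type level)."""

    threshold: float
    fp: int
    fn: int

    @property
    def wp(self) -> int:
        return self.fp + self.fn


def detect(values: np.ndarray, M: float) -> np.ndarray:
    """Erroneous-kmer calls: strictly below the threshold."""
    return np.asarray(values) < M


def kmer_truth(spectrum: KmerSpectrum, sim_truth: SimTruth) -> np.ndarray:
    """True erroneous-kmer mask: observed kmer types absent from the genome."""
    if sim_truth.k != spectrum.k:
        raise ValueError("truth tabulated at a different k")
    return sim_truth.alpha_of(spectrum.codes) == 0


def wp_curve(
    values: np.ndarray, truth_err: np.ndarray, thresholds: Sequence[float]
) -> list[DetectionResult]:
    """FP/FN/WP at each threshold, via sorted one-pass counting."""
    values = np.asarray(values, dtype=float)
    truth_err = np.asarray(truth_err, dtype=bool)
    if values.shape != truth_err.shape:
        raise ValueError("values and truth mask have different lengths")
    clean_sorted = np.sort(values[~truth_err])
    err_sorted = np.sort(values[truth_err])
    out = []
    for M in thresholds:
        fp = int(np.searchsorted(clean_sorted, M, side="left"))
        fn = int(err_sorted.size - np.searchsorted(err_sorted, M, side="left"))
        out.append(DetectionResult(threshold=float(M), fp=fp, fn=fn))
    return out


def default_threshold_grid(values: np.ndarray) -> np.ndarray:
    """Integer grid 0..ceil(max)+1, wide enough to reach the all-called end."""
    hi = int(np.ceil(np.max(values))) + 1 if len(values) else 1
    return np.arange(0, hi + 1, dtype=float)


def min_wp(curve: Sequence[DetectionResult]) -> tuple[float, int]:
    """(threshold, WP) minimizing WP; ties broken toward the smaller threshold."""
    best = min(curve, key=lambda r: (r.wp, r.threshold))
    return best.threshold, best.wp


def save_curve_tsv(path, curve: Sequence[DetectionResult]) -> None:
    with open(path, "w") as fh:
        fh.write("M\tFP\tFN\tWP\n")
        for r in curve:
            fh.write(f"{r.threshold:g}\t{r.fp}\t{r.fn}\t{r.wp}\n")
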