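"""Base-level correction metrics against simulator truth.

Definitions (per base of every evaluated read): a true positive is an
erroneous base changed to the true base; a false positive is a true base
changed at all; a true negative is a true base left unchanged; a false
negative is an erroneous base that remains erroneous — which includes an
erroneous base rewritten to a *different* wrong base (the error was not
removed, and no true base was harmed, so such a change is scored FN and
not FP).

Sensitivity = TP / (TP + FN); Specificity = TN / (TN + FP);
Gain = (TP - FP) / (TP + FN), the net fraction of erroneous bases removed
from the data by correction (gain <= sensitivity, and is negative when
correction introduces more errors than it fixes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Genome, Read, encode_bases, reads_to_matrix
from .simulate import SimTruth


@dataclass(frozen=True)
class CorrectionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 1.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 1.0

    @property
    def gain(self) -> float:
        d = self.tp + self.fn
        return (self.tp - self.fp) / d if d else 0.0


def correction_metrics(
    original: Sequence[Read],
    corrected: Sequence[Read],
    truth: SimTruth,
    genome: Genome,
) -> CorrectionMetrics:
    """Classify every base of every read; reads must align by id and order."""
    if len(original) != len(corrected):
        raise ValueError("read sets differ in size")
    for o, c in zip(original, corrected):
        if o.id != c.id:
            raise ValueError(f"read id mismatch: {o.id!r} vs {c.id!r}")
        if len(o.seq) != len(c.seq):
            raise ValueError(f"read {o.id}: length changed by correction")
    orig = reads_to_matrix(list(original))
    corr = reads_to_matrix(list(corrected))
    L = orig.shape[1]
    gbases = encode_bases(genome.seq)
    true_b = gbases[truth.starts[:, None] + np.arange(L)]
    flags = truth.error_flags
    if flags.shape != orig.shape:
        raise ValueError("truth flags do not match read dimensions")

    changed = corr != orig
    fixed = corr == true_b
    tp = int(np.sum(flags & fixed))
    fn = int(np.sum(flags & ~fixed))
    fp = int(np.sum(~flags & changed))
    tn = int(np.sum(~flags & ~changed))
    return CorrectionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def save_metrics_tsv(path, metrics: CorrectionMetrics) -> None:
    with open(path, "w") as fh:
        fh.write("TP\tFP\tTN\tFN\tsensitivity\tspecificity\tgain\n")
        fh.write(
            f"{metrics.tp}\t{metrics.fp}\t{metrics.tn}\t{metrics.fn}\t"
            f"{metrics.sensitivity:.6f}\t{metrics.specificity:.6f}\t{metrics.gain:.6f}\n"
        )
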