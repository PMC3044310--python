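"""End-to-end experiment orchestration on simulated data.

These functions chain the simulator, spectrum builder, EM estimator,
detector and corrector the way the benchmark experiments do, and are the
machinery behind both the command-line ``pipeline`` subcommand and the
reproduction scripts.  Detection experiments compare the minimum
wrong-prediction count (FP + FN over a full integer threshold sweep)
achieved on the raw counts Y versus on the EM attempts T; correction
experiments additionally run the posterior corrector and score it at
base level.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .detect import default_threshold_grid, kmer_truth, min_wp, wp_curve
from .correct import correct_reads
from .em import AttemptEstimates, run_em
from .errors import PositionalErrorModel, ReadErrorProfile, UniformErrorModel
from .evaluate import CorrectionMetrics, correction_metrics
from .simulate import simulate_preset
from .spectrum import build_spectrum, build_neighbor_rows

logger = logging.getLogger(__name__)

DEFAULT_K = 13
DEFAULT_DMAX = 1
DEFAULT_PE = 0.006


def sloped_read_profile(L: int, lo: float = 0.96, hi: float = 0.995) -> ReadErrorProfile:
    """Illumina-like read profile: accuracy decays quadratically toward 3'.

    Diagonal of M_i runs from ``hi`` at the 5' end down to ``lo`` at the
    3' end; each wrong base takes an equal share of the remainder.
    """
    x = np.arange(L) / (L - 1)
    diag = hi - (hi - lo) * x**2
    M = np.empty((L, 4, 4))
    for i in range(L):
        M[i] = np.full((4, 4), (1.0 - diag[i]) / 3.0)
        M[i][range(4), range(4)] = diag[i]
    return ReadErrorProfile(M)


def sloped_kmer_model(
    k: int = DEFAULT_K, lo: float = 0.96, hi: float = 0.995, reverse: bool = True
) -> PositionalErrorModel:
    """Positional kmer model with the same accuracy range as
    :func:`sloped_read_profile` but, by default, the opposite positional
    trend — a deliberately *wrong* model for robustness experiments."""
    x = np.arange(k) / (k - 1)
    if reverse:
        x = 1.0 - x
    diag = hi - (hi - lo) * x**2
    q = np.empty((k, 4, 4))
    for i in range(k):
        q[i] = np.full((4, 4), (1.0 - diag[i]) / 3.0)
        q[i][range(4), range(4)] = diag[i]
    return PositionalErrorModel(q)


@dataclass
class DetectionExperiment:
    """Y-vs-T threshold-sweep comparison on one simulated dataset."""

    preset: str
    seed: int
    n_kmers: int
    min_wp_Y: int
    min_wp_T: int
    threshold_Y: float
    threshold_T: float
    em: AttemptEstimates | None = None

    @property
    def reduction_pct(self) -> float:
        """Percent fewer wrong predictions when thresholding on T vs Y."""
        if self.min_wp_Y == 0:
            return 0.0
        return 100.0 * (self.min_wp_Y - self.min_wp_T) / self.min_wp_Y


def run_detection_experiment(
    preset: str,
    seed: int,
    sim_model=None,
    inf_model=None,
    k: int = DEFAULT_K,
    d_max: int = DEFAULT_DMAX,
    keep_em: bool = False,
    _cache: dict | None = None,
) -> DetectionExperiment:
    """Simulate a preset, estimate T, and sweep thresholds on Y and T.

    ``sim_model`` drives the simulator (uniform rate or read profile);
    ``inf_model`` drives the neighborhood weights (uniform or kmer-position
    model).  Defaults: matched uniform rate 0.006 on both sides.
    """
    sim_model = sim_model or UniformErrorModel(DEFAULT_PE)
    inf_model = inf_model or UniformErrorModel(DEFAULT_PE)
    t0 = time.time()
    genome, reads, truth = simulate_preset(preset, sim_model, seed=seed, k=k)
    spectrum = build_spectrum(reads, k)
    rows = build_neighbor_rows(spectrum, inf_model, d_max)
    est = run_em(spectrum, rows)
    truth_err = kmer_truth(spectrum, truth)

    grid = default_threshold_grid(np.maximum(spectrum.Y, est.T))
    MY, wpY = min_wp(wp_curve(spectrum.Y, truth_err, grid))
    MT, wpT = min_wp(wp_curve(est.T, truth_err, grid))
    logger.info(
        "%s seed=%d: |R^k|=%d, EM %d iter, min WP Y=%d (M=%g) T=%d (M=%g) [%.1fs]",
        preset, seed, spectrum.n, est.n_iterations, wpY, MY, wpT, MT, time.time() - t0,
    )
    out = DetectionExperiment(
        preset=preset,
        seed=seed,
        n_kmers=spectrum.n,
        min_wp_Y=wpY,
        min_wp_T=wpT,
        threshold_Y=MY,
        threshold_T=MT,
        em=est if keep_em else None,
    )
    if _cache is not None:
        _cache.update(
            genome=genome, reads=reads, truth=truth, spectrum=spectrum,
            rows=rows, est=est, truth_err=truth_err,
        )
    return out


def run_correction_experiment(
    preset: str,
    seed: int,
    sim_model=None,
    inf_model=None,
    k: int = DEFAULT_K,
    d_max: int = DEFAULT_DMAX,
    liberal_M: float | None = None,
    _cache: dict | None = None,
) -> CorrectionMetrics:
    """Full simulate -> estimate -> correct -> score run on a preset.

    ``liberal_M`` defaults to 3x the WP-optimal detection threshold on T.
    """
    cache: dict = {}
    expt = run_detection_experiment(
        preset, seed, sim_model, inf_model, k=k, d_max=d_max, _cache=cache
    )
    if liberal_M is None:
        liberal_M = 3.0 * max(expt.threshold_T, 1.0)
    corrected, records = correct_reads(
        cache["reads"], cache["spectrum"], cache["est"].T, cache["rows"], liberal_M
    )
    metrics = correction_metrics(
        cache["reads"], corrected, cache["truth"], cache["genome"]
    )
    logger.info(
        "%s seed=%d d_max=%d: %d corrections, sens=%.3f spec=%.5f gain=%.3f",
        preset, seed, d_max, len(records),
        metrics.sensitivity, metrics.specificity, metrics.gain,
    )
    if _cache is not None:
        _cache.update(cache, corrected=corrected, records=records, experiment=expt)
    return metrics
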