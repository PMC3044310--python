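"""Gamma + Normals + Uniform mixture on the attempt histogram.

The histogram of estimated attempts T is multi-modal: kmers absent from
the genome pile up near 0, and kmers with genomic occurrence g = 1, 2, ...
form peaks near g * c, where c is the coverage constant (attempt mass per
genomic occurrence).  The mixture fitted here has G + 2 components:

* a Gamma(shape a, rate b) for the erroneous kmers near 0;
* G Normal components for occurrence classes g = 1..G, with means
  mu_g = g * m and variances sigma_g^2 = g * v, the moments of a sum of g
  iid Negative Binomial deviates with mean m = mu*p/(1-p) and variance
  v = mu*p/(1-p)^2 (a Poisson read count whose rate is itself Gamma
  distributed; the Normal approximation is good when coverage is high);
* a Uniform over the observed range of T absorbing the few kmers with
  occurrence above G.

Parameters are estimated by EM; the number of occurrence classes G is
chosen by minimizing BIC; a kmer is classified erroneous when its
posterior membership in the Gamma component exceeds 0.5 (T = 0 is
assigned to the Gamma component deterministically).

The internal Normal parameterization is (m, v); the NegBin pair (mu, p)
is recovered as p = 1 - m/v, mu = m^2/(v - m) whenever v > m and reported
alongside.  The (m, v) M-step has closed-form weighted-ML updates; the
Gamma shape is the root of the usual digamma equation, found by a
bracketed 1-D solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

_TINY = 1e-300
_T_ZERO = 1e-12


@dataclass
class MixtureFit:
    """Fitted mixture over the attempt histogram."""

    G: int
    pi: np.ndarray  # (G + 2,): gamma, normals 1..G, uniform
    gamma_shape: float
    gamma_rate: float
    m: float  # normal mean spacing, = mu * p / (1 - p)
    v: float  # normal variance spacing, = mu * p / (1 - p)^2
    support: tuple[float, float]
    loglik: float = np.nan
    bic: float = np.nan
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def p(self) -> float:
        """NegBin success parameter implied by (m, v); clipped to (0, 1)."""
        return float(np.clip(1.0 - self.m / self.v, 1e-9, 1 - 1e-9))

    @property
    def mu(self) -> float:
        return self.m * (1.0 - self.p) / self.p

    def component_means(self) -> np.ndarray:
        return self.m * np.arange(1, self.G + 1)

    def component_densities(self, t: np.ndarray) -> np.ndarray:
        """Unweighted densities, shape (len(t), G + 2)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((t.size, self.G + 2))
        pos = t > _T_ZERO
        out[pos, 0] = stats.gamma.pdf(
            t[pos], a=self.gamma_shape, scale=1.0 / self.gamma_rate
        )
        for g in range(1, self.G + 1):
            out[:, g] = stats.norm.pdf(t, loc=g * self.m, scale=np.sqrt(g * self.v))
        lo, hi = self.support
        inside = (t >= lo) & (t <= hi)
        out[inside, self.G + 1] = 1.0 / max(hi - lo, _TINY)
        return out

    def responsibilities(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        dens = self.component_densities(t) * self.pi
        tot = dens.sum(axis=1, keepdims=True)
        z = dens / np.where(tot > 0, tot, 1.0)
        # T ~ 0 belongs to the gamma component deterministically (density
        # limit), as does anything out of every component's reach
        force = (t <= _T_ZERO) | (tot[:, 0] <= 0)
        if force.any():
            z[force] = 0.0
            z[force, 0] = 1.0
        return z

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "pi": [float(x) for x in self.pi],
            "gamma_shape": self.gamma_shape,
            "gamma_rate": self.gamma_rate,
            "m": self.m,
            "v": self.v,
            "mu": self.mu,
            "p": self.p,
            "support": list(self.support),
            "loglik": self.loglik,
            "bic": self.bic,
        }


def mixture_density(t, fit: MixtureFit) -> np.ndarray | float:
    """Mixture density at t (vectorized)."""
    dens = (fit.component_densities(np.atleast_1d(t)) * fit.pi).sum(axis=1)
    return dens if np.ndim(t) else float(dens[0])


def _solve_shape(gap: float) -> float:
    """Root of log(a) - digamma(a) = gap on a wide bracket."""
    if gap <= 0:  # numerically degenerate (zero-variance component)
        return 1e3
    f = lambda a: np.log(a) - special.digamma(a) - gap
    lo, hi = 1e-6, 1e6
    if f(lo) < 0 or f(hi) > 0:
        raise RuntimeError("gamma shape root not bracketed (parameter: shape)")
    return float(optimize.brentq(f, lo, hi))


def _gamma_ml(mean: float, meanlog: float, mean_cap: float | None) -> tuple[float, float]:
    """Weighted-ML gamma (shape, rate), optionally with mean <= mean_cap.

    The cap expresses an identifiability constraint: the gamma component
    describes erroneous kmers, whose attempt mass sits well below the
    single-occurrence coverage peak; without it a high-shape gamma can
    impersonate one of the normal components.  When the cap binds, the
    shape maximizes the weighted likelihood along the mean = cap boundary
    (still a proper constrained M-step, so EM stays monotone).
    """
    if mean_cap is not None and mean > mean_cap:
        gap = np.log(mean_cap) - meanlog + mean / mean_cap - 1.0
        shape = _solve_shape(gap)
        return shape, shape / mean_cap
    shape = _solve_shape(np.log(mean) - meanlog)
    return shape, shape / mean


def fit_mixture(
    T: np.ndarray, G: int, max_iter: int = 500, tol: float = 1e-8
) -> MixtureFit:
    """EM fit of the (G + 2)-component mixture to the attempt vector T.

    The likelihood surface has local optima when the initial class
    spacing lands between histogram peaks, so EM is restarted from a
    small deterministic set of candidate spacings (the dominant peak,
    half of it, and the median of the above-mean mass) and the best
    final likelihood wins.  Everything is deterministic; there is no
    randomness to seed.
    """
    T = np.asarray(T, dtype=float)
    candidates = _spacing_candidates(T)
    best: MixtureFit | None = None
    err: Exception | None = None
    for m0 in candidates:
        try:
            fit = _fit_mixture_from(T, G, m0, max_iter, tol)
        except (ValueError, RuntimeError) as exc:
            err = exc
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise err if err is not None else RuntimeError("mixture fit failed")
    return best


def _spacing_candidates(T: np.ndarray) -> list[float]:
    cut = float(np.quantile(T, 0.20))
    above_mean = T[T > max(cut, float(np.mean(T)))]
    upper = above_mean if above_mean.size >= 50 else T[T > cut]
    cands = []
    if upper.size:
        counts, edges = np.histogram(upper, bins=100)
        peak = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
        cands += [peak, peak / 2.0]
        cands.append(float(np.median(upper)))
    else:
        cands.append(max(float(np.mean(T)), 1.0))
    return [max(c, 1e-6) for c in cands]


def _fit_mixture_from(
    T: np.ndarray, G: int, m_init: float, max_iter: int, tol: float
) -> MixtureFit:
    n = T.size
    if n < 10 * (G + 4):
        raise ValueError(f"need at least {10 * (G + 4)} points to fit G={G}")
    lo, hi = float(T.min()), float(T.max())

    # deterministic initialization; the uniform catch-all is for the few
    # kmers beyond class G, so it starts with little weight (letting it
    # start as an equal partner lets it swallow the other components' tails
    # and traps EM in a poor optimum)
    pi = np.full(G + 2, 0.98 / (G + 1))
    pi[G + 1] = 0.02
    low = T[T <= np.quantile(T, 0.10)]
    med_low = float(np.median(low)) if low.size and np.median(low) > 0 else 1.0
    shape, rate = 1.0, 1.0 / med_low
    m = m_init
    v = 2.0 * m  # p = 0.5 start
    fit = MixtureFit(G=G, pi=pi, gamma_shape=shape, gamma_rate=rate, m=m, v=v, support=(lo, hi))

    g_idx = np.arange(1, G + 1)
    prev_ll = -np.inf
    trace: list[float] = []
    for _ in range(max_iter):
        dens = fit.component_densities(T) * fit.pi
        tot = dens.sum(axis=1)
        ll = float(np.sum(np.log(np.maximum(tot, _TINY))))
        trace.append(ll)
        z = fit.responsibilities(T)

        N = z.sum(axis=0)  # component occupancies N_g
        empty = N < 1e-8
        if empty.any():
            warnings.warn(
                f"pruning {int(empty.sum())} empty mixture component(s)", RuntimeWarning
            )
        pi = N / n

        # normal classes first: closed-form weighted ML in (m, v)
        zg = z[:, 1 : G + 1]
        Ng = zg.sum()
        if Ng > 1e-8:
            m = float(np.sum(zg * T[:, None]) / np.sum(zg * g_idx))
            m = max(m, 1e-6)
            dev = (T[:, None] - g_idx * m) ** 2 / g_idx
            v = max(float(np.sum(zg * dev) / Ng), 1e-9)
        # gamma component (weighted ML on T > 0), mean capped below the
        # freshly updated single-occurrence peak
        z0 = z[:, 0]
        tpos = np.maximum(T, _T_ZERO)
        N0 = z0.sum()
        if N0 > 1e-8:
            mean0 = float(np.sum(z0 * tpos) / N0)
            meanlog0 = float(np.sum(z0 * np.log(tpos)) / N0)
            cap = 0.5 * m if Ng > 1e-8 else None
            shape, rate = _gamma_ml(mean0, meanlog0, cap)
        fit = MixtureFit(
            G=G, pi=pi, gamma_shape=shape, gamma_rate=rate, m=m, v=v, support=(lo, hi)
        )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            break
        prev_ll = ll

    dens = fit.component_densities(T) * fit.pi
    fit.loglik = float(np.sum(np.log(np.maximum(dens.sum(axis=1), _TINY))))
    trace.append(fit.loglik)
    n_params = (G + 1) + 2 + 2  # free mixing weights + gamma + negbin
    fit.bic = -2.0 * fit.loglik + n_params * np.log(n)
    fit.loglik_trace = trace
    return fit


def select_G(T: np.ndarray, G_range=range(1, 5), **kwargs) -> MixtureFit:
    """Fit each candidate number of occurrence classes; keep the BIC minimizer."""
    fits: list[MixtureFit] = []
    errors: list[str] = []
    for G in G_range:
        try:
            fits.append(fit_mixture(T, G, **kwargs))
        except (ValueError, RuntimeError) as exc:
            errors.append(f"G={G}: {exc}")
    if not fits:
        raise RuntimeError("all mixture fits failed: " + "; ".join(errors))
    return min(fits, key=lambda f: f.bic)


def classify_erroneous(T: np.ndarray, fit: MixtureFit, tau: float = 0.5) -> np.ndarray:
    """Erroneous iff posterior membership in the gamma component exceeds tau."""
    z = fit.responsibilities(np.asarray(T, dtype=float))
    return z[:, 0] > tau
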