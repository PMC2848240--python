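"""Multi-point HBD estimation with a two-state hidden Markov model.

The hidden state at each marker is HBD / non-HBD.  The chain is stationary
with P(HBD) = f, and switches states along the genome at exchange rate
``a`` per Morgan: over genetic distance d, with r = exp(-a d),

    P(HBD -> HBD)     = r + f (1 - r)      P(HBD -> non) = (1 - f)(1 - r)
    P(non -> HBD)     = f (1 - r)          P(non -> non) = r + (1 - f)(1 - r)

so the stationary vector is (f, 1 - f) and d -> 0 / d -> inf give the
identity / stationary limits.  Emissions are the per-marker genotype
probabilities of :func:`hbdkit.singlepoint.hbd_emission_probs`; chromosomes
are independent, each started at the stationary distribution.  The
inbreeding coefficient is estimated by joint maximization of the forward
log-likelihood over (f, a).  Long homozygous stretches drive f upward far
more than isolated homozygous markers — the essential difference from the
single-point estimators.

The forward/backward recursions are numba-compiled: one likelihood
evaluation walks a few thousand markers and the MLE needs hundreds of
evaluations per individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .genotypes import FrequencySource, MarkerMap
from .singlepoint import hbd_emission_probs

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass
class HMMParams:
    f: float
    a: float  # per Morgan
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must lie in [0, 1]")
        if self.a <= 0:
            raise ValueError("a must be positive")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")


def transition_matrix(params: HMMParams, distance_morgans: float) -> np.ndarray:
    """2x2 transition matrix over ``distance_morgans``; rows = (HBD, non)."""
    if distance_morgans < 0:
        raise ValueError("distance must be non-negative")
    r = np.exp(-params.a * distance_morgans)
    f = params.f
    return np.array(
        [
            [r + f * (1.0 - r), (1.0 - f) * (1.0 - r)],
            [f * (1.0 - r), r + (1.0 - f) * (1.0 - r)],
        ]
    )


@njit(cache=True)
def _forward_ll(eh, en, dist, f, a):
    """Scaled forward pass; dist[i] < 0 marks a chromosome start."""
    ll = 0.0
    ah = 0.0
    an = 0.0
    for i in range(eh.shape[0]):
        if dist[i] < 0.0:
            ph = f * eh[i]
            pn = (1.0 - f) * en[i]
        else:
            r = np.exp(-a * dist[i])
            one_r = 1.0 - r
            ph = (ah * (r + f * one_r) + an * f * one_r) * eh[i]
            pn = (ah * (1.0 - f) * one_r + an * (r + (1.0 - f) * one_r)) * en[i]
        s = ph + pn
        if s <= 0.0:
            return -np.inf
        ll += np.log(s)
        ah = ph / s
        an = pn / s
    return ll


@njit(cache=True)
def _forward_backward(eh, en, dist, f, a):
    """Posterior P(HBD | all genotypes on the chromosome) per marker."""
    n = eh.shape[0]
    alpha_h = np.empty(n)
    alpha_n = np.empty(n)
    ah = 0.0
    an = 0.0
    for i in range(n):
        if dist[i] < 0.0:
            ph = f * eh[i]
            pn = (1.0 - f) * en[i]
        else:
            r = np.exp(-a * dist[i])
            one_r = 1.0 - r
            ph = (ah * (r + f * one_r) + an * f * one_r) * eh[i]
            pn = (ah * (1.0 - f) * one_r + an * (r + (1.0 - f) * one_r)) * en[i]
        s = ph + pn
        ah = ph / s
        an = pn / s
        alpha_h[i] = ah
        alpha_n[i] = an
    post = np.empty(n)
    bh = 1.0
    bn = 1.0
    for i in range(n - 1, -1, -1):
        if i == n - 1 or dist[i + 1] < 0.0:
            bh = 1.0
            bn = 1.0
        else:
            r = np.exp(-a * dist[i + 1])
            one_r = 1.0 - r
            nh = (r + f * one_r) * eh[i + 1] * bh + (1.0 - f) * one_r * en[i + 1] * bn
            nn = f * one_r * eh[i + 1] * bh + (r + (1.0 - f) * one_r) * en[i + 1] * bn
            s = nh + nn
            bh = nh / s
            bn = nn / s
        num = alpha_h[i] * bh
        post[i] = num / (num + alpha_n[i] * bn)
    return post


def _chain_arrays(
    genotypes: np.ndarray,
    markers: MarkerMap,
    freqs: FrequencySource,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Emissions + inter-marker distances with chromosome-start sentinels.

    Missing and frequency-undefined markers stay in the chain with emission
    1 in both states (equivalent to summing distances across them).
    """
    eh, en, use = hbd_emission_probs(genotypes, freqs, error_rate)
    dist = np.empty(len(markers))
    for sl in markers.chrom_slices():
        dist[sl.start] = -1.0
        if sl.stop - sl.start > 1:
            dist[sl.start + 1 : sl.stop] = np.diff(markers.genetic_pos[sl])
    return eh, en, dist, int(use.sum())


def forward_loglik(
    genotypes: np.ndarray,
    markers: MarkerMap,
    freqs: FrequencySource,
    params: HMMParams,
) -> float:
    """Log-likelihood of one individual's genotypes under the HBD chain.

    Chromosomes contribute independent terms, each initialized at the
    stationary distribution (f, 1 - f).
    """
    eh, en, dist, _ = _chain_arrays(genotypes, markers, freqs, params.error_rate)
    ll = _forward_ll(eh, en, dist, params.f, params.a)
    if np.isnan(ll):
        raise FloatingPointError("non-finite forward likelihood")
    return float(ll)


def hbd_posterior(
    genotypes: np.ndarray,
    markers: MarkerMap,
    freqs: FrequencySource,
    params: HMMParams,
) -> np.ndarray:
    """Forward-backward smoothed P(HBD) per marker, typically at the MLE."""
    if params.f == 0.0:
        return np.zeros(len(markers))
    eh, en, dist, _ = _chain_arrays(genotypes, markers, freqs, params.error_rate)
    return _forward_backward(eh, en, dist, params.f, params.a)


@dataclass
class FEstimResult:
    f: float
    a: float
    loglik: float
    converged: bool
    at_boundary: bool
    n_markers_used: int


DEFAULT_STARTS: tuple[tuple[float, float], ...] = tuple(
    (f0, a0) for f0 in (0.001, 0.0625, 0.25) for a0 in (0.1, 1.0, 10.0)
)

#: reduced start set for large replicate sweeps; covers the small-f basin,
#: a first-cousin-scale basin, and a high-f/high-a basin
FAST_STARTS: tuple[tuple[float, float], ...] = ((0.01, 1.0), (0.0625, 6.0), (0.25, 20.0))


def festim_mle(
    genotypes: np.ndarray,
    markers: MarkerMap,
    freqs: FrequencySource,
    error_rate: float = 0.0,
    a_bounds: tuple[float, float] = (0.01, 100.0),
    starts=DEFAULT_STARTS,
    fatol: float = 1e-6,
    xatol: float = 1e-4,
    maxiter: int = 400,
) -> FEstimResult:
    """Joint ML estimate of (f, a) by multistart bounded Nelder-Mead.

    The search runs on (logit f, logit-scaled a) so both parameters stay
    inside their boxes; an explicit f = 0 evaluation afterwards lets the
    estimate land exactly on the boundary (the likelihood there does not
    depend on a).  ``fatol`` is the convergence tolerance on the
    log-likelihood.
    """
    eh, en, dist, n_used = _chain_arrays(genotypes, markers, freqs, error_rate)
    if n_used == 0:
        return FEstimResult(np.nan, np.nan, np.nan, False, False, 0)
    a_min, a_max = a_bounds
    log_amin, log_amax = np.log(a_min), np.log(a_max)

    def unpack(t: np.ndarray) -> tuple[float, float]:
        f = float(expit(t[0]))
        a = float(np.exp(log_amin + (log_amax - log_amin) * expit(t[1])))
        return f, a

    def neg_ll(t: np.ndarray) -> float:
        f, a = unpack(t)
        ll = _forward_ll(eh, en, dist, f, a)
        return -ll if np.isfinite(ll) else 1e300

    best: tuple[float, float, float, bool] | None = None  # (ll, f, a, success)
    n_failed = 0
    for f0, a0 in starts:
        t0 = np.array(
            [
                logit(np.clip(f0, 1e-6, 1 - 1e-6)),
                logit(np.clip((np.log(a0) - log_amin) / (log_amax - log_amin), 1e-6, 1 - 1e-6)),
            ]
        )
        try:
            res = minimize(
                neg_ll,
                t0,
                method="Nelder-Mead",
                options={"fatol": fatol, "xatol": xatol, "maxiter": maxiter},
            )
        except Exception:
            n_failed += 1
            continue
        f_hat, a_hat = unpack(res.x)
        ll = -res.fun
        if best is None or ll > best[0]:
            best = (ll, f_hat, a_hat, bool(res.success))
    if best is None:
        raise RuntimeError(f"festim_mle: all {n_failed} optimizer starts failed")
    ll_best, f_hat, a_hat, success = best
    # the f = 0 boundary: genotypes all emitted from the non-HBD state
    ll0 = _forward_ll(eh, en, dist, 0.0, a_hat)
    if np.isfinite(ll0) and ll0 >= ll_best - fatol and f_hat < 0.01:
        f_hat, ll_best = 0.0, max(ll0, ll_best)
    at_boundary = (
        f_hat in (0.0, 1.0)
        or a_hat <= a_min * 1.001
        or a_hat >= a_max * 0.999
    )
    return FEstimResult(f_hat, a_hat, float(ll_best), success, at_boundary, n_used)


def simulate_from_hmm(
    markers: MarkerMap,
    params: HMMParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (genotypes, hbd_states) from the model's own generative process.

    Used for parameter-recovery checks: states follow the stationary chain
    along each chromosome, genotypes follow the emission model.
    """
    n = len(markers)
    p = markers.freq_a1
    states = np.empty(n, dtype=bool)
    for sl in markers.chrom_slices():
        h = rng.random() < params.f
        states[sl.start] = h
        pos = markers.genetic_pos[sl]
        for k in range(1, sl.stop - sl.start):
            r = np.exp(-params.a * (pos[k] - pos[k - 1]))
            stay = r + (params.f if h else 1.0 - params.f) * (1.0 - r)
            if rng.random() >= stay:
                h = not h
            states[sl.start + k] = h
    eps = params.error_rate
    q = 1.0 - p
    probs_hbd = np.stack([(1 - eps) * p + eps * p * p, eps * 2 * p * q, (1 - eps) * q + eps * q * q])
    probs_non = np.stack([p * p, 2 * p * q, q * q])
    u = rng.random(n)
    geno = np.empty(n, dtype=np.int8)
    for m in range(n):
        pr = probs_hbd[:, m] if states[m] else probs_non[:, m]
        geno[m] = np.searchsorted(np.cumsum(pr), u[m])
    return geno, states
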