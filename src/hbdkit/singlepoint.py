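"""Single-point (marker-independent) homozygosity estimators.

Four measures that treat every marker independently:

* ``mlh`` — multilocus heterozygosity, the fraction of heterozygous calls.
* ``f_plink`` — method-of-moments F from genome-wide expected homozygosity,
  (O - E) / (L - E), as computed by PLINK's ``--het``.
* ``f_adc`` — inverse-variance-weighted average of per-locus homozygosity
  deviations.
* ``festim_spt`` — maximum-likelihood F under a per-marker mixture of an
  HBD and a non-HBD (Hardy-Weinberg) emission model; the single-point
  degenerate case of the hidden-Markov estimator in :mod:`hbdkit.hmm`.

All four skip exactly the same markers (missing call, or undefined /
monomorphic frequency) so ``n_markers_used`` is comparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .genotypes import HET, MISSING, FrequencySource


@dataclass
class SinglePointEstimate:
    individual_id: str
    method: str
    value: float
    n_markers_used: int
    flag: str | None = None


def _usable(genotypes: np.ndarray, freqs: FrequencySource) -> np.ndarray:
    """Mask of markers entering the estimate: called, 0 < p < 1."""
    g = np.asarray(genotypes)
    with np.errstate(invalid="ignore"):
        ok = (g != MISSING) & np.isfinite(freqs.values) & (freqs.values > 0) & (freqs.values < 1)
    return ok


def mlh(genotypes: np.ndarray) -> tuple[float, int]:
    """Proportion of heterozygous loci among non-missing calls."""
    g = np.asarray(genotypes)
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        return np.nan, 0
    return float(np.sum(g[called] == HET) / n), n


def f_plink(genotypes: np.ndarray, freqs: FrequencySource) -> tuple[float, int]:
    """Moment estimator (O - E) / (L - E) over usable markers.

    E sums the per-marker expected homozygosity 1 - 2 p q c, where the
    small-sample factor c = 2N/(2N-1) applies only when frequencies were
    estimated from the sample itself (N = non-missing individuals at the
    marker); externally provided frequencies use c = 1.
    """
    use = _usable(genotypes, freqs)
    L = int(use.sum())
    if L == 0:
        return np.nan, 0
    p = freqs.values[use]
    if freqs.mode == "sample_estimated" and freqs.n_nonmissing is not None:
        twoN = 2.0 * freqs.n_nonmissing[use]
        c = np.where(twoN > 1, twoN / np.maximum(twoN - 1.0, 1.0), 1.0)
    else:
        c = 1.0
    exp_hom = np.sum(1.0 - 2.0 * p * (1.0 - p) * c)
    obs_hom = float(np.sum(np.asarray(genotypes)[use] != HET))
    denom = L - exp_hom
    if denom <= 0:
        return np.nan, L
    return float((obs_hom - exp_hom) / denom), L


def f_adc(genotypes: np.ndarray, freqs: FrequencySource) -> tuple[float, int]:
    """Inverse-variance-weighted mean of per-locus homozygosity deviations.

    Per usable locus with expected homozygosity e = 1 - 2pq and observed
    o in {0, 1}: f_l = (o - e) / (1 - e), weighted by w_l = (1 - e) / e,
    the reciprocal null (f = 0) variance of f_l.
    """
    use = _usable(genotypes, freqs)
    L = int(use.sum())
    if L == 0:
        return np.nan, 0
    p = freqs.values[use]
    e = 1.0 - 2.0 * p * (1.0 - p)
    o = (np.asarray(genotypes)[use] != HET).astype(float)
    f_l = (o - e) / (1.0 - e)
    w = (1.0 - e) / e
    wsum = w.sum()
    if not np.isfinite(wsum) or wsum <= 0:
        return np.nan, L
    return float(np.sum(w * f_l) / wsum), L


def hbd_emission_probs(
    genotypes: np.ndarray, freqs: FrequencySource, error_rate: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker P(genotype | HBD) and P(genotype | non-HBD).

    Under HBD the two alleles are copies of one ancestral allele, so with
    genotyping-error rate eps: P(hom_a1|HBD) = (1-eps) p + eps p^2,
    P(het|HBD) = eps 2pq, P(hom_a2|HBD) = (1-eps) q + eps q^2.  Under
    non-HBD the Hardy-Weinberg probabilities p^2, 2pq, q^2 apply.  Markers
    outside the usable mask get probability 1 in both states (no
    information).  Returns (P_hbd, P_nonhbd, usable_mask).
    """
    g = np.asarray(genotypes)
    use = _usable(g, freqs)
    p = np.where(use, freqs.values, 0.5)
    q = 1.0 - p
    eps = float(error_rate)
    hbd_by_code = np.stack(
        [(1 - eps) * p + eps * p * p, eps * 2 * p * q, (1 - eps) * q + eps * q * q]
    )
    non_by_code = np.stack([p * p, 2 * p * q, q * q])
    idx = np.clip(g, 0, 2)
    cols = np.arange(len(g))
    eh = np.where(use, hbd_by_code[idx, cols], 1.0)
    en = np.where(use, non_by_code[idx, cols], 1.0)
    return eh, en, use


def spt_loglik(f, eh: np.ndarray, en: np.ndarray) -> float | np.ndarray:
    """Single-point mixture log-likelihood sum_l log(f*eh + (1-f)*en)."""
    f = np.asarray(f, dtype=float)
    scalar = f.ndim == 0
    fv = np.atleast_1d(f)[:, None]
    with np.errstate(divide="ignore"):
        ll = np.sum(np.log(fv * eh + (1.0 - fv) * en), axis=1)
    return float(ll[0]) if scalar else ll


def festim_spt(
    genotypes: np.ndarray,
    freqs: FrequencySource,
    error_rate: float = 0.0,
    xatol: float = 1e-6,
) -> tuple[float, int]:
    """ML estimate of f in [0, 1] under the per-marker mixture model.

    The log-likelihood is concave in f (each term is log of a linear
    function of f), so one bounded Brent search plus explicit endpoint
    checks at f = 0 and f = 1 finds the global maximum.
    """
    eh, en, use = hbd_emission_probs(genotypes, freqs, error_rate)
    L = int(use.sum())
    if L == 0:
        return np.nan, 0
    ll0, ll1 = spt_loglik(np.array([0.0, 1.0]), eh, en)
    if not (np.isfinite(ll0) or np.isfinite(ll1)):
        return np.nan, L
    res = minimize_scalar(
        lambda f: -spt_loglik(f, eh, en),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": xatol},
    )
    cands = [(ll0, 0.0), (ll1, 1.0), (-res.fun, float(res.x))]
    best = max(cands, key=lambda t: t[0] if np.isfinite(t[0]) else -np.inf)
    return best[1], L


def truncate_negative(values) -> np.ndarray:
    """Clip negative estimates to zero (simulation-comparison convention).

    Applied to the moment estimators before comparing against true HBD;
    raw per-cohort output keeps negatives.
    """
    v = np.asarray(values, dtype=float)
    return np.where(v < 0, 0.0, v)
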