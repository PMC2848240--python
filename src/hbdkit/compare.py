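"""Comparison of HBD estimators on simulated and cohort data.

The central product is the simulation study: gene-drop replicates of
first/second/third-cousin offspring, all five estimators per replicate,
then per-estimator means, empirical central 95% ranges and a Spearman
correlation matrix against the known true HBD proportion.  Negative
values of the moment estimators are truncated to zero before the
comparison, so the comparison operates on the same scale as the
likelihood estimators (which cannot go negative).

Also here: the nonparametric group comparisons used on cohort data —
Mann-Whitney between neighbouring a-priori homozygosity groups, the
Wilcoxon signed-rank test on sibling pairs, and Spearman correlations
conditioned on being detectably inbred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import FrequencySource
from .hmm import FAST_STARTS, festim_mle
from .simulate import SimMap, simulate_replicates
from .singlepoint import f_adc, f_plink, festim_spt, mlh, truncate_negative

ESTIMATOR_COLUMNS = ["MLH", "F_PLINK", "F_ADC", "FEstimSPT", "FEstim"]
SIGNIFICANCE_LEVEL = 0.05


@dataclass
class SimulationSummary:
    """Per-degree analogue of one block of the simulation results table."""

    degree: int
    n_replicates: int
    n_dropped: int
    table: pd.DataFrame  # replicate x (true_hbd + estimators)
    means: pd.Series
    interval: pd.DataFrame  # rows lo/hi = empirical 2.5% / 97.5% quantiles
    correlations: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def estimate_all(
    genotypes: np.ndarray,
    sim_map: SimMap,
    freqs: FrequencySource,
    estimators: list[str],
    error_rate: float = 0.0,
    festim_starts=FAST_STARTS,
) -> dict[str, float]:
    out: dict[str, float] = {}
    if "MLH" in estimators:
        out["MLH"] = mlh(genotypes)[0]
    if "F_PLINK" in estimators:
        out["F_PLINK"] = f_plink(genotypes, freqs)[0]
    if "F_ADC" in estimators:
        out["F_ADC"] = f_adc(genotypes, freqs)[0]
    if "FEstimSPT" in estimators:
        out["FEstimSPT"] = festim_spt(genotypes, freqs, error_rate)[0]
    if "FEstim" in estimators:
        out["FEstim"] = festim_mle(
            genotypes, sim_map.markers, freqs, error_rate, starts=festim_starts
        ).f
    return out


def simulate_estimates(
    degree: int,
    n_replicates: int,
    sim_map: SimMap,
    seed: int | np.random.SeedSequence,
    estimators: list[str] | None = None,
    error_rate: float = 0.0,
    festim_starts=FAST_STARTS,
) -> pd.DataFrame:
    """Replicate x (true_hbd + estimators) table for one cousin degree.

    Allele frequencies are the map's true frequencies (provided mode):
    each replicate holds a single simulated proband, so sample estimation
    is not possible.  Moment-estimator negatives are NOT yet truncated.
    """
    estimators = estimators or ESTIMATOR_COLUMNS
    freqs = FrequencySource("provided", sim_map.markers.freq_a1)
    rows = []
    for i, geno, track in simulate_replicates(degree, n_replicates, sim_map, seed):
        row = {"replicate": i, "true_hbd": track.f_true}
        row.update(
            estimate_all(geno, sim_map, freqs, estimators, error_rate, festim_starts)
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("replicate")


def summarize_simulation(
    table: pd.DataFrame,
    degree: int,
    truncate: bool = True,
    corr_method: str = "spearman",
    metadata: dict | None = None,
) -> SimulationSummary:
    """Means, empirical 95% ranges and the correlation matrix of one block."""
    tab = table.copy()
    if truncate:
        for col in ("F_PLINK", "F_ADC"):
            if col in tab:
                tab[col] = truncate_negative(tab[col].to_numpy())
    complete = tab.dropna()
    n_dropped = len(tab) - len(complete)
    means = complete.mean()
    interval = complete.quantile([0.025, 0.975])
    interval.index = ["lo", "hi"]
    corr = correlation_matrix(complete, method=corr_method)
    meta = dict(metadata or {})
    meta.update(
        truncation_applied=truncate,
        interval="empirical central 95% range of replicates",
        correlation=corr_method,
    )
    return SimulationSummary(degree, len(complete), n_dropped, tab, means, interval, corr, meta)


def run_simulation_study(
    degree_list: list[int],
    n_replicates: int,
    sim_map: SimMap,
    estimators: list[str] | None = None,
    seed: int = 0,
    error_rate: float = 0.0,
    festim_starts=FAST_STARTS,
    corr_method: str = "spearman",
) -> dict[int, SimulationSummary]:
    """The full simulation study: one summary block per cousin degree."""
    root = np.random.SeedSequence(seed)
    out: dict[int, SimulationSummary] = {}
    for degree, child in zip(degree_list, root.spawn(len(degree_list))):
        table = simulate_estimates(
            degree, n_replicates, sim_map, child, estimators, error_rate, festim_starts
        )
        out[degree] = summarize_simulation(
            table,
            degree,
            truncate=True,
            corr_method=corr_method,
            metadata={"seed": seed, "map": sim_map.params},
        )
    return out


def correlation_matrix(table: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Pairwise rank (or Pearson) correlations, pairwise-complete rows.

    Constant columns yield NaN entries (flagged, not errors); diagonal 1
    wherever the column has any variation.
    """
    if len(table.dropna(how="all")) < 3:
        raise ValueError("need >= 3 rows for a correlation matrix")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    return table.corr(method=method)


def neighbouring_group_tests(
    estimates: pd.Series, grouping: pd.Series, all_pairs: bool = False
) -> pd.DataFrame:
    """Mann-Whitney tests between neighbouring (or all) ordered groups.

    Groups are ordered by their label's sort order (a-priori expected
    homozygosity).  The exact null distribution is used when the smaller
    group has <= 8 members, the tie-corrected normal approximation
    otherwise.  Returns (group_a, group_b, n_a, n_b, p, significant).
    """
    groups = sorted(grouping.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pairs = (
        [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
        if all_pairs
        else list(zip(groups[:-1], groups[1:]))
    )
    rows = []
    for ga, gb in pairs:
        xa = estimates[grouping == ga].dropna().to_numpy()
        xb = estimates[grouping == gb].dropna().to_numpy()
        if len(xa) == 0 or len(xb) == 0:
            rows.append((ga, gb, len(xa), len(xb), np.nan, "empty group"))
            continue
        method = "exact" if min(len(xa), len(xb)) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append((ga, gb, len(xa), len(xb), float(res.pvalue), ""))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p", "note"])
    df["significant"] = df["p"] < SIGNIFICANCE_LEVEL
    return df


def sibling_pair_test(
    estimates: pd.Series, sib_pairs: list[tuple[str, str]]
) -> tuple[float, float, str]:
    """Wilcoxon signed-rank on within-sib-pair differences.

    Zero differences are dropped and ties get average ranks.  Returns
    (statistic, two-sided p, note); all-zero differences give p = 1.
    """
    if not sib_pairs:
        raise ValueError("need >= 1 sibling pair")
    diffs = np.array([estimates[a] - estimates[b] for a, b in sib_pairs])
    diffs = diffs[np.isfinite(diffs)]
    if len(diffs) == 0:
        raise ValueError("no pair has both members estimated")
    if np.all(diffs == 0):
        return 0.0, 1.0, "all within-pair differences are zero"
    res = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue), ""


def conditional_correlation(
    estimates: pd.DataFrame,
    col_x: str,
    col_y: str,
    condition_column: str | None = None,
    threshold: float = 0.0,
    method: str = "spearman",
) -> tuple[float, int]:
    """Correlation of two estimate columns on the subset where
    ``condition_column`` (default ``col_y``) exceeds ``threshold``.

    Used to re-correlate estimators among detectably inbred individuals
    (e.g. dropping everyone the stricter marker set calls exactly zero).
    Returns (rho, subset size); rho is NaN when fewer than 3 rows remain.
    """
    cond = condition_column or col_y
    sub = estimates[estimates[cond] > threshold][[col_x, col_y]].dropna()
    if len(sub) < 3:
        return np.nan, len(sub)
    rho = sub[col_x].corr(sub[col_y], method=method)
    return float(rho), len(sub)
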