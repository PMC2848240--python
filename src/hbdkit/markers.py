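"""Marker quality control and LD-threshold marker selection.

QC mirrors standard genome-wide association practice: individuals are
dropped first on call rate, then markers on Hardy-Weinberg departure
(exact test), call rate and minor-allele frequency — in that order, each
filter acting on the survivors of the previous one.

LD selection is a greedy per-chromosome scan that guarantees no retained
pair of markers within a genetic window exceeds an r-squared threshold,
preferring to keep the more informative (higher-MAF) member of an
offending pair.  It approximates information-content-maximizing marker
selection tools used to prepare SNP panels for multi-point linkage and
autozygosity methods, which assume linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeDataset, estimate_frequencies

_A1_COUNT = np.array([2.0, 1.0, 0.0])  # dosage per genotype code


@dataclass
class QCThresholds:
    max_individual_missing: float = 0.05
    min_marker_callrate: float = 0.95
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-7


@dataclass
class SelectionReport:
    """Per-stage removal counts plus the surviving ids."""

    stages: list[tuple[str, int]] = field(default_factory=list)
    retained_individuals: list[str] = field(default_factory=list)
    retained_markers: list[str] = field(default_factory=list)

    def removed(self, stage: str) -> int:
        for name, n in self.stages:
            if name == stage:
                return n
        raise KeyError(stage)

    def to_lines(self) -> list[str]:
        out = [f"{name}\t{n}" for name, n in self.stages]
        out.append(f"retained_individuals\t{len(self.retained_individuals)}")
        out.append(f"retained_markers\t{len(self.retained_markers)}")
        return out


def hwe_exact_test(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact Hardy-Weinberg test on one marker's genotype counts.

    Conditional on the observed allele counts, the heterozygote count has
    an exact distribution under HWE; the p-value is the total probability
    of all heterozygote counts no more probable than the observed one
    (no mid-p adjustment).  Probabilities are built by the stable ratio
    recurrence P(h+2)/P(h) = 4 n_aa n_bb / ((h+2)(h+1)), walking out from
    the modal count.  Monomorphic markers return p = 1.
    """
    if min(n_hom_a1, n_het, n_hom_a2) < 0 or n_hom_a1 + n_het + n_hom_a2 < 1:
        raise ValueError("counts must be non-negative with total >= 1")
    n = n_hom_a1 + n_het + n_hom_a2
    n_a = 2 * n_hom_a1 + n_het  # copies of the rarer-or-not allele 1
    n_b = 2 * n_hom_a2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # valid heterozygote counts share the parity of the rare-allele count
    h_values = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(len(h_values))
    # start at the largest valid h and recurse downward:
    # P(h-2)/P(h) = h (h-1) / (4 (n_aa+1)(n_bb+1))
    probs[-1] = 1.0
    for i in range(len(h_values) - 1, 0, -1):
        h = h_values[i]
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (naa + 1) * (nbb + 1))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(h_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeDataset, SelectionReport]:
    """Sequential QC: individual call rate, then marker HWE / call rate / MAF."""
    report = SelectionReport()

    ind_miss = dataset.individual_missingness()
    keep_ind = np.flatnonzero(ind_miss <= thresholds.max_individual_missing)
    report.stages.append(("individuals_low_callrate", dataset.n_individuals - len(keep_ind)))
    ds = dataset.subset(individuals=keep_ind)

    counts = ds.genotype_counts()
    hwe_p = np.array(
        [
            hwe_exact_test(r.n_hom_a1, r.n_het, r.n_hom_a2)
            if (r.n_hom_a1 + r.n_het + r.n_hom_a2) > 0
            else 1.0
            for r in counts.itertuples()
        ]
    )
    keep = hwe_p > thresholds.hwe_p_floor
    report.stages.append(("markers_hwe", int(np.sum(~keep))))
    ds = ds.subset(markers=np.flatnonzero(keep))

    callrate = 1.0 - ds.marker_missingness()
    keep = callrate >= thresholds.min_marker_callrate
    report.stages.append(("markers_low_callrate", int(np.sum(~keep))))
    ds = ds.subset(markers=np.flatnonzero(keep))

    freqs = estimate_frequencies(ds)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freqs.values, 1.0 - freqs.values)
    keep = ~(maf < thresholds.min_maf)  # NaN-frequency markers were all-missing: none left here
    keep &= np.isfinite(maf)
    report.stages.append(("markers_low_maf", int(np.sum(~keep))))
    ds = ds.subset(markers=np.flatnonzero(keep))

    report.retained_individuals = list(ds.individuals)
    report.retained_markers = list(ds.markers.marker_id)
    return ds, report


def ld_r2(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Composite (genotypic) r^2: squared Pearson correlation of allele
    dosages over pairwise-complete individuals.

    Zero variance in either vector (or < 2 complete pairs) is undefined and
    returned as 0.0, which the pruning scan treats as "no LD".
    """
    a = np.asarray(vec_a)
    b = np.asarray(vec_b)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = _A1_COUNT[a[ok]]
    y = _A1_COUNT[b[ok]]
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def select_markers_ld(
    dataset: GenotypeDataset,
    r2_threshold: float,
    window_cm: float = 0.5,
    ld_reference: GenotypeDataset | None = None,
) -> tuple[list[str], SelectionReport]:
    """Greedy LD pruning: within each chromosome, any retained pair closer
    than ``window_cm`` is guaranteed to have r^2 <= ``r2_threshold``.

    When a new marker conflicts with already-retained ones, the lower-MAF
    member of each conflicting pair is dropped (tie: the later map
    position, i.e. the incoming marker, goes).  r^2 is computed on
    ``ld_reference`` if given (e.g. an external reference panel), else on
    ``dataset`` itself.
    """
    ld_ds = ld_reference if ld_reference is not None else dataset
    if ld_ds.n_markers != dataset.n_markers:
        raise ValueError("ld_reference must cover the same markers")
    freqs = estimate_frequencies(dataset)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freqs.values, 1.0 - freqs.values)
    maf = np.nan_to_num(maf, nan=0.0)
    window_m = window_cm / 100.0
    m = dataset.markers
    retained: list[int] = []
    for sl in m.chrom_slices():
        chrom_kept: list[int] = []
        for j in range(sl.start, sl.stop):
            conflicts = [
                k
                for k in chrom_kept
                if m.genetic_pos[j] - m.genetic_pos[k] <= window_m
                and ld_r2(ld_ds.calls[:, k], ld_ds.calls[:, j]) > r2_threshold
            ]
            if not conflicts:
                chrom_kept.append(j)
            elif all(maf[k] < maf[j] for k in conflicts):
                for k in conflicts:
                    chrom_kept.remove(k)
                chrom_kept.append(j)
            # else: some conflicting retained marker has MAF >= ours -> drop j
        retained.extend(chrom_kept)
    retained_ids = [m.marker_id[j] for j in sorted(retained)]
    report = SelectionReport(
        stages=[("markers_ld_pruned", dataset.n_markers - len(retained_ids))],
        retained_individuals=list(dataset.individuals),
        retained_markers=retained_ids,
    )
    return retained_ids, report
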