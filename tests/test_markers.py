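import itertools
from math import lgamma

import numpy as np
import pytest

import hbdkit as hk
from hbdkit.genotypes import HET, HOM_A1, HOM_A2, MISSING, GenotypeDataset, MarkerMap
from hbdkit.markers import (
    QCThresholds,
    apply_qc,
    hwe_exact_test,
    ld_r2,
    select_markers_ld,
)


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent log-factorial enumeration of the exact HWE test."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab

    def log_prob(h):
        naa = (na - h) // 2
        nbb = (nb - h) // 2
        return (
            lgamma(n + 1) - lgamma(naa + 1) - lgamma(h + 1) - lgamma(nbb + 1)
            + h * np.log(2) + lgamma(na + 1) + lgamma(nb + 1) - lgamma(2 * n + 1)
        )

    hs = [h for h in range(min(na, nb) + 1) if (na - h) % 2 == 0 and h % 2 == min(na, nb) % 2]
    probs = {h: np.exp(log_prob(h)) for h in hs}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def dataset_from_calls(calls, spacing=0.008, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_mark = calls.shape
    chrom = np.ones(n_mark, int) if chrom is None else chrom
    m = MarkerMap([f"m{j}" for j in range(n_mark)], chrom,
                  np.arange(n_mark) * spacing)
    return GenotypeDataset([f"i{k}" for k in range(n_ind)], m, calls)


class TestHWEExactTest:
    @pytest.mark.parametrize(
        "counts",
        [(57, 14, 50), (25, 50, 25), (0, 20, 0), (3, 7, 90), (1, 1, 1)],
    )
    def test_matches_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_modal_counts_give_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_het_extreme(self):
        p = hwe_exact_test(0, 30, 0)
        assert 0 < p <= 1
        # p-value includes at least the all-het table itself:
        # P(h=30) = 2^30 * 30! 30! / 60!  (n! term cancels h!)
        assert p >= np.exp(30 * np.log(2) + 2 * lgamma(31) - lgamma(61)) * 0.999

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_uniform_conservative_under_null(self):
        # P(p <= alpha) <= alpha + tol for HWE-simulated markers
        rng = np.random.default_rng(13)
        n_markers, n_ind = 10000, 80
        pvals = np.empty(n_markers)
        for j in range(n_markers):
            p = rng.uniform(0.1, 0.9)
            g = rng.binomial(1, p, (n_ind, 2)).sum(axis=1)
            pvals[j] = hwe_exact_test(
                int(np.sum(g == 2)), int(np.sum(g == 1)), int(np.sum(g == 0))
            )
        for alpha in (0.01, 0.05, 0.1):
            assert np.mean(pvals <= alpha) <= alpha + 0.01


class TestApplyQC:
    def test_constructed_fixture_counts(self):
        # 6 individuals x 6 markers; one individual and one marker per filter:
        # ind5 fails call rate (3/6 missing); among the remaining 5,
        # m0 has a heterozygote deficit (2/0/3, exact p = 1/21 <= 0.05),
        # m1 has call rate 3/5, m2 has MAF 0.1; m3-m5 pass everything
        calls = np.array(
            [
                # m0      m1       m2      m3      m4      m5
                [HOM_A1, MISSING, HOM_A1, HOM_A1, HET, HOM_A2],
                [HOM_A1, MISSING, HOM_A1, HET, HOM_A1, HOM_A2],
                [HOM_A2, HOM_A1, HOM_A1, HOM_A1, HET, HET],
                [HOM_A2, HOM_A1, HOM_A1, HOM_A2, HOM_A1, HET],
                [HOM_A2, HOM_A1, HET, HET, HET, HOM_A2],
                [MISSING, MISSING, MISSING, HOM_A1, HET, HOM_A2],
            ],
            dtype=np.int8,
        )
        ds = dataset_from_calls(calls)
        filtered, report = apply_qc(
            ds, QCThresholds(max_individual_missing=0.4, min_marker_callrate=0.8,
                             min_maf=0.15, hwe_p_floor=0.05)
        )
        assert report.removed("individuals_low_callrate") == 1
        assert report.removed("markers_hwe") == 1
        assert report.removed("markers_low_callrate") == 1
        assert report.removed("markers_low_maf") == 1
        assert filtered.n_individuals == 5
        assert filtered.n_markers == 3

    def test_zero_missing_tolerance(self):
        calls = np.array([[HOM_A1, MISSING], [HET, HOM_A2]], dtype=np.int8)
        ds = dataset_from_calls(calls)
        filtered, report = apply_qc(
            ds, QCThresholds(max_individual_missing=0.0, min_marker_callrate=0.0,
                             min_maf=0.0, hwe_p_floor=0.0)
        )
        assert report.removed("individuals_low_callrate") == 1
        assert filtered.n_individuals == 1

    def test_idempotent(self, small_map):
        rng = np.random.default_rng(21)
        n_ind = 60
        p = small_map.markers.freq_a1
        calls = (
            (rng.random((n_ind, len(small_map))) < p).astype(np.int8)
            + (rng.random((n_ind, len(small_map))) < p).astype(np.int8)
        )
        calls = (2 - calls).astype(np.int8)  # dosage -> genotype code
        calls[rng.random(calls.shape) < 0.03] = MISSING
        ds = GenotypeDataset([f"i{k}" for k in range(n_ind)], small_map.markers, calls)
        once, _ = apply_qc(ds)
        twice, report2 = apply_qc(once)
        assert twice.n_individuals == once.n_individuals
        assert twice.n_markers == once.n_markers
        assert all(n == 0 for _, n in report2.stages)


class TestLDR2:
    def test_identical_vectors(self):
        v = np.array([HOM_A1, HET, HOM_A2, HET, HOM_A1], dtype=np.int8)
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        b = np.array([2, 2, 1, 1, 0, 0], dtype=np.int8)
        assert ld_r2(a, b) == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        a = np.full(5, HOM_A1, dtype=np.int8)
        b = np.array([HOM_A1, HET, HOM_A2, HET, HOM_A1], dtype=np.int8)
        assert ld_r2(a, b) == 0.0

    def test_haplotype_d_prime_oracle(self):
        # two loci with known haplotype frequencies: sample genotypic r^2
        # approaches D^2 / (pA qA pB qB)
        rng = np.random.default_rng(31)
        pA, pB, D = 0.6, 0.4, 0.12
        hap_probs = np.array([
            pA * pB + D, pA * (1 - pB) - D, (1 - pA) * pB - D, (1 - pA) * (1 - pB) + D,
        ])
        n = 6000
        haps = rng.choice(4, size=(n, 2), p=hap_probs)
        a1_a = (haps < 2).sum(axis=1)   # allele-1 dosage locus A
        a1_b = (haps % 2 == 0).sum(axis=1)
        ga = (2 - a1_a).astype(np.int8)
        gb = (2 - a1_b).astype(np.int8)
        r2_expected = D**2 / (pA * (1 - pA) * pB * (1 - pB))
        assert ld_r2(ga, gb) == pytest.approx(r2_expected, abs=0.03)


class TestSelectMarkersLD:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(41)
        base = rng.integers(0, 3, 40).astype(np.int8)
        other = rng.integers(0, 3, 40).astype(np.int8)
        ds = dataset_from_calls(np.column_stack([base, base, other]))
        retained, _ = select_markers_ld(ds, r2_threshold=0.5, window_cm=10)
        assert sorted(retained) == ["m1", "m2"] or sorted(retained) == ["m0", "m2"]
        assert len(retained) == 2

    def test_threshold_one_keeps_all(self):
        rng = np.random.default_rng(42)
        ds = dataset_from_calls(rng.integers(0, 3, (20, 12)).astype(np.int8))
        retained, _ = select_markers_ld(ds, r2_threshold=1.0, window_cm=10)
        assert len(retained) == 12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_no_retained_pair_above_threshold(self, seed):
        rng = np.random.default_rng(seed)
        # correlated blocks: duplicate some columns with noise
        cols = []
        for _ in range(15):
            c = rng.integers(0, 3, 30).astype(np.int8)
            cols.append(c)
            if rng.random() < 0.5:
                noisy = c.copy()
                flip = rng.random(30) < 0.15
                noisy[flip] = rng.integers(0, 3, flip.sum())
                cols.append(noisy)
        calls = np.column_stack(cols)
        ds = dataset_from_calls(calls, spacing=0.001)
        thr = 0.3
        retained, _ = select_markers_ld(ds, r2_threshold=thr, window_cm=0.5)
        idx = {mid: j for j, mid in enumerate(ds.markers.marker_id)}
        kept = [idx[m] for m in retained]
        for a, b in itertools.combinations(kept, 2):
            if abs(ds.markers.genetic_pos[a] - ds.markers.genetic_pos[b]) <= 0.005:
                assert ld_r2(calls[:, a], calls[:, b]) <= thr

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(43)
        cols = []
        for _ in range(10):
            c = rng.integers(0, 3, 40).astype(np.int8)
            cols += [c, np.where(rng.random(40) < 0.2, rng.integers(0, 3, 40), c).astype(np.int8)]
        ds = dataset_from_calls(np.column_stack(cols), spacing=0.001)
        r_strict, _ = select_markers_ld(ds, 0.05, window_cm=0.5)
        r_loose, _ = select_markers_ld(ds, 0.1, window_cm=0.5)
        assert len(r_strict) <= len(r_loose)

    def test_linkage_equilibrium_keeps_most(self):
        # independent markers, many individuals: null sample r^2 ~ 1/n,
        # so threshold 0.05 should retain the large majority
        rng = np.random.default_rng(44)
        n_ind, n_mark = 400, 60
        p = rng.uniform(0.2, 0.8, n_mark)
        calls = (
            (rng.random((n_ind, n_mark)) < p).astype(int)
            + (rng.random((n_ind, n_mark)) < p).astype(int)
        )
        ds = dataset_from_calls((2 - calls).astype(np.int8), spacing=0.001)
        retained, _ = select_markers_ld(ds, 0.05, window_cm=0.5)
        assert len(retained) >= 0.85 * n_mark
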