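# hbdkit

Genome-wide **homozygosity-by-descent (HBD)** estimation from SNP
genotypes, and the machinery to compare HBD estimators against exact
simulated truth.

An individual's inbreeding coefficient *f* is the probability that a
random locus carries two alleles that are copies of one ancestral allele
(autozygosity).  Dense SNP data let us estimate *f* without genealogies —
but different estimators see very different things.  `hbdkit` implements
the five standard measures side by side:

| estimator   | type         | idea |
|-------------|--------------|------|
| `MLH`       | single-point | proportion of heterozygous loci (homozygosity-by-state only) |
| `F_PLINK`   | single-point | method of moments, (O − E)/(L − E) on observed vs expected homozygote counts (PLINK `--het`) |
| `F_ADC`     | single-point | inverse-variance-weighted mean of per-locus homozygosity deviations (o − e)/(1 − e) |
| `FEstimSPT` | single-point | ML of *f* under a per-marker mixture of HBD and Hardy-Weinberg emission models |
| `FEstim`    | multi-point  | joint ML of (*f*, *a*) under a two-state hidden Markov model along genetic distance |

The HMM is the scientific core.  With stationary distribution (*f*, 1 − *f*)
and exchange rate *a* per Morgan, the transition over distance *d* uses
*r* = e^(−*ad*): P(HBD→HBD) = *r* + *f*(1 − *r*), P(non→HBD) = *f*(1 − *r*).
Long runs of homozygosity therefore drive *f̂* upward while isolated
homozygous markers are discounted — the key to separating
homozygosity-by-descent from homozygosity-by-state.

The package also provides:

* a **gene-dropping simulator**: founder haplotypes labelled uniquely and
  dropped through first/second/third-cousin pedigrees with Haldane
  (Poisson) recombination, so true HBD is known exactly per marker;
* **marker QC** (call-rate, exact Hardy-Weinberg test, MAF) and greedy
  **LD pruning** to an r² threshold — multi-point HBD estimation assumes
  linkage equilibrium and inflates *f̂* when LD is left in;
* the **comparison pipeline**: per-degree means, empirical 95% ranges and
  Spearman correlation matrices against true HBD, plus Mann-Whitney
  group comparisons and Wilcoxon sibling-pair tests for cohort data.

## Worked example

Simulate 200 offspring of first cousins (expected *f* = 1/16) on the
default linkage-equilibrium map (4,849 SNPs, 22 chromosomes, 0.8 cM
spacing) and compare all five estimators with the truth:

```python
import hbdkit as hk
from hbdkit.compare import run_simulation_study

sim_map = hk.make_sim_map(seed=0)            # 4,849 SNPs, 22 chromosomes
study = run_simulation_study([1], 200, sim_map, seed=0)
block = study[1]
print(block.means.round(3).to_string())
print(block.correlations["true_hbd"].round(2).to_string())
```

```
true_hbd     0.062
MLH          0.342
F_PLINK      0.062
F_ADC        0.062
FEstimSPT    0.061
FEstim       0.062

true_hbd     1.00
MLH         -0.73
F_PLINK      0.73
F_ADC        0.73
FEstimSPT    0.80
FEstim       0.93
```

Every estimator is essentially unbiased for first-cousin offspring
(means ≈ 0.062 = 1/16), but only the multi-point HMM tracks the
*individual* replicate's realized autozygosity closely (ρ = 0.93 vs
≈ 0.73–0.80 for the single-point measures).  The gap widens sharply for
second- and third-cousin offspring, where single-point estimates are both
noisier and inflated.

The same estimators run from the shell on PLINK text data:

```sh
hbdkit qc       --ped data.ped --map data.map --out-prefix clean
hbdkit prune    --ped clean.ped --map clean.map --r2 0.05 --out-prefix pruned
hbdkit estimate --method festim --ped pruned.ped --map pruned.map -o f.tsv
hbdkit simstudy --degrees 1,2,3 --replicates 1000 --out-dir study/
```

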