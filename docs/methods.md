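# Methods

## The estimation problem

A locus is homozygous-by-descent (HBD, autozygous) when both alleles
descend from a single ancestral copy through a consanguineous loop; the
genome-wide proportion of HBD loci is the individual's realized
inbreeding coefficient *f*.  SNP panels observe only homozygosity by
*state*, so an estimator must separate chance homozygosity (frequent for
common alleles) from descent.  `hbdkit` implements one multi-point and
four single-point estimators over a shared genotype model: biallelic
autosomal markers coded hom₁/het/hom₂/missing, allele-1 frequencies
*p_l* either estimated from the sample or supplied externally, genetic
positions in Morgans.

## Single-point estimators

Let *e_l* = 1 − 2*p_l*(1 − *p_l*) be the expected homozygosity of marker
*l* under Hardy-Weinberg equilibrium, *o_l* ∈ {0, 1} its observed
homozygosity, *O* = Σ *o_l*, and *L* the number of usable markers
(non-missing call, 0 < *p_l* < 1; the same set for every estimator so
marker counts are comparable).

* **MLH** = (number heterozygous)/*L* — pure homozygosity-by-state.
* **F_PLINK** = (*O* − *E*)/(*L* − *E*) with *E* = Σ [1 − 2*p_l*(1 −
  *p_l*)·*c_l*].  The small-sample factor *c_l* = 2*N_l*/(2*N_l* − 1)
  (with *N_l* the individuals called at *l*) is applied only when
  frequencies come from the sample itself; provided frequencies use
  *c_l* = 1.  Can go negative; negative values are kept in per-cohort
  output and clipped to zero only inside the simulation comparison,
  where they would otherwise be compared against a truth that cannot be
  negative.
* **F_ADC**: per-locus estimate *f_l* = (*o_l* − *e_l*)/(1 − *e_l*),
  combined with inverse-variance weights *w_l* = (1 − *e_l*)/*e_l*
  (the reciprocal of Var(*f_l*) at *f* = 0).  The source description of
  this estimator is for multi-allelic markers; the biallelic
  specialization above is the implemented contract.  With a single
  shared frequency the weights cancel and F_ADC ≡ F_PLINK (asserted in
  tests).
* **FEstimSPT**: maximum likelihood of *f* ∈ [0, 1] for the per-marker
  mixture P(*g_l*) = *f*·P(*g_l*|HBD) + (1 − *f*)·P(*g_l*|non-HBD).
  Emissions under HBD with genotyping-error rate ε: P(hom₁|HBD) =
  (1 − ε)*p* + ε*p*², P(het|HBD) = ε·2*pq*, P(hom₂|HBD) = (1 − ε)*q* +
  ε*q*²; non-HBD uses the HWE probabilities.  Each log-likelihood term
  is the log of a linear function of *f*, so the sum is concave: a
  single bounded Brent search (xatol 10⁻⁶) plus explicit endpoint
  evaluations at *f* ∈ {0, 1} finds the global maximum — no multistart
  is needed.  A grid-search oracle at 10⁻⁴ resolution confirms this in
  the test suite.

## The hidden Markov model (FEstim)

Hidden state HBD/non-HBD per marker; stationary distribution (*f*,
1 − *f*); transition over genetic distance *d* with *r* = e^(−*a d*):

    P(HBD→HBD) = r + f(1 − r)        P(HBD→non) = (1 − f)(1 − r)
    P(non→HBD) = f(1 − r)            P(non→non) = r + (1 − f)(1 − r)

*a* (per Morgan) is the rate of exchange between states; 1/(*a*(1 − *f*))
is the mean HBD segment length.  Emissions are shared with FEstimSPT,
which is exactly the *a* → ∞ degenerate case (asserted to 10⁻⁶ at
*a* = 10⁶).  Chromosomes are independent, each chain started at the
stationary distribution; missing or uninformative markers emit
probability 1 in both states, which is equivalent to summing distances
across them.  The chain is reversible from stationarity, so the
likelihood is invariant to marker-order reversal (tested).

Numerics: the forward pass is scaled per marker (log-space accumulation
of normalizers) and numba-compiled — one evaluation walks all markers
and an MLE needs hundreds.  Correctness is pinned to an exhaustive
2^L path-sum oracle at L ≤ 12 markers, and the posterior
(forward-backward, same scaling) to the corresponding exhaustive
posterior.

The MLE maximizes over (*f*, *a*) jointly by Nelder-Mead on transformed
coordinates (logit *f*; *a* logit-scaled inside [*a*_min, *a*_max] =
[0.01, 100] per Morgan), multistart from *f*₀ ∈ {0.001, 0.0625, 0.25} ×
*a*₀ ∈ {0.1, 1, 10}, convergence tolerance 10⁻⁶ on the log-likelihood.
The lower bound *a*_min = 0.01 prevents degenerate whole-genome-segment
solutions on short maps.  Because the transform cannot reach *f* = 0
exactly, the boundary is checked explicitly afterwards (there the
likelihood does not depend on *a*) and *f̂* = 0 is reported when it wins.
Replicate sweeps in the comparison pipeline use a reduced three-start
set ((0.01, 1), (0.0625, 6), (0.25, 20)) — the full grid and the reduced
set agree on simulated data, and the reduction keeps thousand-replicate
studies at minutes of CPU.

ε defaults to 0, matching the error-free generative model used in
simulation; for real data ε ≈ 0.001 is recommended, since a single
mistyped heterozygote inside a long HBD tract otherwise zeroes the
likelihood of the HBD path.  The choice is recorded in output metadata.

## Gene-dropping simulator

The synthetic-data engine emulates a pruned 10K genotyping array over
offspring of consanguineous matings:

* **Pedigrees**: canonical first/second/third-cousin structures whose
  path-counting F is 1/16, 1/64, 1/256 (verified against a recursive
  kinship computation).  An option adds extra children to the cousin
  couple for sibling analyses.
* **Map**: 4,849 markers at 0.008 M spacing over 22 equal-length
  chromosomes (total 38.8 M), allele-1 frequencies i.i.d.
  Uniform(0.05, 0.95) — i.e. MAF ~ U(0.05, 0.5).  The real chip's exact
  map and frequency spectrum are not public, so an idealized even map is
  used; all map parameters are recorded in output provenance.
* **Meiosis**: Haldane model — crossover counts Poisson in chromosome
  genetic length, positions uniform, random start strand, no
  interference — matching the exponential-distance HMM downstream.  The
  per-interval strand-switch probability (1 − e^(−2d))/2 is verified by
  tally.
* **Truth**: founder haplotypes carry unique labels (one pair per
  founder, shared across chromosomes — equality comparisons only ever
  happen within a marker, so this is equivalent to per-chromosome
  labels); a marker is HBD iff the proband's two labels coincide, and
  *f*_true is the HBD fraction.
* **Genotypes**: each (founder label, marker) cell receives allele 1
  with probability *p_l*, independently across markers and labels
  (linkage equilibrium).  HBD markers are therefore homozygous by
  construction — there is no mutation or genotyping error in the
  generative model.  Draws are shared across probands of one replicate,
  so sib genotypes are mutually consistent.

Replicates are independent via spawned RNG substreams, bit-reproducible
from the seed, and prefix-stable (the first k replicates do not depend
on the total requested).

What the generator does *not* emulate: linkage disequilibrium, realistic
chromosome-length variation, frequency ascertainment of commercial
arrays, genotyping error, mutation.  Passing tests therefore show
estimator behaviour under the assumed model (LE, error-free calls), not
robustness to LD — which is precisely why the package ships an LD
pruner for real data.

## QC and LD selection

QC order: individuals with > 5% missing calls out first, then markers by
exact Hardy-Weinberg test (p ≤ 10⁻⁷), call rate < 95%, MAF < 0.05 —
each stage filtering the survivors of the previous; per-stage counts are
reported and the procedure is idempotent.  The HWE test is the exact
conditional test on heterozygote count given allele counts (stable ratio
recurrence; no mid-p), checked against a log-factorial enumeration
oracle and empirically conservative under the null.

LD pruning is a greedy per-chromosome scan: within a genetic window
(default 0.5 cM) any pair with composite genotypic r² above the
threshold loses its lower-MAF member (ties drop the later marker).  The
scan guarantees no retained pair within the window exceeds the
threshold (verified exhaustively on fixtures).  Preferring high-MAF
markers is a deliberate proxy for information-content-maximizing
selection tools; exact equivalence with any such tool is not claimed.
r² can be computed on an external reference panel instead of the input
sample.

## Comparison pipeline

For each cousin degree: per-estimator mean, empirical central 95% range
(2.5–97.5% quantiles of the replicate distribution — the bracketed
interval in output tables is explicitly empirical, not parametric), and
the pairwise Spearman correlation matrix including true HBD (Pearson
available as a sensitivity switch).  Replicates with any failed
estimator are dropped listwise and counted.  Group comparisons use
Mann-Whitney (exact null when the smaller group has ≤ 8 members,
tie-corrected normal approximation otherwise) between neighbouring
ordered groups; sibling pairs use the Wilcoxon signed-rank on within-pair
differences (zero differences dropped); a conditional-correlation helper
re-correlates estimators on the subset of detectably inbred individuals.

## Problem sizes and reproducibility

The shipped study sizes are 10,000 label-only gene-drop replicates per
degree for true-HBD means and 1,000 fully genotyped replicates per
degree for estimator comparisons — at those sizes the Monte-Carlo
standard error of a correlation is ≈ 0.01–0.03, comfortably inside the
differences being measured, and the whole study runs in minutes on one
CPU.  The HMM parameter-recovery check uses 200 replicates of
model-generated data at *f* = 0.0625 with mean segment length ≈ 0.16 M
(the first-cousin expectation, a ≈ 6.4/M) on a 5,000-marker map; the
median *f̂* recovers truth within 0.01.

## Known limitations

* The multi-allelic generalization of F_ADC (*e_l* = Σ *p_a*²) is
  implemented in spirit but only the biallelic case is exercised.
* The HMM models no LD; on unpruned dense panels *f̂* is inflated by
  construction.  Prune first.
* Numerical equivalence with the original FEstim program is not
  claimable (its optimizer and bounds are unpublished); equivalence is
  at the model level, anchored by the exhaustive-path oracle.
* Binary PLINK (BED) input is not implemented; the text PED/MAP dialect
  is the tested contract.
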