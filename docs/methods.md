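# Methods

This note documents the statistical models the package implements, the
numerical choices behind them, what the synthetic-data generators emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## EHH, iHH and uiHS

For a core SNP allele *i* with c_i carrier haplotypes, the extended
haplotype homozygosity over the interval from the core out to a flanking
SNP is the plug-in homozygosity of the carriers' substrings,

    EHH_i = sum_j e_ij^2 / c_i^2,

where e_ij counts the j-th distinct extended haplotype. The unbiased
variant sum_j C(e_ij,2)/C(c_i,2) is available via `estimator="unbiased"`,
but the plug-in form is the default. Note the plug-in form has a hard
floor of 1/c_i, with consequences discussed under *Truncation* below.

The integrated EHH (iHH) is the trapezoid area under EHH versus physical
distance (bp), walked SNP by SNP in both directions from the core until
EHH first drops below a cutoff (default 0.05). The final segment is
integrated only up to the linearly interpolated point where EHH equals
the cutoff; the observed sub-cutoff value is retained on the curve object
for exactly that interpolation. No genetic map is used: all distances are
physical, and no gap penalty is applied between distant SNPs.

uiHS = ln(iHH_A/iHH_B), with (A,B) either (ancestral, derived) — used by
the bin-standardized score — or (minor, major) — used by the permutation
score, so that positive values mean the minor allele rides the longer
haplotypes. Polarizing by the ancestral allele flips the sign but never
the magnitude.

### Truncation

A direction that reaches the chromosome end with EHH still at or above
the cutoff is flagged truncated; truncated cores are reported but
excluded from standardization and P-values, because their iHH is biased
downward by the missing tail. Because plug-in EHH can never fall below
1/c_i, a core whose minor-allele count is at most 1/cutoff (20 carriers at
cutoff 0.05) can never cross the cutoff and is always flagged. Panel sizes
should therefore keep the MAF floor above 20 carriers; the bundled neutral
generator defaults to 600 haplotypes so that MAF 0.05 means 30 carriers.

## The locus-specific permutation iHS

Core-SNP alleles are reassigned uniformly at random to haplotype rows,
preserving the allele counts and leaving all flanking columns untouched;
uiHS (minor/major) is recomputed for each of n_perm = 1000 draws. This
holds the local LD structure and the allele frequency fixed while
randomizing which haplotypes form the two groups — the null hypothesis of
neutrality at the core. The locus-specific sample SD of the permuted
values scales the observed score:

    siHS_P = (uiHS - 0) / SD(iHS_P).

The permutation distribution is symmetric at MAF 1/2 but acquires a
positive offset at low MAF (fewer carriers concentrate on fewer ancestral
backgrounds and so share longer haplotypes), and its SD grows steeply as
MAF falls. Both effects are frequency-driven, so siHS_P is regressed on
MAF genome-wide — ordinary least squares with an intercept, on the
continuous MAF scale rather than in bins — and the residuals are divided
by their global sample SD:

    iHS = e_i / SD(e),   P = 2 (1 - Phi(|iHS|)).

The intercept is required: without it the residuals would not be centered
and the statistic could not be referred to N(0,1). Sample (n-1) SDs are
used wherever an SD is taken. The raw empirical permutation tail
probability (r+1)/(n_perm+1) is reported alongside for diagnostics.

Degenerate permutation draws (a group with a non-positive integral) are
redrawn with a cap of 10 x n_perm attempts, then flagged; they
essentially never occur away from chromosome termini.

Per-locus permutation seeds are SHA-256 hashes of (master seed, variant
id), so removing SNPs from a panel never changes another SNP's result.

### Implementation

Permuting the core column leaves the flanking identity classes fixed, so
the scan precomputes, per extension step, the partition of haplotypes
into exact-substring classes (iterative refinement with `np.unique`) and
evaluates all permutations against it. For a carrier set S of size c with
class sizes m_j and hit counts x_j,

    EHH_minor = sum x_j^2 / c^2
    EHH_major = (sum m_j^2 - 2 sum m_j x_j + sum x_j^2) / (n-c)^2,

so each permutation costs O(c) per step; the inner loop is JIT-compiled
with numba (a vectorized numpy fallback exists). The observed assignment
is simply row 0 of the same computation. A 5,000-SNP panel of 600
haplotypes at 1,000 permutations scans in about two minutes on one core.

## Bin-standardized iHS (ancestral/derived)

Where ancestral states are annotated, uiHS is polarized to
ln(iHH_anc/iHH_der) and standardized against the empirical mean and SD of
uiHS in bins of derived-allele frequency — deciles by default,
right-closed, fitted from the supplied genome-wide set or taken from a
user-provided table. SNPs without (or with contradictory) annotation are
excluded from this statistic only; the permutation iHS needs no polarity.

## Mixed-model association

The single-SNP model is y = 1*mu + x*beta + a + e with a ~ N(0, G sa^2)
and e ~ N(0, I se^2).

* **Kinship.** G's off-diagonals are method-of-moments IBD estimates:
  per pair, the observed IBS0/IBS1/IBS2 counts are equated to their
  expectations given IBD state (computed from plug-in sample allele
  frequencies) and solved sequentially for P(IBD=0/1/2);
  pi_hat = P(IBD=1)/2 + P(IBD=2), truncated to [0,1] only at the end
  (clipping the intermediate probabilities would bias unrelated pairs
  upward). Diagonals are 1+F with F = (O_hom - E_hom)/(L - E_hom). No
  hidden-Markov smoothing or small-sample bias corrections are applied;
  an externally computed GRM can be injected from a whitespace-delimited
  square file. Before model fitting the matrix is repaired to positive
  definite by the minimal ridge delta*I bringing the smallest eigenvalue
  to 1e-6 (logged).
* **Variance components** are estimated once by REML under the
  intercept-only null model — profile likelihood in the ratio
  gamma = sa^2/se^2 on the spectral decomposition of G, grid search on
  log gamma in [-11.5, 11.5] refined by bounded scalar minimization —
  and plugged into every per-SNP generalized-least-squares fit. A flat
  profile (e.g. G = I, where the two components are not identifiable) is
  flagged and reported as ratio 0.
* **Per-SNP GLS.** With V = sa^2 G + se^2 I fixed, beta and its variance
  come from direct inversion: beta = (X'V^-1X)^-1 X'V^-1 y with
  X = [1, x]. Var(beta) carries a per-SNP dispersion factor
  r_hat = RSS_V/(n-2), the V-weighted residual mean square — E[r_hat]=1
  under a correct model, the sa^2 = 0 limit then reproduces textbook OLS
  exactly, and a perfectly fitting SNP gets Var(beta) = 0. The Wald
  statistic T^2 = beta^2/Var(beta) is referred to chi-square with 1 df.
* **MIXStrat** regresses the 0/1/2 genotype codes on sire + maternal-
  grandsire factors (two-factor additive least squares via an orthonormal
  SVD basis, which also absorbs aliased levels; families smaller than
  min_family = 5 are pooled into one level per factor) and uses the
  residuals as the tested covariate. A SNP whose codes are constant
  within every family residualizes to ~0 and is flagged monomorphic.
* **Adaptive permutation P.** The genotype vector is shuffled among
  individuals (phenotypes and G fixed), T^2 recomputed, and the schedule
  1e3 -> 1e4 -> 1e5 -> 1e6 escalates while fewer than 10 permuted
  statistics reach the observed one; P = (r+1)/(n+1), which cannot be
  zero and so remains usable downstream.
* **Genomic control.** lambda = median(T^2)/0.456, with 0.456 the median
  of the chi-square 1-df distribution at the conventional two-figure
  precision.

## Monte Carlo evaluation

`mc.run_evaluation` measures type-I error and power of MIX vs MIXStrat on
a synthetic version of a progeny-testing design:

* **Family structure.** 973 candidate bulls assigned to 90 sires and 121
  maternal grandsires with Dirichlet-multinomial family sizes.
* **Null genotypes.** Per SNP, allele frequency p ~ U(0,1); every founder
  carries two Bernoulli(p) alleles; the paternal allele is a Mendelian
  draw from the sire; the maternal allele comes from the MGS with
  probability 1/2, otherwise from the population frequency (the dam's own
  maternal contribution). The strictly literal population-only maternal
  rule is available as `dam_mode="population_only"`. No LD between SNPs.
  This transmission gives expected relatedness pi = 1/4 within sire
  families and 1/16 within MGS families.
* **Phenotypes.** Candidate value = sire effect + MGS effect + individual
  term, emulating high-reliability EBVs: with trait heritability
  h2_family (default 0.5), the family effects carry the transmission
  shares h2/4 (sire) and h2/16 (MGS) and the individual term the
  remainder. These shares deliberately match the genotypic relatedness of
  the transmission model: a phenotype whose family covariance exceeds
  what relatedness can represent is inconsistent with *any* additive
  kinship model, and (because the sire/MGS-mean space spans ~210 of the
  287 dimensions) such inconsistency contaminates the fitted V and
  deflates the family-orthogonal MIXStrat statistic. Stratification in
  the analyzed sample instead arises from **selective genotyping**: only
  the 140 highest and 148 lowest candidates are retained (one individual
  is then dropped, mirroring a call-rate exclusion, leaving 287), which
  concentrates extreme family effects and inflates between-family
  variance in the selected subsample.
* **Rates.** Structure, phenotypes and genotypes are regenerated every
  replicate; both models are fitted to identical data with variance
  components re-estimated per replicate on the base phenotype. The
  false-positive rate is the fraction of all (replicate, SNP) asymptotic
  P-values below 0.05 (untestable SNPs count in the denominator, never as
  positives); lambda pools all T^2. For power, every SNP in turn acts as
  the causal locus of its own phenotype y_i = y + x_i * alpha_QTL with
  alpha_QTL = sqrt(sigma2_EBV * QTL_SIZE / (2p(1-p))), all cross-products
  reducing to cached terms, and power is the fraction of causal tests
  below the Bonferroni threshold alpha_Bonf = 2.5e-5 by default
  (configurable; note 0.05/10,000 would be 5e-6). Default scale is m = 10
  replicates of 10,000 SNPs — about 15 seconds — with asymptotic P-values
  inside the loops; adaptive permutation at that scale is impractical and
  available only for targeted SNPs.

## Combined test

Each of the two P-values is transformed to an upper-tail normal quantile
z(P) = Phi^-1(1-P) (two-sided P-values go in unsigned; direction is
reported separately as the sign concordance of iHS and beta), and
Z = sum z(P_i)/sqrt(k) with k = 2, P_COMB = 1 - Phi(Z). The sqrt(k)
denominator is what makes Z standard normal under independent null
inputs. Boundary P-values are clamped into the open interval and logged.
The association P entering the combination is the empirical permutation P
when available, else the asymptotic P, recorded per SNP.

q-values use a tail-area FDR: eta0_hat = min(1, frac(P > 0.5)/0.5),
Fdr(p_(i)) = eta0_hat * N * p_(i)/i with step-up monotonicity
enforcement; with fewer than 20 P-values the eta0 estimate is meaningless
and the method falls back to Benjamini-Hochberg (eta0 = 1) with a
warning. Significance is declared at q < 0.10. Under the global null the
probability that a step-up rule at q < 0.10 makes at least one call is
itself close to 0.10 (Simes' identity), so occasional null calls are
expected behaviour, not a defect. Independence of the two P sources is
assumed; the join summary reports their correlation (overall and in the
top 1% / 0.1% of |iHS|) so users can check the assumption.

## Synthetic generators

* `neutral_panel`: founder haplotypes (24 by default) with U(0.05, 0.5)
  allele frequencies; sample haplotypes are founder mosaics with
  exponential segment lengths (mean 50 kb), giving monotone LD decay and
  no EHH asymmetry between alleles beyond the frequency effect. Columns
  whose sampled MAF falls below 0.05 are redrawn. What it does *not*
  emulate: coalescent genealogy (classes of carriers are mosaic-, not
  tree-structured), mutation, demography. Passing calibration here shows
  the statistic is calibrated against its own permutation null and
  MAF regression — not that real cattle data are neutral.
* `sweep_panel`: forward Wright-Fisher simulation (N = 200 diploids,
  fitness 1 / 1+s / 1+2s, Poisson recombination at 1e-6 per bp per
  generation — rescaled, as usual for desk-scale N, so that background LD
  still decays inside the 1 Mb region) on a neutral base population. The
  beneficial allele is introduced at start_freq (default 0.10) as
  identical-by-descent copies of one founder haplotype — a hard sweep; a
  soft sweep from standing variation spread over many backgrounds leaves
  little iHS signal, which is a property of the statistic, not a bug.
  Evolution stops when the allele frequency reaches a target drawn
  uniformly from the sampling band (default [0.5, 0.8]), so sampled
  sweeps span the incomplete-sweep regime; loss or overshoot restarts the
  simulation (capped at 100). 240 haplotypes are sampled and columns
  below 5% MAF dropped.
* `pedigree_fixture`: bundles the Monte Carlo generators into a ready
  (family structure, genotypes, phenotypes, pedigree) dataset, preset to
  the 973/90/121/140+148-1 design.

All generators are pure functions of (configuration, seed).

## Numerical choices and degenerate inputs

* Minor/major ties at MAF exactly 0.5 break to the lexicographically
  smaller allele string; coordinates are 1-based bp throughout.
* QC order: individual call rate, autosome/position, SNP missingness,
  MAF — per-SNP statistics recomputed after the individual filter.
  Missing genotype calls surviving QC are mean-imputed in association
  designs (missingness is below 10% there by construction).
* The monomorphic-design guard in GLS is det <= 1e-12 * a11 * a22.
* P-value clamps: [1e-300, 1 - 1e-16] before normal quantiles.
* Problem sizes used by the shipped checks: 10 replicates x 10,000 SNPs
  for the association rates; 5,000 SNPs x 1,000 permutations for iHS
  calibration; 20 sweep replicates at 500 permutations for recovery —
  sizes chosen to keep each experiment in the minutes range on one core
  while leaving Monte Carlo error well inside the asserted bands.

## Known limitations

* The Monte Carlo genotypes carry no LD, so the association rates say
  nothing about locally correlated tests; the evaluation targets
  stratification behaviour, as conservative Bonferroni thresholds are
  used.
* The moment-based IBD estimator is noisier than a hidden-Markov
  genome-partition estimator and can underestimate relatedness in
  admixed or inbred samples; inject an external GRM where that matters.
* MIX's anticonservatism under stratification depends strongly on how far
  the phenotype's family covariance departs from additive-kinship
  consistency; with the bundled (consistent-by-design) phenotype
  generator the inflation is mild, whereas real selectively genotyped
  EBV data can inflate it far more.
* The permutation iHS inherits the plug-in EHH floor: loci with fewer
  than 1/cutoff minor-allele carriers are never scored.
* Bifurcation trees and EHH curves are exact but O(steps^2) in the
  public one-core API; the scan path is the optimized one.
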