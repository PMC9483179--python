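# Methods

## The model

`lactgwas` analyses first-lactation dairy test-day records with a single-trait
random-regression model (RRM).  A record of cow *l* at days in milk (DIM) *t*
is modelled as

    y = HTD_i + AGE_j + SEASON_k + phi(t)' a_l + phi(t)' p_l + e

where `phi(t)` holds normalized Legendre polynomials of standardized DIM
(`w = 2(t-5)/(305-5) - 1`, `phi_m = sqrt((2m+1)/2) P_m(w)`), `a_l` is the
cow's additive-genetic regression coefficient vector, `p_l` her permanent-
environment (PE) coefficient vector, and the fixed effects are herd-test-date,
calving month x age class and calving year x season class.  The covariance
structure is

    Var[a; p; e] = [ A (x) G      0          0
                     0            I (x) P    0
                     0            0          I sigma_e2 ]

with `A` the pedigree numerator relationship matrix and `G`, `P` the
coefficient-scale covariance matrices.  Residuals are homogeneous across DIM.
All DIM-specific quantities follow from the fitted components: additive
variance `phi'G phi`, PE variance `phi'P phi`, heritability
`h2(t) = phi'G phi / (phi'G phi + phi'P phi + sigma_e2)`, genetic correlation
`r(t1,t2) = phi1'G phi2 / sqrt(phi1'G phi1 * phi2'G phi2)`, and the
DIM-specific EBV `phi(t)' a_hat`.

The basis order is configurable and defaults to 5 (basis dimension 6), the
standard choice for lactation curves; the bundled simulation experiments use
order 2 so that desk-scale runs finish in minutes — the algebra is
order-generic.

## REML estimation

Variance components are estimated by restricted maximum likelihood on
Henderson's mixed-model equations (MME).  Numerically important choices:

* **PE absorption.**  The PE block of the MME is block-diagonal (one k x k
  block per cow) and is eliminated exactly through its Schur complement,
  leaving a dense symmetric system in the fixed-effect and additive equations
  only.  All REML traces are recovered through the same complement, so the
  absorbed iteration is algebraically identical to the full one at roughly an
  eighth of the cost.
* **Pedigree pruning.**  Animals with neither records nor recorded
  descendants are removed before assembly; their BLUPs are reconstructed
  afterwards as parent averages, which is exact for such animals.
* **EM with AI acceleration and SQUAREM.**  Each round first attempts an
  average-information (quasi-Newton) step taken in the Cholesky
  parametrization `G = L L'` — every proposal is then positive semi-definite
  by construction, which matters because REML optima for coefficient
  covariances frequently sit on the PSD boundary.  The AI system is solved by
  truncated eigendecomposition (directions with no curvature information are
  frozen), and a step is accepted only if it increases the restricted
  likelihood.  When the AI step fails, the round falls back to an EM cycle
  with SQUAREM extrapolation in Cholesky-log coordinates, which repairs EM's
  notoriously slow progress along the additive-vs-PE exchange manifold while
  remaining monotone (the extrapolated point is only taken when it beats the
  second EM step).
* **Starting values.**  A method-of-moments initializer regresses each cow's
  fixed-effect-adjusted trajectory on the basis; cross-products of the
  coefficient estimates over related pairs identify `G`
  (`Cov(b_A, b_B) = a_AB G`), and the within-cow moment then gives `P` and
  `sigma_e2`.  Starting close to the right mode is important: the REML
  surface is multimodal in (G, P) and generic starts can converge to an
  inferior mode.
* **Convergence.**  Relative parameter change below `tol` (default 1e-6)
  after an undamped step, or a stalled likelihood (spread < 1e-6 relative
  over twelve rounds, which occurs when a component is pinned at the PSD
  boundary).  Non-convergence sets `converged=False` on the result rather
  than raising.  The reported log-likelihood omits the constant
  `-N/2 log(2pi)`.
* The restricted log-likelihood, its analytic gradient and the absorbed
  system were each verified against dense-matrix oracles (direct `V`-matrix
  REML evaluation, finite differences, and an unabsorbed MME build).

Fixed-effect levels that are aliased after reference-level coding are
detected by pivoted QR; `build_mme` reports them as an error, while the
fitting front ends drop them with a warning, as animal-model software
customarily does.

## Synthetic data generator

The generator emulates the structure of a large DHI (Dairy Herd Improvement)
first-lactation data set:

* **Pedigree** — founders followed by discrete generations; each dam is mated
  to one randomly drawn sire (optionally capped via `max_sires`, emulating
  heavy AI-stud use), with `offspring_per_dam` offspring of alternating sex.
* **Genotypes** — biallelic SNPs gene-dropped through the pedigree; founder
  allele frequencies uniform in `maf_range`, loci unlinked, positions evenly
  spaced on `n_chromosomes` chromosomes.
* **Coefficients** — additive vectors sampled with covariance `A (x) G` via
  Cholesky factors of `A` and `G`; PE vectors i.i.d. with covariance `P`.
  Optionally a fraction (`qtl_var_fraction`, default 0.3) of the additive
  intercept variance is planted on `n_qtl` markers (constant effect across
  lactation by default), the polygenic remainder being sampled with the
  correspondingly reduced `G`, so association scans have known truth.
* **Records** — roughly monthly tests: each cow's nominal schedule (default
  ten tests, DIM 20-285) is snapped to shared mid-month herd visit dates, so
  herd-test-date cells contain many cows, as in real data.  Fixed effects are
  i.i.d. normal per level with configurable SDs (defaults 2.0 / 1.0 / 1.0 kg
  for HTD / age / season).  Milk yield is the primary simulated trait
  (mean 28 kg/d, additive scale `G` with intercept variance 6, PE 12,
  residual 8 — kg^2, giving mid-lactation h2 about 0.17); fat percentage,
  protein percentage and SCS are independent scaled draws with the same
  covariance shape; fat and protein yields are derived as FP*MY/100 and
  PP*MY/100 plus 0.01 kg measurement noise, so the derivation step downstream
  is exercised nontrivially.  SCC is emitted as the inverse of the SCS
  transform.

The generator reproduces the covariance structure the model assumes; it does
not attempt typical lactation-curve shapes beyond the Legendre mechanism,
heat-stress processes, linkage disequilibrium, genotyping error, or
selection.  Passing tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to real-data
violations of them.

## Recovery experiment design

The parameter-recovery experiment fits an order-2 model to populations of
810 phenotyped cows with ten tests each and known components.  The pedigree
uses two overlapping phenotyped generations (135 founder dams, up to 30
sires, four offspring per dam), so the information for separating additive
from PE variance comes jointly from paternal half-sib groups, full-sib pairs
and phenotyped dam-daughter pairs.  A single replicate of this size estimates
DIM-specific h2 with a standard error of roughly 0.03 at mid-lactation and
0.045 at the lactation ends (measured across seeds); the experiment therefore
averages five independent replicates, giving the mean curve a standard error
near 0.02 — small enough to resolve a bias of 0.05, which is the acceptance
tolerance.  A 1,800-cow check run recovered the truth curve within 0.02 at
every evaluation DIM, supporting consistency of the estimator.

## Genome scans

The response for association analysis is the DIM-specific EBV `phi(t)' a_hat`
at the stage DIM grid {7, 35, 50, 140, 280}.

* **QC** — samples with call rate < 0.95 are removed first, then SNPs with
  call rate < 0.90, Hardy-Weinberg exact p < 1e-6 (conditional exact test,
  computed by the standard recurrence on heterozygote counts), or MAF < 0.05.
* **GRM / PCA** — VanRaden method-1 (`ZZ'/(2 sum p(1-p))`, frequency-centred,
  per-SNP mean imputation of missing dosages); principal components are
  eigenvectors of the GRM, and the top three enter every scan as covariates.
* **MLM** — single-marker mixed model `y = Wb + m h + u + e`,
  `u ~ N(0, G sigma_a2)`.  Variance components are estimated once under the
  no-marker null (P3D) by REML on the spectral decomposition of the GRM;
  each marker is then tested by GLS in the rotated coordinates with a
  t-statistic on `N - p - 1` degrees of freedom.  With the identity kinship
  this reduces exactly to OLS, which the tests exploit as an oracle.
* **FarmCPU-style multi-locus scan** — alternates (i) a fixed-effect scan of
  every marker with the current pseudo-QTNs as covariates, markers inside a
  pseudo-QTN's genomic bin being tested with that bin's QTN left out, and
  (ii) pseudo-QTN reselection: p-ranked markers are deduplicated per bin for
  bin sizes {0.5, 5, 50} Mb and candidate set sizes {2,4,8,16,32} (capped at
  n/10), and the combination maximizing the restricted likelihood of the
  random model `y = u + e`, `u ~ N(0, 2K sigma_u2)` with `K` built from the
  candidate QTNs, is kept.  Iteration stops when the QTN set repeats or after
  10 rounds; a 0.01 screening threshold guards entry, and when nothing passes
  in round one the covariate-only scan is returned with a warning.
* **Significance** — fixed thresholds: genome-wide 5e-8, suggestive 5e-6; no
  FDR procedure.  Inflation is reported as the median-based genomic lambda.

The null-calibration experiment uses 1,000 unrelated samples by 2,000 markers
with a fully polygenic response; FarmCPU power uses 20 replicates of 500
samples by 1,000 markers with one planted QTL explaining 10% of the response
variance (at this size the expected non-centrality makes detection essentially
certain, so the replicate count tests procedure stability rather than
marginal power).

## Annotation

Significant SNPs are extended +-150 kb (clipped at position 1), and windows
are intersected with gene and QTL interval tables on 1-based inclusive
coordinates (BED input is shifted on read).  QTLs spanning 1 Mb or more are
excluded before counting.  A SNP whose window overlaps at least one QTL of a
class counts once for that class in its trait-DIM cell; one SNP may count in
several classes.  Empty windows report the nearest gene and its distance.

## Edits (phenotype QC)

Record-level: age at first calving 19-37 months (whole calendar months),
DIM 5-305, milk 1.0-65 kg, fat 0.5-8.5%, protein 0.5-7.5%, all bounds
inclusive; SCC strictly below 2,000 (1,000 cells/mL).  SCC units follow the
DHI convention of 1,000 cells/mL, making the somatic cell score
`SCS = log2(SCC/100) + 3`.  Cow-level: at least three surviving records, one
of them before DIM 45, and calving before 2019-12-01 (configurable).
Records with missing required fields are rejected under a dedicated rule
rather than raising.  Seasons default to calendar quarters and age classes to
6-month bins; both are configurable because class definitions vary between
recording systems.

## Known limitations

* Single-trait fits only; no heterogeneous residual classes, persistency
  indices, genomic BLUP or multi-trait RRM.
* The dense absorbed MME targets populations up to a few thousand animals —
  adequate for the bundled experiments, not for national evaluations.
* DIM-specific h2 at the lactation extremes is intrinsically noisy at desk
  scale; order-2 tails carry per-replicate standard errors near 0.045 even
  with a strong design, which is why the recovery experiment averages
  replicates.
* FarmCPU bin/QTN defaults follow the published method; no LD-aware binning.
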