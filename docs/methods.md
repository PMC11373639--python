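# Methods

## Model

A trait observed at T ordered postharvest time points (1D, 1W, 3W, 7W) on a
population of autotetraploid genotypes is modelled jointly across time
points as

    y = X1 β + X2 t + X3 g1 + Z g2 + e,
    g2 ~ MVN(0, Σt ⊗ G),      e ~ MVN(0, Σe ⊗ I),

with the following structure:

* **Per-time means.** The population mean at each time point and the fixed
  storage-time effect are not separately identifiable, so the design uses
  one intercept per time point; the Wald test of the time effect is a test
  of equality of these intercepts.
* **Year effects.** Entries are phenotyped unreplicated in a single year;
  a panel of check genotypes repeated in every year connects years
  (augmented design).  Year enters as a fixed additive effect common to
  all time points.
* **Checks vs entries.** Check genotypes are fixed effects (one per
  check); regular genotypes carry the random genotype-by-time effects g2.
  A genotype is a check iff flagged in the phenotype table.
* **Covariance structures.** Σt and Σe are T×T matrices across time
  points.  Genetic structure: `unstructured` (T(T+1)/2 parameters),
  `common` (one parameter: equal variance, correlation 1 — the
  no-interaction reduction), or `independent` (diagonal).  Residual
  structure: `unstructured` or `independent`.  Residuals are correlated
  across time points within a harvest unit (genotype × year) and
  independent between units.  Traits observed at a single time point fit
  as the T = 1 special case.
* **G matrix.** VanRaden relationship matrix generalized to ploidy m:
  dosages are centred by m·p_j and the cross-product is scaled by
  Σ m p_j (1−p_j), the dosage variance under polysomic Hardy–Weinberg
  equilibrium.  Monomorphic (zero-variance) markers are excluded; missing
  dosages are mean-imputed per marker after frequency estimation (an
  imputed cell centres to exactly zero); a ridge (default 1e-6) keeps G
  invertible.  `min_maf` defaults to 0 — every polymorphic marker is used.

## REML estimation

Covariances are parameterized by log-Cholesky factors (diagonal of the
Cholesky factor on the log scale), which keeps every iterate positive
semi-definite by construction.  The restricted log-likelihood

    lR = −½ [ log|V| + log|X′V⁻¹X| + y′Py + (N − p) log 2π ]

is maximized by L-BFGS-B with analytic gradients; responses are
standardized internally (components and effects are rescaled back), and
log-standard-deviation parameters are bounded in [−12, 8], so boundary
variance estimates floor at ~1e-10 rather than going negative — a
heritability of 0.00 is representable.  The optimizer runs tighter than
the declared convergence tolerance (relative logL change < 1e-8 by
default) and restarts from its solution until a restart stops improving,
because a single flat step on a ridged REML surface can otherwise trigger
premature termination.  Moment-based starting values split the phenotypic
covariance evenly between Σt (scaled by the mean diagonal of G) and Σe.
An EM/average-information scheme would estimate the same quantities; the
quasi-Newton/log-Cholesky route was chosen for its unconditional PSD
guarantee and because exact gradients are cheap in both computational
routes below.

Two routes evaluate lR and its gradient:

* **Balanced route.** When every regular genotype is phenotyped in one
  year at the same time-point set, rotating the data by the eigenvectors
  of G decouples the likelihood into independent T×T blocks
  (d_k Σt + Σe per eigenvalue d_k, plus Σe blocks for check units), making
  each evaluation O(n T³).  This is the route used by default at study
  scale and inside cross-validation.
* **General route.** Arbitrary record-level missingness and multiple years
  per genotype are handled with a dense N×N covariance matrix; gradients
  accumulate the weighted trace identities blockwise by time pair.

Both routes are verified against each other and against a brute-force
maximization of an independently assembled restricted likelihood on tiny
instances (agreement to 1e-4 in logL, typically 1e-8).

GEBVs for every non-check genotype in G — phenotyped or not — come from
the same solution: û = G_{·,obs} Ê Σt, where Ê collects V⁻¹(y − Xβ̂) by
genotype and time.  For a genotype without records this equals
G_new,obs G_obs,obs⁻¹ û_obs; a genotype unrelated to all phenotyped ones
gets the prior mean 0.

## Inference conventions

* **Wald test (time effect):** conditional χ² on the T−1 contrasts of the
  per-time intercepts at the REML covariance estimates; calibration is
  asymptotic (mildly anticonservative below ~100 genotypes).
* **LRT (genotype-by-time interaction):** 2·ΔlogL between the unstructured
  and common genetic structures, referred to χ² with df equal to the
  difference in covariance-parameter counts.  The common structure lies
  partly on the boundary of the unstructured parameter space, so the
  nominal reference is conservative in a direction that depends on the
  alternative; the nominal df is used and stated.
* **BIC:** −2 logL + k log n with k = number of covariance parameters and
  n = phenotypic records after rep-averaging.  REML information criteria
  differ between software dialects; this convention is applied uniformly
  to both structures being compared, which is all a comparison needs.
* **Heritability:** h²_i = σ²g(i) / (σ²g(i) + σ²e(i)) from the diagonals
  of Σt and Σe.
* **Ψ (crossover proportion):** a genotype pair is a crossover between two
  time points iff the sign of the breeding-value difference strictly
  flips; ties count as non-crossover (the defining inequalities are
  strict).  The Monte-Carlo estimator samples unordered pairs uniformly
  with replacement (default 100,000 iterations, seeded); an exact
  enumerator over all C(n,2) pairs serves as its oracle.  Ψ is computed on
  BLUPs of the full longitudinal fit, and is invariant to per-time-point
  location shifts and positive rescaling.

## Cross-validation

Folds partition the non-check genotypes (checks are fixed effects, never
test individuals) into k=10 near-equal random groups; one master seed
derives per-repeat fold seeds through a `SeedSequence`, so the pipeline is
bit-for-bit reproducible and CV1/CV2 at the same seed share identical
partitions (paired comparisons).

* **CV1** deletes all records of the test genotypes, refits the model by
  REML (warm-started from the previous fold), and correlates test GEBVs
  with the held-out phenotypes at each time point.  Phenotypes are
  rep-averaged and fixed-effect-adjusted (fitted time and year effects
  subtracted) before correlating; a raw-phenotype option exists.  PA
  pools test pairs across folds within a repeat and averages over repeats
  (a per-fold aggregation option exists).
* **CV2(known → target)** keeps the test genotypes' records at one earlier
  time point.  Variance components are REML-estimated on the fully
  phenotyped training genotypes only — the identical fit to CV1 — and the
  known-time records enter at a fixed-component BLUP stage on the
  augmented record set (the general-route mixed-model solve).  This keeps
  component estimation untouched by any test-genotype data, makes CV2
  collapse exactly to CV1 when the known-time records are absent, and
  runs the 10×10-fold scheme in minutes.  The alternative — re-estimating
  components jointly with the known-time records — would expose the
  component estimates to test-genotype data and is not what a two-stage
  prediction pipeline does in practice.

## Synthetic population

The generator emulates a subtropical-blueberry-style postharvest trial:
588 genotypes (16 checks repeated across 3 years, the rest one year each,
uniformly assigned), 2,000 unlinked tetraploid markers, 4 storage time
points, 2 technical reps averaged before analysis.

Key design choices, with defaults:

| parameter | default | why |
|---|---|---|
| `n_parents` / `n_families` | 30 / 343 | one generation of biparental crosses from a reused elite-parent pool; 30 is the smallest pool supporting 343 distinct crosses. Tetrasomic gametes are Hypergeometric(4, dosage, 2), preserving Binomial(4, p) margins while creating the full-/half-sib kinship without which variance components and genomic prediction in an unreplicated design are barely identified. `n_families=None` gives an idealized unrelated population. |
| `n_qtl` | `None` (all markers) | fully polygenic architecture: breeding-value covariance is then exactly proportional to the realized marker G, the model GBLUP assumes. A sparse-QTL option exists; with few QTL among unlinked markers the marker G mismeasures QTL kinship and recovery degrades. |
| `h2` | 0.5 per time | mid-range of what postharvest quality traits show. |
| genetic correlations | 0.9 / 0.7 / 0.4 by lag | decaying with storage-time lag, the pattern that produces realistic crossover proportions. |
| residual correlations | 0.3 / 0.2 / 0.1 by lag | fruit of one harvest shares handling and ripeness; unit residual variances set the trait scale. |
| `year_effect_sd` | 0.3 | moderate year-to-year shifts relative to residual sd 1. |
| `rep_noise_frac` | 0.1 | technical reps differ by instrument noise only. |
| time means | 10 − 0.5·lag | a gentle postharvest decline so the time effect is testable. |

Per-time genetic variances are rescaled so the realized heritability
matches its target exactly up to residual sampling; the realized breeding
values, Σt, heritabilities, and year effects are returned as the truth
object, and recovery is benchmarked against these realized quantities, not
the asymptotic targets.

**What the generator does not emulate:** linkage disequilibrium and
haplotype structure (markers are unlinked), multi-generation pedigrees and
inbreeding, dominance/epistasis (the fitted model is additive-only, so the
generative model matches it), genotype-by-year interaction, spatial field
trends, and non-Gaussian measurement error.  Passing tests therefore show
that the estimators recover the truth of a correctly specified polygenic
additive world at study scale — not that real fruit data meet those
assumptions.

**Precision at study scale.** With unreplicated genotypes the separation
of Σt from Σe is identified only through between-family relatedness, so
the effective sample for variance-component precision is closer to the
number of parental lineages than to 588.  At the default design the
per-time-point h² standard error is ≈ 0.05 and genetic-correlation errors
of 0.1–0.2 occur for single realizations, with the REML optimum verified
exact by an independent maximizer.  Single-realization recovery tests
should be read with that yardstick.

## Numerical choices and degenerate inputs

* Collinear fixed-effect columns (e.g. a check panel that spans a whole
  year) are dropped greedily left-to-right (times, then years, then
  checks) before fitting.
* Zero-variance phenotypes, all-missing markers, non-PSD G, and
  heritability targets ≥ 1 raise errors; markers below `min_maf` and
  monomorphic markers are excluded with an error only when none remain.
* Rep-averaging is the arithmetic mean and is idempotent; Δ-traits are
  computed within (genotype, year) on rep-averaged values, skipping series
  without a baseline with a logged warning.
* Phenotypic correlations and baseline regressions use year-centred,
  rep-averaged genotype values by default (switchable); postharvest
  descriptives use raw rep-averaged values so means stay in trait units.
  "Softer/firmer" classification is strict; exact ties count as unchanged.
* Problem sizes in the test suite: the study-scale fixtures use 588
  genotypes × 2,000 markers (one REML fit ≈ 1 s via the balanced route);
  oracle comparisons use ≤ 10 genotypes; cross-validation checks run 10
  repeats × 10 folds at study scale, with the permuted-phenotype null at 2
  repeats.

## Known limitations

* Wald calibration and LRT boundary behaviour are asymptotic; no
  Kenward–Roger-type small-sample correction is implemented.
* The CV2 two-stage solve fixes components at training-set estimates;
  uncertainty in components is not propagated into PA.
* The dense route scales as O(N³) per iteration and is intended for
  N ≲ 5,000 records.
* Dominance/digenic relationship matrices, pedigree A-matrices, spatial
  adjustment, and Bayesian alternatives are out of scope.
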