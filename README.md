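# tetrablup

Longitudinal GBLUP for autotetraploid breeding populations: tetrasomic
genomic relationship matrices, multivariate REML across repeated-measures
time points, crossover-interaction statistics, and CV1/CV2 genomic
prediction.

## The problem

Postharvest fruit quality — firmness, acidity, water loss — changes over
weeks of cold storage, and different genotypes change differently.  A
breeding program that phenotypes hundreds of selections at several storage
time points (e.g. 1 day, 1 week, 3 weeks, 7 weeks) in an augmented design
(unreplicated entries connected across years by repeated checks) needs to
answer: how heritable is each trait at each time point, how strongly do
genotype rankings reorder during storage, and how well can genomic data —
possibly combined with an early measurement — predict performance after
long storage?  This package implements that analysis for autotetraploid
crops such as highbush blueberry, where marker genotypes are allele
dosages in 0–4.

## The model

For a trait measured at T storage time points,

```
y = X1 β + X2 t + X3 g1 + Z g2 + e
g2 ~ MVN(0, Σt ⊗ G),    e ~ MVN(0, Σe ⊗ I)
```

where β and t give a fixed mean per time point plus year-of-evaluation
effects, g1 holds fixed effects of the replicated check genotypes, and g2
holds random genotype-by-time effects (GEBVs).  G is the additive
relationship matrix built from allele dosages by the VanRaden method
generalized to tetrasomic inheritance:

```
W = M − m·P,    G = W W′ / Σ_j m p_j (1 − p_j)      (m = ploidy)
```

Σt and Σe are unstructured T×T genetic and residual covariance matrices,
estimated by REML (log-Cholesky parameterization, analytic-gradient
quasi-Newton, with a fast eigen-rotation route for the balanced layout).
Derived quantities:

* narrow-sense heritability per time point, `h²_i = σ²g(i) / (σ²g(i) + σ²e(i))`;
* Wald χ² test of the storage-time effect and a likelihood-ratio test of the
  genotype-by-time interaction (unstructured vs a common genetic effect),
  with BIC for structure comparison;
* the crossover proportion Ψ: the share of genotype pairs whose breeding-value
  ranking strictly reverses between two time points (Monte-Carlo over
  100,000 sampled pairs, or exact enumeration);
* prediction ability (PA) = Pearson correlation of GEBVs with phenotypes in
  10-fold cross-validation, in a CV1 scheme (test genotypes fully
  unphenotyped) and CV2 schemes (test genotypes keep one earlier time
  point).

A synthetic-population module generates tetraploid dosage matrices with
family structure (parent pool → biparental crosses with hypergeometric
gamete segregation), fully polygenic additive time-course effects, and the
augmented phenotyping design, with the realized truth recorded for
benchmarking.

## Worked example

```python
from tetrablup import (SimulationConfig, ModelSpec, simulate_dosages,
                       simulate_phenotypes, vanraden_grm, fit_longitudinal,
                       heritability, genetic_correlations, lrt_interaction,
                       psi_monte_carlo)

cfg = SimulationConfig(n_genotypes=300, n_checks=12, n_markers=1000,
                       n_families=180, n_parents=20, seed=42)
dosages = simulate_dosages(cfg)                    # 300 x 1000 tetraploid dosages
pheno, truth = simulate_phenotypes(dosages, cfg)   # 4 storage time points, 3 years
G = vanraden_grm(dosages)                          # tetrasomic VanRaden G

fit = fit_longitudinal(pheno, G, ModelSpec(trait="trait1"))
print("converged:", fit.converged, " REML logL: %.2f" % fit.loglik)
print("h2 per time point:")
print(heritability(fit.components).round(2).to_string())
print("genetic correlation 1D-7W: %.2f"
      % genetic_correlations(fit.components).loc["1D", "7W"])

reduced = fit_longitudinal(pheno, G, ModelSpec(trait="trait1",
                                               genetic_structure="common"))
stat, p = lrt_interaction(fit, reduced)
print("G x time LRT: chi2 = %.1f, p = %.2g" % (stat, p))

psi = psi_monte_carlo(fit.blups, "1D", "7W", n_iter=100_000, seed=1)
print("crossover proportion Psi(1D-7W): %.3f" % psi.psi)
print("realized simulated h2:", truth.h2.round(2).tolist())
```

prints

```
converged: True  REML logL: -1995.38
h2 per time point:
1D    0.60
1W    0.51
3W    0.43
7W    0.41
genetic correlation 1D-7W: 0.50
G x time LRT: chi2 = 55.9, p = 8e-09
crossover proportion Psi(1D-7W): 0.348
realized simulated h2: [0.51, 0.51, 0.49, 0.52]
```

The heritability estimates bracket the simulated truth of ~0.5 per time
point; the LRT detects the genotype-by-time interaction that the
lag-decaying genetic correlations (0.9/0.7/0.4) induce, and about a third
of genotype pairs cross over in breeding value between harvest and 7 weeks
— exactly the pattern such data imply (for bivariate-normal breeding
values, Ψ = arccos(r)/π ≈ 0.33 at r = 0.5).

A command-line pipeline is available as `tetrablup simulate | grm | fit |
summary | psi | cv`; every subcommand writes CSV/JSON artifacts plus a
run-metadata JSON with seeds and versions.

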