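# polymort

Comparative analysis of polyandry and female mortality in mammals: life-table
demography, phylogenetic generalized least squares (PGLS) with maximum-likelihood
Pagel's λ, and AICc-based model selection — with a synthetic-data generator that
produces trees, trait tables and life tables with known ground truth so every
stage is testable without external downloads.

## The scientific problem

Across mammals, does the level of female polyandry — proxied by male relative
testes mass (paired testes mass conditioned on body mass, the classic
sperm-competition signal) and by the percentage of multiply-sired litters —
predict female mortality patterns?  Two mortality metrics are derived per
species from age-specific survival data:

* **median lifespan** — the age at which survivorship l(x) of a cohort
  initialised at age 1 drops to 0.5 (linear interpolation between age classes);
* **aging rate** — the OLS slope of annual survival s(x) on age from the onset
  of senescence onward, where the onset is located on a smoothed
  (spline-GAM) survival trajectory; analysed as log |slope|.

Because both metrics co-vary with the pace of life, age at first reproduction
(AFR) enters every candidate model set as the slow–fast-continuum control, and
male body mass accompanies testes mass in every model that includes it (so
relative investment is modelled without regressing on residuals).

Species are not independent observations: under Brownian trait evolution the
expected covariance of two species equals their shared root-to-ancestor branch
length V[i,j].  The regression model is

    y = Xβ + ε,   ε ~ N(0, σ² V(λ)),   V(λ) = λ·V off-diagonal, diag(V) kept,

with λ ∈ [0, 1] (Pagel's λ) profiled out by bounded ML optimisation.  Candidate
models are ranked by AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k counting
coefficients plus σ² and λ; Akaike weights w_i ∝ exp(−Δᵢ/2) quantify relative
support, and when two models sit within 2 AICc units the one with fewest
parameters is retained (parsimony rule).

## Worked example

Generate a synthetic 51-species study in which AFR drives both mortality
metrics and testes mass has no effect (the null the analysis is designed to
probe), extract the demographic metrics, and run the testes-mass candidate set
for median lifespan:

```python
from polymort import (make_study_fixture, metrics_table, assemble,
                      run_block, table2_models)

fx = make_study_fixture(n_species=51, seed=42)
m = metrics_table(fx.life_tables)
ds = assemble(m, fx.traits, fx.tree)
cmp = run_block(ds, "log_median_lifespan", table2_models("log_median_lifespan"))
print(cmp.table.round(3))
```

```
                                          label  k  lambda  r2_adj   aicc  delta_aicc  weight selected
                                       Constant  3   0.136   0.000 52.874      15.644   0.000
                      Age at first reproduction  4   0.000   0.291 37.230       0.000   0.894        *
                                      Body mass  4   0.000   0.001 54.676      17.446   0.000
                          Testes mass+Body mass  5   0.000  -0.018 57.054      19.824   0.000
Age at first reproduction+Testes mass+Body mass  6   0.000   0.262 42.138       4.907   0.077
Age at first reproduction*Testes mass+Body mass  7   0.000   0.257 44.083       6.853   0.029
```

The AFR-only model carries essentially all the Akaike weight (0.894) and is
retained; every model containing testes mass performs worse than the
pace-of-life model alone — the generated null is recovered.  The headline
bivariate fit on the same dataset prints

```
lifespan~AFR slope = 1.140 ± 0.246, t = 4.63, lambda = 0.000, adj R2 = 0.29, n = 51
```

i.e. median lifespan scales close to proportionally with age at first
reproduction on the log scale (generative truth: slope 1.0, no residual
phylogenetic signal).

The same workflow is available from a shell:

```bash
polymort simulate --n-species 51 --seed 42 --out fixture/
polymort metrics --life-tables fixture/life_tables.csv --out metrics.tsv
polymort analyze --metrics metrics.tsv --traits fixture/traits.csv \
                 --tree fixture/tree.nwk --out report/
```

`analyze` writes one TSV per (response × subset) comparison block plus a
headline-fit summary, and accepts `--subset <order>` for taxonomic blocks and
`--drop <species>` for sensitivity reruns.

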