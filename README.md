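# spatgxe

Spatial fine-mapping of disease risk into environmental (E) and
gene-by-environment (GxE) components, for epidemiologists and statistical
geneticists working with georeferenced cohort or case-cohort data (e.g.
national registries linked to genotypes).

Where one's upbringing place carries disease risk, and where it modulates
genetic liability, are usually studied through coarse proxies such as
urban/rural categories. `spatgxe` instead estimates latent spatial random
fields directly: it partitions the map into *locales* — contiguous units
holding a minimum number of cohort members, built by adaptively merging
Voronoi cells along their Delaunay neighbour graph — and then fits a
weighted mixed-effects Cox model over those locales.

## Model

For subject *i* in locale ℓ(*i*) with covariates *x*ᵢ and standardized
polygenic score PRSᵢ, the hazard is

```
λ_i(t) = λ_{0,s(i)}(t) · exp( x_i'β + b_E[ℓ(i)] + b_GxE[ℓ(i)] · PRS_i )

b_E ~ N(0, σ²_E I)        locale random intercepts  (E field)
b_GxE ~ N(0, σ²_GxE I)    locale random PRS slopes  (GxE field)
```

with stratum-specific baseline hazards (duration of residence) and
inverse-probability-of-sampling weights for case-cohort designs (cases
weight 1, subcohort members 1/sampling fraction). Estimation is penalized
partial likelihood (Breslow ties) with Newton–Raphson for (β, b), and a
bounded derivative-free search over the variance components maximizing the
Laplace-approximate integrated partial likelihood. Posterior means of the
random effects (BLUPs) give per-locale hazard-ratio maps; between-locale
heterogeneity is summarized by the **median hazard ratio**, the median of
exp(|bᵢ − bⱼ|) over all locale pairs (closed form exp(√(2σ²)·z₀.₇₅) under
normality). A model-free companion map uses age-stratified Mantel–Haenszel
risk ratios per locale versus the rest of the sample.

Supporting modules: PRS construction from GWAS summary statistics and VCF
dosages (allele alignment, clumping at r² = 0.1 within 250 kb, pruning at
r² = 0.8 in 2 kb windows, standardized scoring) and a Monte Carlo
simulation suite that generates case-cohort populations with known E/G/GxE
structure to calibrate the estimator.

## Worked example

`examples/03_spatial_cox_fit.py` simulates 20,000 subjects over 100
locales with σ²_E = 0.25, σ²_GxE = 0.15 and a perfect genetic instrument,
then fits the full model:

```
20000 subjects, 410 cases, 100 locales
sigma2_E   = 0.177  (truth 0.25)
sigma2_GxE = 0.107  (truth 0.15)
beta_PRS   = 1.585  (truth 1.528)
LRT vs fixed-effects model: chi2_2 = 72.0, p = 2.35e-16
median HR (E): pairwise 1.22, closed-form 1.49
median HR (GxE): pairwise 1.22, closed-form 1.37
```

The variance components are recovered to within single-replicate Monte
Carlo noise (run `examples/05_calibration_study.py` for the averaged
picture), the likelihood-ratio test decisively rejects the fixed-effects
model, and the median hazard ratios translate the variances onto the
hazard-ratio scale: two random locales differ in environmental risk by a
median factor of ~1.5. The other examples cover locale construction
(`01`), Mantel–Haenszel risk maps (`02`), and PRS construction (`04`).

A thin CLI mirrors the library for shell pipelines:

```
spatgxe tessellate --subjects s.tsv --min-count 100 --out locales.geojson
spatgxe fit --records r.tsv --model 3 --out fit.json
spatgxe pipeline --config cfg.json
```

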