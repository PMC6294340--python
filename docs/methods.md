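# Methods

## Locale construction

Subjects enter as planar projected coordinates (metres). Coordinates are
first collapsed to a privacy grid — half-open cells of `resolution` metres
(default 1000 m, matching 1 km² registry blurring), each occupied cell
becoming one generator with a multiplicity. The Voronoi tessellation of
the generators, clipped to a boundary polygon, partitions the map so every
location belongs to the cell of its nearest generator; the Delaunay
triangulation supplies the neighbour graph. The default boundary is the
convex hull of the generators buffered by one grid resolution; without a
finite boundary the exterior cells would have infinite area and undefined
density.

Cells are then merged into locales until each holds at least `n_min`
members (default 100). The merge schedule is deterministic: repeatedly
take the locale with the fewest members below `n_min` (ties: lower id) and
merge it into the neighbouring locale whose population-weighted centroid
is nearest (ties: fewer graph neighbours, then lower id). A single lower
bound is used rather than a target interval: merging stops as soon as a
locale reaches `n_min`, so an upper bound emerges implicitly, and a hard
upper bound could make the merge infeasible on some graphs. A connected
component whose total population is below `n_min` is kept as one
undersized locale with a warning. Locale population density is
members/area (persons/km²); because cell size adapts to point density,
density falls out of the construction for free.

Degeneracies are handled explicitly: duplicate coordinates are collapsed
before tessellating (Voronoi requires distinct sites); co-circular
quadruples, where the Delaunay triangulation is not unique, are resolved
by a documented lexicographic rule (order each candidate diagonal's
endpoints by (x, y); the diagonal whose lower endpoint sorts first wins).
Delaunay adjacency ignores water, so neighbour relations may cross straits
on real coastlines; this is accepted and documented rather than patched.

Subjects — including cases excluded from map construction — are assigned
to the locale of their nearest generator, which coincides with polygon
containment in the interior and resolves boundary ties deterministically.
Points outside the boundary are assigned to the nearest locale with a
warning.

## Mantel–Haenszel risk map

The model-free overall risk map compares each locale against all subjects
outside it (every locale is small relative to the country, so "outside"
approximates the national average). Counts are pooled over age bands of
the age at study end (default 5-year bands, configurable) with the
Mantel–Haenszel risk-ratio estimator; 95% CIs use the Greenland–Robins
variance. Strata with a zero inside or outside total are dropped without
continuity correction, and undefined ratios are flagged rather than
imputed. Counts may be inverse-probability weighted so case-cohort tallies
estimate population tallies; both weighted and raw counts are supported
because either convention is defensible for a descriptive map. Note the MH
estimate is invariant to rescaling a stratum's counts only when all strata
share a common risk ratio (it is a weighted pool otherwise); the test
suite checks exactly that collapsible form.

## Spatial mixed-effects Cox model

Linear predictor: η_i = x_i'β + b_E[ℓ(i)] + b_GxE[ℓ(i)]·PRS_i, with
independent Gaussian locale intercepts (variance σ²_E) and PRS slopes
(variance σ²_GxE). The two fields are kept independent and iid across
locales because they are reported as two separate scalar variance
components; spatially correlated fields (CAR/Matérn) are a possible
extension, not the default. Weights enter the Breslow partial likelihood
as case weights (inverse sampling probabilities; cases 1, subcohort
1/fraction), and strata (duration of residence: 5 or 7 years) define
separate baseline hazards and risk sets.

Estimation is nested optimization:

* **Inner:** at fixed θ = (σ²_E, σ²_GxE), Newton–Raphson with step
  halving maximizes the penalized partial log-likelihood
  ℓ(β, b) − ½ b_E'b_E/σ²_E − ½ b_GxE'b_GxE/σ²_GxE. Convergence when the
  relative objective change is < 1e-8 or the gradient sup-norm < 1e-6;
  max 50 iterations, non-convergence returns a flagged partial fit. The
  kernel exploits the locale-indicator structure of the random-effect
  columns, so each evaluation is O(n + m·q·p) (n subjects, m event times,
  q locales, p fixed terms) rather than dense in the full design.
* **Outer:** θ maximizes the Laplace-approximate integrated partial
  likelihood ℓ_pen(mode) − ½ log det K + ½ log det Q, with K the
  random-effect block of the penalized information and Q the penalty
  precision. The search is derivative-free and bounded (Brent for one
  component, Powell for two) on the log10 scale over θ ∈ [1e-8, 10]. A
  REML-type variant adding a fixed-effect profile correction is available
  behind a flag; the maximum-likelihood objective is the default. An
  estimate at the lower bound is reported as exactly 0 with a boundary
  flag.

Fixed-effect standard errors come from the inverse penalized information;
robust (sandwich) SEs from weighted score residuals (random effects held
as offsets) are computed by default and match a reference implementation
on weighted stratified fits. Model 1 is fixed effects only; Model 2 adds
the E intercepts; Model 3 adds the GxE slopes plus all pairwise
PRS × covariate fixed interactions. Population density enters as a
log-transformed continuous covariate (linear is available), with the
urbanicity contrast reported as exp(β·(log 5220 − log 55)), the
conventional urban and rural density categories.

Likelihood-ratio tests compare integrated log-likelihoods of nested
models with df = number of added variance components, against a plain
χ²_df reference. At the boundary σ² = 0 this is conservative (a 50:50
χ² mixture, available as an option, would halve the p-value); the null
calibration test confirms rejection at or below the nominal level.

The median hazard ratio is reported both ways: empirically as the median
of exp(|b_i − b_j|) over all locale pairs of BLUPs, and in closed form as
exp(√(2σ̂²)·z₀.₇₅). Because BLUPs are shrunken toward zero, the pairwise
value sits below the closed form whenever the per-locale information is
modest; both are exposed because the two conventions answer slightly
different questions (realized map heterogeneity vs model-scale
heterogeneity).

## Synthetic populations and calibration

The generator emulates a registry case-cohort study: n individuals
(reference profile 30,000) split evenly over q locale clusters (default
100) on a square grid with 10 km spacing and 1.5 km within-cluster
scatter; a standard-normal genetic liability G; an instrument
PRS = √r²·G + √(1−r²)·noise; locale effects b_E ~ N(0, σ²_E) and
b_GxE ~ N(0, σ²_GxE). Event ages are exponential proportional-hazards
draws with the baseline rate calibrated by root finding so the expected
cumulative incidence by the censoring age (default 35 years, the upper
end of a registry follow-up window for early-adult-onset disease) equals
the target prevalence (default 1%); non-events are censored there.

Heritability (default 0.7) is anchored on the liability scale with a unit
individual-level non-genetic variance: β_G = √(h²/(1−h²)) per SD of true
G, so the genetic share of individual-level liability variance is h². The
spatial components sit on top of this and are excluded from the
heritability bookkeeping — this keeps β_G finite and well-defined in null
simulations and gives β_G = 0 at h² = 0. A liability-threshold variant
(case = liability above the (1−prevalence) quantile, onset age uniform)
is available for robustness checks.

Case-cohort sampling keeps all cases at weight 1 and a Bernoulli
subcohort of non-cases at weight 1/fraction. The calibration study
defaults to fitting the full simulated sample (fraction 1): the reference
Monte Carlo profile treats the stated sample size as the analysis sample,
and the weighting machinery is validated separately through
Horvitz–Thompson identities. Replicate RNGs derive from a documented
counter scheme (master seed, cell index, replicate index), so every run
is reproducible end to end.

Desk-scale profiles used by the test suite and the acceptance script:
50 replicates at n = 10,000 with 100 locales for environmental-variance
recovery; 30 replicates per cell over r² ∈ {0.1, 0.5, 1.0} with
σ²_GxE = 0.25 for the attenuation curve (0.25 matches the E condition, so
both fields live on the same scale); 200 replicates at n = 4,000 with 50
locales for null LRT calibration. The full reference profile
(1000 × 30,000) is available through the same config.

What the generator does not emulate: real geography (coastlines,
migration, spatially correlated fields), SNP-level genotypes (the PRS is
simulated directly as a noisy instrument; SNP-level behaviour is tested
in the PRS module on constructed dosages), secular trends in incidence,
and residence changes between birth and age 7. Passing calibration
therefore shows the estimator recovers its own generative model at
realistic sparsity — about 1% events — not that every registry
complication is handled.

## PRS construction

Alleles are matched on SNP id (or chrom:pos), betas sign-flipped for
swapped effect/other coding, strand-ambiguous (A/T, C/G) SNPs dropped.
LD is the squared Pearson correlation of dosages in the analysis sample
itself — standard for imputed data, and self-contained since no external
panel is assumed. Clumping is greedy by ascending p-value (ties: lower
chrom, then position): keep the index SNP, remove SNPs within 250 kb at
r² > 0.1, repeat. Pruning slides 2 kb windows in 2 kb steps, repeatedly
dropping the larger-p member of the strongest remaining pair above
r² = 0.8. No p-value threshold filters SNPs. Scores are raw
dosage-weighted sums, zero-centred and scaled to unit variance; a
zero-variance score (e.g. all betas 0) is returned unstandardized with a
flag. Monomorphic SNPs, whose r² is undefined, are excluded up front.

## Known limitations

* With ~1 event per locale the Laplace approximation shows a small
  downward tilt in σ̂²_GxE (a few hundredths at truth 0.25) and the usual
  boundary pile-up at zero inflates means when the truth is near zero;
  both are visible in, and bounded by, the calibration outputs.
* When the instrument is weak (r² ≪ 1) and the genetic main effect is
  large, the unexplained genetic variance acts as individual-level
  frailty and inflates σ̂²_E; the E-recovery guarantee applies to the
  well-instrumented setting.
* The pairwise median hazard ratio of BLUPs is attenuated by shrinkage
  relative to the closed form; neither is "the" truth and both are
  reported.
* Exact/Efron tie handling, time-varying covariates, competing risks and
  non-Gaussian frailties are out of scope; Breslow ties only.
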