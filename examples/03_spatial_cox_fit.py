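"""Decompose spatial risk into E and GxE with the mixed-effects Cox model.

Simulates a cohort whose log-hazard carries locale intercepts (E,
variance 0.25) and locale-specific slopes on the polygenic score (GxE,
variance 0.15), fits the model, and reports variance components, the
likelihood-ratio test against the fixed-effects model, and median hazard
ratios — the expected change in risk between two randomly chosen locales.
"""

import numpy as np

from spatgxe import (
    ModelSpec,
    SimulationConfig,
    fit_variance_components,
    lrt_random_effects,
    simulate_population,
)

cfg = SimulationConfig(
    n_individuals=20_000, n_locales=100, sigma2_E=0.25, sigma2_GxE=0.15,
    instrument_r2=1.0, prevalence=0.02, seed=3,
)
population, truth = simulate_population(cfg)
print(f"{len(population)} subjects, {population.case.sum()} cases, "
      f"{cfg.n_locales} locales")

full = fit_variance_components(
    population, ModelSpec(("prs",), random_intercept=True, random_slope=True,
                          strata_col=None), robust=False,
)
reduced = fit_variance_components(
    population, ModelSpec(("prs",), False, False, strata_col=None), robust=False
)

print(f"sigma2_E   = {full.sigma2_E:.3f}  (truth {cfg.sigma2_E})")
print(f"sigma2_GxE = {full.sigma2_GxE:.3f}  (truth {cfg.sigma2_GxE})")
print(f"beta_PRS   = {full.beta['prs']:.3f}  (truth {truth['beta_g']:.3f})")
stat, df, p = lrt_random_effects(full, reduced)
print(f"LRT vs fixed-effects model: chi2_{df} = {stat:.1f}, p = {p:.2e}")
for comp, d in full.median_hr().items():
    print(f"median HR ({comp}): pairwise {d['pairwise_empirical'].mhr:.2f}, "
          f"closed-form {d['closed_form'].mhr:.2f}")
print("The closed form converts the variance component itself; the pairwise "
      "value uses shrunken BLUPs and is therefore slightly smaller.")
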