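import numpy as np
import pandas as pd
import pytest

from spatgxe.simulation import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_survival_frame(seed: int, n: int = 400, n_locales: int = 10,
                          weighted: bool = True, stratified: bool = True) -> pd.DataFrame:
    """Small random survival table with covariates, weights and strata."""
    r = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "event_age": r.exponential(10, n) + 0.5,
            "case": r.binomial(1, 0.4, n),
            "weight": np.where(r.random(n) < 0.5, 1.0, 3.0) if weighted else 1.0,
            "x1": r.normal(size=n),
            "x2": r.normal(size=n),
            "prs": r.normal(size=n),
            "locale_id": r.integers(0, n_locales, n),
        }
    )
    if stratified:
        df["res_stratum"] = r.integers(0, 2, n)
    return df


@pytest.fixture(scope="session")
def small_population():
    """One simulated population at desk scale with spatial structure."""
    cfg = SimulationConfig(n_individuals=4000, n_locales=25, sigma2_E=0.25, seed=7)
    pop, truth = simulate_population(cfg)
    return pop, truth, cfg


@pytest.fixture()
def subject_table(rng):
    """Well-formed subject table matching the full input schema."""
    n = 200
    r = np.random.default_rng(42)
    xy = r.uniform(0, 30000, (n, 2))
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "x_birth": xy[:, 0], "y_birth": xy[:, 1],
            "x_age5": xy[:, 0], "y_age5": xy[:, 1],
            "x_age7": xy[:, 0], "y_age7": xy[:, 1],
            "case": r.binomial(1, 0.2, n),
            "event_age": r.uniform(1, 35, n),
            "sex": r.integers(0, 2, n),
            "pc1": r.normal(size=n), "pc2": r.normal(size=n), "pc3": r.normal(size=n),
            "famhx": r.binomial(1, 0.05, n),
            "prs": r.normal(size=n),
            "samp_prob": np.where(r.random(n) < 0.5, 1.0, 0.5),
            "res_stratum": np.where(r.random(n) < 0.5, "5y", "7y"),
        }
    )
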