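import numpy as np
import pandas as pd
import pytest

from maizegs.genomic import build_grm
from maizegs.simdata import default_stage1_config, simulate_population_set, \
    simulate_trials


def small_config(seed=11, **overrides):
    """A compact three-family scenario used across the suite."""
    params = dict(
        n_populations=3, lines_per_population=[40, 40, 40],
        n_chromosomes=5, markers_per_chromosome=40, n_qtl=50,
        environments=[("WW1", "WW"), ("WW2", "WW"), ("WS1", "WS")],
        blocks_per_rep=5, n_checks=4, seed=seed,
    )
    params.update(overrides)
    return default_stage1_config(**{k: v for k, v in params.items()
                                    if k != "seed"}, seed=params["seed"])


@pytest.fixture(scope="session")
def small_scenario():
    cfg = small_config()
    geno, truth = simulate_population_set(cfg)
    pheno = simulate_trials(truth, cfg)
    return cfg, geno, truth, pheno


@pytest.fixture(scope="session")
def small_grm(small_scenario):
    _, geno, _, _ = small_scenario
    return build_grm(geno)


def balanced_trial_frame(n_entries=40, n_loc=2, n_reps=2, seed=0,
                         s2_g=1.0, s2_gl=0.5, s2_e=0.8, mean=5.0):
    """Balanced multi-location plot data with known simulated components,
    one block per replicate (RCBD)."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2_g), n_entries)
    gl = rng.normal(0, np.sqrt(s2_gl), (n_entries, n_loc))
    loc_eff = rng.normal(0, 0.5, n_loc)
    rep_eff = rng.normal(0, 0.3, (n_loc, n_reps))
    rows = []
    for i in range(n_entries):
        for j in range(n_loc):
            for r in range(n_reps):
                rows.append({
                    "trial": "T01", "location": f"L{j + 1}",
                    "management": "WW", "rep": f"R{r + 1}", "block": "B1",
                    "entry": f"E{i:03d}", "tester": "T1", "cohort": "GS",
                    "y": mean + loc_eff[j] + rep_eff[j, r] + g[i] + gl[i, j]
                    + rng.normal(0, np.sqrt(s2_e)),
                })
    return pd.DataFrame(rows)
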