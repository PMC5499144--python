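import numpy as np
import pandas as pd
import pytest

from qfascreen import (
    ScreenFitnessTable,
    SimulationConfig,
    simulate_screen_pair,
    summarize_screen,
)


def make_fitness_table(values_by_orf, screen_id="SCR", background="control",
                       treatment="chronic"):
    """Build a ScreenFitnessTable directly from {orf: [replicate fitnesses]}."""
    rows = []
    for orf in sorted(values_by_orf):
        reps = [float(v) for v in values_by_orf[orf]]
        rows.append({
            "orf": orf, "gene": orf.lower(), "n": len(reps),
            "fitness_mean": float(np.mean(reps)),
            "fitness_median": float(np.median(reps)),
            "mdr_mean": 1.0, "mdp_mean": 1.0,
            "replicates": reps,
        })
    return ScreenFitnessTable(screen_id, background, treatment, pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=60, n_replicates=4, seed=7,
                            dead_fraction=0.0, noise_sigma=0.02)


@pytest.fixture(scope="session")
def small_pair(small_config):
    """One small noisy simulated screen pair, shared across tests."""
    return simulate_screen_pair(small_config)


@pytest.fixture(scope="session")
def small_tables(small_pair):
    control_curves, query_curves, _ = small_pair
    return summarize_screen(control_curves), summarize_screen(query_curves)
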