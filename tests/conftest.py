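import warnings

import numpy as np
import pytest

from berrysync import synthetic

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def design():
    return synthetic.stage_design(n_reps=3)


@pytest.fixture(scope="session")
def default_cohort():
    """One stage-sampled Syrah cohort at default study conditions."""
    cfg = synthetic.CohortConfig(seed=7)
    return synthetic.make_stage_cohort(cfg, synthetic.GENOTYPES["syrah"], 3)


@pytest.fixture(scope="session")
def null_counts(design):
    """All-flat (null) count matrix for calibration tests."""
    arch = {"flat": (synthetic.ExpressionArchetype("flat", 1.0), 1.0)}
    counts, lengths, truth = synthetic.simulate_counts(
        design, archetypes=arch, n_genes=2000, seed=11)
    return counts, lengths, truth


@pytest.fixture(scope="session")
def switchoff_counts(design):
    """Flat background plus a 5-fold switch-off class at high expression."""
    arch = {
        "flat": (synthetic.ExpressionArchetype("flat", 1.0), 0.8),
        "switch_off": (synthetic.ExpressionArchetype("switch_off", 0.2, 500.0), 0.2),
    }
    counts, lengths, truth = synthetic.simulate_counts(
        design, archetypes=arch, n_genes=1000, seed=13)
    return counts, lengths, truth


@pytest.fixture()
def toy_tukey_data():
    rng = np.random.default_rng(5)
    values = np.concatenate([rng.normal(10, 1, 5), rng.normal(0, 1, 5), rng.normal(0, 1, 5)])
    groups = np.array(["G"] * 5 + ["P"] * 5 + ["S"] * 5)
    return values, groups
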