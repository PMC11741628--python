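import numpy as np
import pandas as pd
import pytest

from kirmod import syndata


@pytest.fixture(scope="session")
def interaction_cohort():
    """Mid-sized cohort with a strong score-by-genotype interaction."""
    cfg = syndata.default_cohort_config(
        1500, 1500, interaction_beta=0.9, seed=11
    )
    return cfg, syndata.generate_cohort_frame(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with genotype effects but no score interaction and no class I
    linkage, so the iKIR score is exchangeable against disease status."""
    cfg = syndata.default_cohort_config(1000, 1000, interaction_beta=0.0, seed=7)
    cfg.ld_links = []
    return cfg, syndata.generate_cohort_frame(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = syndata.default_cohort_config(150, 150, seed=3)
    return cfg, syndata.generate_cohort_frame(cfg)


def frame_from_counts(a, b, c, d, rng_seed=0):
    """Cohort-like frame realising a 2x2 carriage-by-status table, with a
    carriage indicator column ``g`` (no genotype columns needed)."""
    rows = (
        [(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d
    )
    carr, status = zip(*rows)
    rng = np.random.default_rng(rng_seed)
    return pd.DataFrame(
        {
            "status": status,
            "g": carr,
            "sex": rng.choice(["F", "M"], size=len(rows)),
        }
    )
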