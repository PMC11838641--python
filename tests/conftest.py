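import numpy as np
import pytest

from hdproxy import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort with notes, codes and covariates."""
    cfg = SimConfig(
        n_patients=120,
        n_latent=2,
        alpha=0.6,
        gamma=0.4,
        n_claims_codes=15,
        n_ehr_codes=8,
        vocab_size=30,
        notes_per_patient=2.0,
        tokens_per_note=8.0,
        n_researcher_flags=3,
        seed=42,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
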