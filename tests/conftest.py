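import numpy as np
import pytest

from perifuse import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject cohort with default planted signal (session-cached)."""
    spec = synthetic.CohortSpec(n_subjects=60, seed=42)
    return spec, synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def trained_dual_ae():
    """A dual-loss autoencoder trained on a 150-subject strong-signal cohort."""
    from perifuse import autoencoder

    spec = synthetic.CohortSpec(n_subjects=150, seed=7)
    subjects = synthetic.generate_cohort(spec)
    x = np.stack([s.image.pixels for s in subjects])
    y = np.array([s.labels.severity for s in subjects])
    cfg = autoencoder.AEConfig(latent_dim=64, seed=3)
    model = autoencoder.train_ae(x, y, cfg)
    return model, subjects, x, y


@pytest.fixture(scope="session")
def multiseed_results():
    """The 5-seed synthetic study backing the fusion / dual-loss /
    interpretability claims (expensive; shared across acceptance tests)."""
    from perifuse.experiments import multiseed_study

    return multiseed_study(n_seeds=5, base_seed=0, n_subjects=400)
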