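import numpy as np
import pytest

from nanodyn import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def four_class_cohort():
    """Labeled mixture at the four reference motion regimes, 150 frames,
    30-ms interval, 20-nm localization error."""
    components = (
        ("immobile", synthetic.TrajectorySpec(n_frames=150, D=0.001, alpha=1.0,
                                              sigma_err=0.02), 75),
        ("subdiffusion", synthetic.TrajectorySpec(n_frames=150, D=0.05, alpha=0.4,
                                                  sigma_err=0.02), 75),
        ("normal", synthetic.TrajectorySpec(n_frames=150, D=0.05, alpha=1.0,
                                            sigma_err=0.02), 75),
        ("superdiffusion", synthetic.TrajectorySpec(n_frames=150, D=0.05, alpha=1.6,
                                                    sigma_err=0.02), 75),
    )
    spec = synthetic.CohortSpec(components=components, seed=20260927)
    return synthetic.simulate_cohort(spec)
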