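import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def female_low_params():
    from pigmove import synthetic

    return synthetic.default_hmm_params("female", "low_forage")


@pytest.fixture(scope="session")
def short_series(female_low_params):
    """A handful of moderate simulated bursts for fit smoke tests."""
    from pigmove import synthetic

    rng = np.random.default_rng(7)
    return [
        synthetic.simulate_track(
            female_low_params, 400, rng=rng, animal_id=f"A{i}"
        )[2]
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def small_landscape():
    from pigmove import synthetic

    return synthetic.make_landscape(
        synthetic.LandscapeConfig(extent=3000.0, seed=5)
    )
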