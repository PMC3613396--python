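import pytest

from dpsevolve.simulate import generate_cohort

# scaled-down stated world used by most unit tests: 2 Mb replicons with a
# proportional 0.5 Mb arm region keep the suite fast; acceptance tests use
# full-size defaults where the criterion budget allows
SMALL = dict(length=2_000_000, n_genes=25, arm_threshold=500_000)


@pytest.fixture(scope="session")
def small_cohort():
    """Five genomes, all carrying a dpsB/dpsB2 paralog pair, no Ct noise."""
    return generate_cohort(n_genomes=5, noise_sd=0.0, seed=3, **SMALL)


@pytest.fixture(scope="session")
def small_params():
    return {"arm_threshold": SMALL["arm_threshold"], "bootstrap_reps": 50}
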