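import numpy as np
import pytest

from cyp2d6dup.alleles import AlleleRegistry
from cyp2d6dup.simulate import (
    SimConfig,
    load_study_fixture,
    make_study_cohort,
    simulate_run,
    truth_record,
)


@pytest.fixture(scope="session")
def registry():
    return AlleleRegistry.default()


@pytest.fixture(scope="session")
def fixture_df():
    return load_study_fixture()


@pytest.fixture(scope="session")
def cohort():
    return make_study_cohort(seed=1)


def noise_free_config(**kw) -> SimConfig:
    base = dict(seed=5, sigma_f=0.0, lot_sd=0.0, amp_sd=0.0, sigma_c=0.0)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noise_free_main_run(cohort):
    """The 73-case main cohort simulated without any noise source."""
    return simulate_run(cohort.main, noise_free_config())


@pytest.fixture(scope="session")
def stochastic_cohort():
    """200 three-copy cases drawn from the main-dataset genotype mix."""
    df = load_study_fixture()
    main = df[df["dataset"] == "main"]
    rng = np.random.default_rng(42)
    genotypes = rng.choice(
        main["genotype"], size=200, p=main["n_cases"] / main["n_cases"].sum()
    )
    return [truth_record(f"S{i:03d}", g) for i, g in enumerate(genotypes)]
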