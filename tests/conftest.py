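import pytest

from mitoshift import GenomeAnnotation, PairCohortConfig, simulate_pair_cohort
from mitoshift.simulate import make_fixture_vcfs


@pytest.fixture(scope="session")
def ann():
    return GenomeAnnotation.default()


@pytest.fixture(scope="session")
def fixture_vcfs(tmp_path_factory, ann):
    return make_fixture_vcfs(tmp_path_factory.mktemp("fixtures"), ann)


@pytest.fixture(scope="session")
def small_cohort(ann):
    """20 noise-free pairs with truth, shared across tests."""
    return simulate_pair_cohort(
        PairCohortConfig.noise_free(n_pairs=20, seed=11), ann
    )


@pytest.fixture(scope="session")
def noisy_cohort(ann):
    """20 pairs under the full default conditions (artifacts enabled)."""
    return simulate_pair_cohort(PairCohortConfig(n_pairs=20, seed=7), ann)
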