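import pytest

from misexpression.model import MisexpressionModel
from misexpression.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(default_bundle):
    """Fitted misexpression results on the default cohort."""
    b = default_bundle
    return MisexpressionModel(b.tpm, b.covariates, b.genes).fit()


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast cohort for IO/CLI round-trip tests."""
    return simulate_cohort(
        SimulationConfig(
            seed=5, n_samples=60, n_genes=300, n_sv_driven_events=8,
            n_null_rare_svs=60, n_readthrough_loci=2,
        )
    )
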