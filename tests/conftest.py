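import pytest

from csbayes import (
    DirichletContingencyModel,
    McmcSettings,
    OrdinalSeverityModel,
    PriorSpec,
    load_severity_table,
)


@pytest.fixture(scope="session")
def table2():
    return load_severity_table()


@pytest.fixture(scope="session")
def dirichlet_results(table2):
    """Jeffreys-prior posterior draws shared by the contingency checks."""
    return DirichletContingencyModel(table2).fit(n_draws=200_000, seed=101)


@pytest.fixture(scope="session")
def full_schedule():
    """The study's MCMC schedule: 3 chains, 5000 burn-in, 150000 iters, thin 3."""
    return McmcSettings(seed=11)


@pytest.fixture(scope="session")
def vague_fit(table2, full_schedule):
    model = OrdinalSeverityModel.from_table(table2, priors=PriorSpec.vague())
    return model.fit(full_schedule)


@pytest.fixture(scope="session")
def optimistic_fit(table2, full_schedule):
    model = OrdinalSeverityModel.from_table(table2, priors=PriorSpec.optimistic())
    return model.fit(full_schedule)


def short_settings(seed: int, chains: int = 2) -> McmcSettings:
    """Reduced schedule for distributional (non-replication) checks."""
    return McmcSettings(
        n_chains=chains, burn_in=1500, n_iterations=9000, thin=3, seed=seed
    )
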