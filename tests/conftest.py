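import numpy as np
import pytest

from traitshift import MCMCConfig, PopulationTraits, SyntheticConfig, TRAIT_NAMES


@pytest.fixture
def fast_mcmc() -> MCMCConfig:
    """Short chains for unit tests where only qualitative behavior matters."""
    return MCMCConfig(n_chains=3, n_iterations=600, n_burnin=200, seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_record(
    species: str,
    site: int = 1,
    stage: str = "adult",
    phenology: str = "evergreen",
    growth_form: str = "free_standing",
    **trait_values: float,
) -> PopulationTraits:
    traits = {t: None for t in TRAIT_NAMES}
    traits.update(trait_values)
    return PopulationTraits(
        species_id=species,
        site_id=site,
        stage=stage,
        phenology=phenology,
        growth_form=growth_form,
        traits=traits,
    )


@pytest.fixture
def paired_table() -> list[PopulationTraits]:
    """Five populations; three have SLA at both stages, two only at one."""
    rows = []
    sla_adult = {"sp1": 90.0, "sp2": 110.0, "sp3": 150.0, "sp4": 120.0}
    sla_seedling = {"sp1": 180.0, "sp2": 210.0, "sp3": 260.0, "sp5": 240.0}
    for sp, v in sla_adult.items():
        rows.append(make_record(sp, site=1, stage="adult", SLA=v, LDMC=0.4))
    for sp, v in sla_seedling.items():
        rows.append(make_record(sp, site=1, stage="seedling", SLA=v, LDMC=0.35))
    return rows


@pytest.fixture
def small_synth_config() -> SyntheticConfig:
    return SyntheticConfig(n_populations_per_site=30, missing_rate=0.02, seed=7)
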