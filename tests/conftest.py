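import numpy as np
import pytest

from airburden import burden as burden_mod
from airburden import synthetic_data as synth
from airburden.types import AgeGrid, EconomyParams, EmploymentProfile, LifeTable


@pytest.fixture(scope="session")
def grid() -> AgeGrid:
    return AgeGrid()


@pytest.fixture(scope="session")
def panels():
    """Five synthetic state panels (small for speed; 31-state runs live in acceptance tests)."""
    cfg = synth.GeneratorConfig(n_states=5)
    return synth.generate_panel(cfg, seed=11)


@pytest.fixture(scope="session")
def curves():
    return synth.default_risk_curves()


@pytest.fixture(scope="session")
def burden_table(panels, curves):
    return burden_mod.compute_attributable(panels, curves)


@pytest.fixture()
def flat_life_table(grid) -> LifeTable:
    return LifeTable(l=np.full(grid.max_single_year + 1, 100_000.0))


@pytest.fixture()
def full_employment(grid) -> EmploymentProfile:
    """e = 1 everywhere at or above the working-age threshold, 0 below."""
    e = np.array([0.0 if s + w <= 15 else 1.0 for s, w in zip(grid.group_starts, grid.widths)])
    return EmploymentProfile(e=e, age_grid=grid)


@pytest.fixture()
def simple_economy() -> EconomyParams:
    return EconomyParams(
        gdp=1000.0,  # US$ millions
        labour_share=0.5,
        employed_count=100_000.0,
        growth_rate=0.0,
        discount_rate=0.06,
    )
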