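"""Output-based cost-of-illness model.

Premature mortality is valued as the present discounted value of expected
market and non-market output over the remainder of working life, conditioned
on survival; morbidity is valued as one year of expected output per YLD at
the age it occurs. Conventions (see package docs):

* the death year (t = 0) counts as a lost, undiscounted year;
* output per worker grows at rate g from t = 1 (baseline output is y0 exactly);
* deaths in a 5-year group are assigned the group midpoint age;
* losses truncate at ``horizon_age`` (default 65); non-market output (30% of
  market output, for people not working) accrues only within
  [min_working_age, horizon_age).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .types import (
    BurdenTable,
    EconomyParams,
    EmploymentProfile,
    LifeTable,
    LossResult,
    OutputSchedule,
    StatePanel,
)

__all__ = [
    "output_per_worker",
    "expected_output",
    "build_output_schedule",
    "survival_probability",
    "pv_lost_output",
    "pv_schedule",
    "mortality_loss",
    "morbidity_loss",
    "state_loss",
    "compute_losses",
    "losses_to_frame",
    "discount_sensitivity",
]


def output_per_worker(economy: EconomyParams) -> float:
    """Baseline output per worker, US$ per worker-year: labour share × GDP / employed."""
    if economy.employed_count <= 0:
        raise DomainError("output_per_worker: employed_count must be positive")
    return economy.labour_share * economy.gdp * 1e6 / economy.employed_count


def expected_output(
    age: int,
    t: int,
    economy: EconomyParams,
    employment: EmploymentProfile,
) -> float:
    """Expected per-person output at ``age`` in year offset ``t``, US$/person-year.

    Zero outside [min_working_age, horizon_age); otherwise
    y0 (1+g)^t [e(age) + (1 − e(age)) · nonmarket_share].
    """
    if t < 0:
        raise DomainError("expected_output: t must be non-negative")
    if age < economy.min_working_age or age >= economy.horizon_age:
        return 0.0
    y0 = output_per_worker(economy)
    e = employment.rate_at_age(age)
    return y0 * (1.0 + economy.growth_rate) ** t * (e + (1.0 - e) * economy.nonmarket_share)


def build_output_schedule(economy: EconomyParams, employment: EmploymentProfile) -> OutputSchedule:
    """Baseline (t = 0) expected output per single age, as an :class:`OutputSchedule`."""
    max_age = employment.age_grid.max_single_year
    base = np.array(
        [expected_output(a, 0, economy, employment) for a in range(max_age + 1)]
    )
    return OutputSchedule(y0=output_per_worker(economy), per_age_expected=base, growth_rate=economy.growth_rate)


def survival_probability(lt: LifeTable, a: int, t: int) -> float:
    """S(a, a+t) = l(a+t)/l(a)."""
    return lt.survival(a, t)


def pv_lost_output(
    a: int,
    economy: EconomyParams,
    employment: EmploymentProfile,
    lt: LifeTable,
    discount_rate: float | None = None,
) -> float:
    """Present value of expected lost output for a death at age ``a``, US$.

    Σ_{t=0}^{horizon−1−a} S(a, a+t) (1+r)^{−t} · expected_output(a+t, t);
    zero when ``a`` is at or beyond the horizon.
    """
    if a < 0:
        raise DomainError("pv_lost_output: age must be non-negative")
    r = economy.discount_rate if discount_rate is None else discount_rate
    horizon = economy.horizon_age
    if a >= horizon:
        return 0.0
    total = 0.0
    for t in range(horizon - a):
        out = expected_output(a + t, t, economy, employment)
        if out == 0.0:
            continue
        total += survival_probability(lt, a, t) * out / (1.0 + r) ** t
    return total


def pv_schedule(
    panel: StatePanel, discount_rate: float | None = None
) -> dict[int, float]:
    """PV of lost output per age group (keyed by group start), using midpoint ages."""
    out: dict[int, float] = {}
    for start, mid in zip(panel.age_grid.group_starts, panel.age_grid.midpoints):
        out[start] = pv_lost_output(
            mid, panel.economy, panel.employment, panel.life_table, discount_rate
        )
    return out


def _check_single_state_risk(burden_df: pd.DataFrame) -> None:
    if burden_df.empty:
        return
    if burden_df["state_id"].nunique() > 1:
        raise ValidationError("loss computation requires a single state's burden rows")
    if burden_df["risk"].nunique() > 1:
        raise ValidationError("loss computation requires a single risk's burden rows")


def mortality_loss(
    burden_df: pd.DataFrame,
    economy: EconomyParams,
    employment: EmploymentProfile,
    lt: LifeTable,
    age_grid=None,
    discount_rate: float | None = None,
) -> float:
    """Σ_a deaths(a) · PV(midpoint of a), in US$ millions. One state × risk."""
    _check_single_state_risk(burden_df)
    if burden_df.empty:
        return 0.0
    grid = age_grid
    if grid is None:
        grid = employment.age_grid
    mid_by_start = dict(zip(grid.group_starts, grid.midpoints))
    deaths = burden_df.groupby("age_start")["deaths"].sum()
    total = 0.0
    for age_start, d in deaths.items():
        pv = pv_lost_output(mid_by_start[int(age_start)], economy, employment, lt, discount_rate)
        total += d * pv
    return total / 1e6


def morbidity_loss(
    burden_df: pd.DataFrame,
    economy: EconomyParams,
    employment: EmploymentProfile,
    age_grid=None,
) -> float:
    """Σ_a YLD(a) · expected_output(midpoint of a, t = 0), in US$ millions.

    A single undiscounted year per YLD; independent of the discount rate and
    the life table.
    """
    _check_single_state_risk(burden_df)
    if burden_df.empty:
        return 0.0
    grid = age_grid
    if grid is None:
        grid = employment.age_grid
    mid_by_start = dict(zip(grid.group_starts, grid.midpoints))
    ylds = burden_df.groupby("age_start")["yld"].sum()
    total = 0.0
    for age_start, y in ylds.items():
        total += y * expected_output(mid_by_start[int(age_start)], 0, economy, employment)
    return total / 1e6


def state_loss(
    panel: StatePanel,
    burden: BurdenTable,
    risk: str,
    discount_rate: float | None = None,
) -> LossResult:
    """Full loss result for one state × risk."""
    rows = burden.for_state_risk(panel.state_id, risk)
    mort = mortality_loss(
        rows, panel.economy, panel.employment, panel.life_table,
        panel.age_grid, discount_rate,
    )
    morb = morbidity_loss(rows, panel.economy, panel.employment, panel.age_grid)
    total = mort + morb
    return LossResult(
        state_id=panel.state_id,
        risk=risk,
        mortality_loss=mort,
        morbidity_loss=morb,
        pct_gdp=total / panel.economy.gdp * 100.0,
        per_capita=total * 1e6 / panel.total_population,
    )


def compute_losses(
    panels: Sequence[StatePanel],
    burden: BurdenTable,
    risks: Sequence[str] | None = None,
    discount_rate: float | None = None,
) -> list[LossResult]:
    """Loss results for every state × risk present in the burden table."""
    if risks is None:
        risks = sorted(burden.df["risk"].unique())
    return [
        state_loss(panel, burden, risk, discount_rate)
        for panel in panels
        for risk in risks
    ]


def losses_to_frame(results: Sequence[LossResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state_id": [r.state_id for r in results],
            "risk": [r.risk for r in results],
            "mortality_loss": [r.mortality_loss for r in results],
            "morbidity_loss": [r.morbidity_loss for r in results],
            "total_loss": [r.total_loss for r in results],
            "pct_gdp": [r.pct_gdp for r in results],
            "per_capita": [r.per_capita for r in results],
        }
    )


def discount_sensitivity(
    panels: Sequence[StatePanel],
    burden: BurdenTable,
    rates: Sequence[float],
    risks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Recompute all losses at each discount rate.

    Returns the loss frame with a leading ``discount_rate`` column; mortality
    losses are decreasing in the rate, morbidity losses invariant.
    """
    if len(rates) == 0:
        raise ValidationError("discount_sensitivity: empty rate list")
    for r in rates:
        if not 0 < r < 1:
            raise DomainError(f"discount rate must lie in (0, 1), got {r}")
    frames = []
    for r in rates:
        frame = losses_to_frame(compute_losses(panels, burden, risks, discount_rate=r))
        frame.insert(0, "discount_rate", r)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
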