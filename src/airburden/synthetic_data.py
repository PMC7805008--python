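"""Seeded synthetic state panels with the structure the analysis assumes.

The generator produces ~31 geographic units with 5-year age groups 0-95+,
three risk components and eight causes. All-risk cause envelopes are drawn
first and attributable burden is then obtained by applying known PAFs, so the
burden stage's PAF recovery is exact by construction.

Per-state randomness comes from substreams derived by stable hashing of
(seed, state_id): adding a state never perturbs the others.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from . import burden as burden_mod
from .errors import ConfigurationError, DomainError
from .types import (
    CAUSES,
    AgeGrid,
    BurdenTable,
    EconomyParams,
    EmploymentProfile,
    ExposureSummary,
    LifeTable,
    RiskCurve,
    StatePanel,
)

#: (risk, cause) pairs for which default risk curves are generated.
RISK_CAUSE_PAIRS: tuple[tuple[str, str], ...] = (
    ("ambient_pm", "copd"),
    ("ambient_pm", "lri"),
    ("ambient_pm", "lung_cancer"),
    ("ambient_pm", "ihd"),
    ("ambient_pm", "stroke"),
    ("ambient_pm", "diabetes"),
    ("ambient_pm", "neonatal"),
    ("hap", "copd"),
    ("hap", "lri"),
    ("hap", "lung_cancer"),
    ("hap", "ihd"),
    ("hap", "stroke"),
    ("hap", "diabetes"),
    ("hap", "neonatal"),
    ("hap", "cataract"),
    ("ozone", "copd"),
)

# smooth unimodal age profiles per cause: (mean age, sd); an assumption of the
# generator, not an empirical pattern
_CAUSE_AGE_PROFILE: dict[str, tuple[float, float]] = {
    "copd": (72.0, 12.0),
    "lri": (40.0, 35.0),
    "lung_cancer": (68.0, 10.0),
    "ihd": (67.0, 13.0),
    "stroke": (70.0, 12.0),
    "diabetes": (65.0, 12.0),
    "neonatal": (0.0, 1.0),
    "cataract": (75.0, 8.0),
}

# crude death rate per 100k drawn log-uniformly within these bounds, per cause
_CAUSE_RATE_RANGE: dict[str, tuple[float, float]] = {
    "copd": (40.0, 120.0),
    "lri": (20.0, 90.0),
    "lung_cancer": (4.0, 15.0),
    "ihd": (80.0, 200.0),
    "stroke": (40.0, 120.0),
    "diabetes": (15.0, 50.0),
    "neonatal": (10.0, 60.0),
    "cataract": (0.05, 0.5),
}

# ratio of YLD to YLL per cause (cataract is almost pure disability)
_CAUSE_YLD_RATIO: dict[str, tuple[float, float]] = {
    "copd": (0.3, 0.8),
    "lri": (0.02, 0.1),
    "lung_cancer": (0.01, 0.05),
    "ihd": (0.05, 0.15),
    "stroke": (0.15, 0.5),
    "diabetes": (1.0, 3.0),
    "neonatal": (0.1, 0.4),
    "cataract": (50.0, 200.0),
}


class Range(BaseModel):
    """Closed interval used for uniform / log-uniform draws."""

    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "Range":
        if not self.low <= self.high:
            raise ValueError(f"range low {self.low} must not exceed high {self.high}")
        return self


class GeneratorConfig(BaseModel):
    """Settings for :func:`generate_panel`; all ranges live here, not in code."""

    n_states: int = 31
    state_prefix: str = "state"
    total_population: Range = Range(low=2e6, high=2.2e8)  # log-uniform
    gdp_per_capita: Range = Range(low=600.0, high=5500.0)  # US$/person, log-uniform
    labour_share: Range = Range(low=0.4, high=0.6)
    growth_rate: Range = Range(low=0.03, high=0.07)
    survival_to_65: Range = Range(low=0.70, high=0.92)  # target l(65)/l(0)
    employment_peak: Range = Range(low=0.45, high=0.80)
    pm25_mean: Range = Range(low=15.0, high=220.0)  # μg/m³, log-uniform
    solid_fuel_prop: Range = Range(low=0.05, high=0.90)
    ozone_ppb: Range = Range(low=45.0, high=80.0)
    discount_rate: float = 0.06
    nonmarket_share: float = 0.30
    min_working_age: int = 15
    horizon_age: int = 65

    @field_validator("n_states")
    @classmethod
    def _positive_states(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("n_states must be positive")
        return v

    @field_validator("discount_rate", "nonmarket_share")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError("rates must lie in [0, 1]")
        return v


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label RNG derived by stable hashing of (seed, label)."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _log_uniform(rng: np.random.Generator, r: Range) -> float:
    if r.low <= 0:
        raise ConfigurationError("log-uniform range requires positive bounds")
    return float(np.exp(rng.uniform(np.log(r.low), np.log(r.high))))


def _uniform(rng: np.random.Generator, r: Range) -> float:
    return float(rng.uniform(r.low, r.high))


def generate_life_table(target_l65_over_l0: float, seed: int, grid: AgeGrid | None = None) -> LifeTable:
    """Random monotone survivorship hitting l(65)/l(0) = target exactly at the anchor.

    A random positive hazard increment is drawn per age group and the
    cumulative hazard to age 65 is rescaled so the abridged anchor at 65
    matches the target; single years are linear between anchors.
    """
    if not 0 < target_l65_over_l0 < 1:
        raise DomainError(
            f"target l(65)/l(0) must lie in (0, 1), got {target_l65_over_l0}"
        )
    grid = grid or AgeGrid()
    rng = substream(seed, "life_table")
    anchor_ages = np.array(list(grid.group_starts) + [grid.max_single_year], dtype=float)
    # child-mortality bump then rising late-life hazard
    shape = 0.04 + 0.1 * np.exp(-anchor_ages[:-1] / 4.0) + 0.002 * np.exp(anchor_ages[:-1] / 14.0)
    increments = shape * rng.uniform(0.5, 1.5, size=shape.size) * np.diff(anchor_ages)
    cum = np.concatenate(([0.0], np.cumsum(increments)))
    i65 = int(np.where(anchor_ages == 65)[0][0])
    if cum[i65] <= 0:
        raise ConfigurationError("degenerate hazard draw")
    scale = -np.log(target_l65_over_l0) / cum[i65]
    l_anchor = 100_000.0 * np.exp(-scale * cum)
    return LifeTable.from_abridged(anchor_ages.astype(int), l_anchor, max_age=grid.max_single_year)


def _employment_profile(rng: np.random.Generator, cfg: GeneratorConfig, grid: AgeGrid) -> EmploymentProfile:
    peak = _uniform(rng, cfg.employment_peak)
    mids = np.asarray(grid.midpoints, dtype=float)
    e = np.zeros(grid.n_groups)
    for i, (start, width, mid) in enumerate(zip(grid.group_starts, grid.widths, mids)):
        if start + width <= cfg.min_working_age:
            continue
        # bell-shaped participation over the working life, tailing off in old age
        e[i] = peak * np.exp(-((mid - 40.0) ** 2) / (2 * 18.0**2))
    e *= rng.uniform(0.92, 1.08, size=e.size)
    return EmploymentProfile(e=np.clip(e, 0.0, 1.0), age_grid=grid)


def _population(rng: np.random.Generator, cfg: GeneratorConfig, grid: AgeGrid) -> np.ndarray:
    total = _log_uniform(rng, cfg.total_population)
    mids = np.asarray(grid.midpoints, dtype=float)
    weights = np.exp(-0.028 * mids) * rng.uniform(0.85, 1.15, size=mids.size)
    weights /= weights.sum()
    return total * weights


def _cause_envelopes(
    rng: np.random.Generator, population: np.ndarray, grid: AgeGrid
) -> pd.DataFrame:
    mids = np.asarray(grid.midpoints, dtype=float)
    records = []
    for cause in CAUSES:
        mean_age, sd = _CAUSE_AGE_PROFILE[cause]
        lo, hi = _CAUSE_RATE_RANGE[cause]
        rate = np.exp(rng.uniform(np.log(lo), np.log(hi)))  # per 100k, all ages
        profile = np.exp(-((mids - mean_age) ** 2) / (2 * sd**2))
        if cause == "neonatal":
            profile = np.zeros_like(mids)
            profile[0] = 1.0
        raw = population * profile
        if raw.sum() <= 0:
            deaths = np.zeros_like(mids)
        else:
            deaths = raw / raw.sum() * rate / 100_000.0 * population.sum()
        deaths = np.minimum(deaths, 0.5 * population)  # envelope never exhausts an age group
        yll = deaths * np.maximum(86.6 - mids, 1.0)
        ylo, yhi = _CAUSE_YLD_RATIO[cause]
        yld = yll * np.exp(rng.uniform(np.log(ylo), np.log(yhi)))
        for i, start in enumerate(grid.group_starts):
            records.append(
                {
                    "age_start": start,
                    "cause": cause,
                    "deaths": deaths[i],
                    "yll": yll[i],
                    "yld": yld[i],
                }
            )
    return pd.DataFrame.from_records(records)


def _generate_one(state_id: str, cfg: GeneratorConfig, seed: int, grid: AgeGrid) -> StatePanel:
    rng = substream(seed, state_id)
    population = _population(rng, cfg, grid)
    life_table = generate_life_table(
        _uniform(rng, cfg.survival_to_65), seed=int(rng.integers(0, 2**31)), grid=grid
    )
    employment = _employment_profile(rng, cfg, grid)
    gdp_pc = _log_uniform(rng, cfg.gdp_per_capita)
    employed = float(np.dot(population, employment.e))
    economy = EconomyParams(
        gdp=gdp_pc * population.sum() / 1e6,  # US$ millions
        labour_share=_uniform(rng, cfg.labour_share),
        employed_count=max(employed, 1.0),
        growth_rate=_uniform(rng, cfg.growth_rate),
        discount_rate=cfg.discount_rate,
        nonmarket_share=cfg.nonmarket_share,
        min_working_age=cfg.min_working_age,
        horizon_age=cfg.horizon_age,
    )
    exposure = ExposureSummary(
        pm25_mean=_log_uniform(rng, cfg.pm25_mean),
        solid_fuel_prop=_uniform(rng, cfg.solid_fuel_prop),
        ozone_ppb=_uniform(rng, cfg.ozone_ppb),
    )
    envelopes = _cause_envelopes(rng, population, grid)
    return StatePanel(
        state_id=state_id,
        population=population,
        life_table=life_table,
        employment=employment,
        economy=economy,
        exposure=exposure,
        cause_envelopes=envelopes,
        age_grid=grid,
    )


def generate_panel(config: GeneratorConfig | None = None, seed: int = 0) -> list[StatePanel]:
    """Generate ``config.n_states`` validated state panels.

    Identical (config, seed) gives bit-identical panels; each state uses an
    independent substream keyed on its id.
    """
    cfg = config or GeneratorConfig()
    if not isinstance(seed, (int, np.integer)):
        raise ConfigurationError(f"seed must be an integer, got {seed!r}")
    grid = AgeGrid()
    ids = [f"{cfg.state_prefix}_{i:02d}" for i in range(1, cfg.n_states + 1)]
    return [_generate_one(sid, cfg, int(seed), grid) for sid in ids]


def default_risk_curves() -> list[RiskCurve]:
    """Fixed exposure-response inputs for the default risk-cause pairs.

    Continuous curves for ambient PM2.5 and ozone (piecewise linear above a
    TMREL), categorical RRs for household solid-fuel use. Values are plausible
    magnitudes for testing, not fitted estimates.
    """
    pm_knots = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 150.0, 250.0])
    pm_peak_rr = {
        "copd": 1.9,
        "lri": 2.1,
        "lung_cancer": 1.7,
        "ihd": 1.6,
        "stroke": 1.5,
        "diabetes": 1.4,
        "neonatal": 1.5,
    }
    hap_rr = {
        "copd": 2.3,
        "lri": 2.1,
        "lung_cancer": 1.6,
        "ihd": 1.5,
        "stroke": 1.4,
        "diabetes": 1.3,
        "neonatal": 1.45,
        "cataract": 1.55,
    }
    curves: list[RiskCurve] = []
    for risk, cause in RISK_CAUSE_PAIRS:
        if risk == "ambient_pm":
            peak = pm_peak_rr[cause]
            # concave rise from RR=1 at the TMREL to the plateau value
            frac = np.sqrt((pm_knots - pm_knots[0]) / (pm_knots[-1] - pm_knots[0]))
            rrs = 1.0 + (peak - 1.0) * frac
            curves.append(
                RiskCurve(
                    risk=risk, cause=cause, kind="continuous",
                    exposures=pm_knots, rrs=rrs, tmrel=pm_knots[0],
                )
            )
        elif risk == "hap":
            curves.append(
                RiskCurve(risk=risk, cause=cause, kind="categorical", rr_exposed=hap_rr[cause])
            )
        else:  # ozone / copd
            oz_knots = np.array([33.0, 45.0, 60.0, 80.0, 100.0])
            oz_rrs = np.array([1.0, 1.05, 1.12, 1.20, 1.25])
            curves.append(
                RiskCurve(
                    risk=risk, cause=cause, kind="continuous",
                    exposures=oz_knots, rrs=oz_rrs, tmrel=33.0,
                )
            )
    return curves


def generate_burden(
    panel: StatePanel,
    curves: list[RiskCurve],
    seed: int = 0,
    pairs: tuple[tuple[str, str], ...] = RISK_CAUSE_PAIRS,
    include_parent: bool = True,
) -> BurdenTable:
    """Attributable burden for one panel by applying known PAFs to its envelopes.

    The PAFs come from the same CRA formulas the analysis stage implements, so
    recovery there is exact. ``pairs`` lists the (risk, cause) cells to
    generate; every pair must have a curve. ``seed`` is accepted for interface
    symmetry; the PAF application itself is deterministic.
    """
    by_pair = {(c.risk, c.cause): c for c in curves}
    missing = [p for p in pairs if p not in by_pair]
    if missing:
        raise ConfigurationError(f"generate_burden: no risk curve for pairs {missing}")
    selected = [by_pair[p] for p in pairs]
    return burden_mod.compute_attributable([panel], selected, include_parent=include_parent)
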