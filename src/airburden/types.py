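"""Core domain types for the state-level burden and cost-of-illness pipeline.

All numeric containers are plain numpy arrays / pandas frames; every type
exposes a ``validate()`` method that raises :class:`~airburden.errors.ValidationError`
naming the offending field, and is called by constructors and by the IO layer
at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

#: Causes handled by the pipeline (labels used in every table).
CAUSES = (
    "copd",
    "lri",
    "lung_cancer",
    "ihd",
    "stroke",
    "diabetes",
    "neonatal",
    "cataract",
)

#: Component risks plus the parent aggregate.
RISKS = ("ambient_pm", "hap", "ozone")
PARENT_RISK = "air_pollution"

BURDEN_COLUMNS = ("state_id", "age_start", "cause", "risk", "deaths", "yll", "yld", "daly")


@dataclass(frozen=True)
class AgeGrid:
    """Five-year age groups 0-4 … 90-94 plus an open terminal group (95+)."""

    group_starts: tuple[int, ...] = tuple(range(0, 100, 5))
    terminal_open: bool = True
    max_single_year: int = 100

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        starts = self.group_starts
        if len(starts) < 2:
            raise ValidationError("AgeGrid.group_starts: need at least two groups")
        if starts[0] != 0:
            raise ValidationError("AgeGrid.group_starts: first start must be 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValidationError("AgeGrid.group_starts: must be strictly increasing")

    @property
    def n_groups(self) -> int:
        return len(self.group_starts)

    @property
    def widths(self) -> tuple[int, ...]:
        w = [b - a for a, b in zip(self.group_starts, self.group_starts[1:])]
        w.append(self.max_single_year - self.group_starts[-1])
        return tuple(w)

    @property
    def midpoints(self) -> tuple[int, ...]:
        """Representative single age per group: start + 2 for 5-year groups
        (62 for 60-64), start + half-width otherwise."""
        return tuple(s + w // 2 for s, w in zip(self.group_starts, self.widths))

    @property
    def labels(self) -> tuple[str, ...]:
        out = [f"{a}-{b - 1}" for a, b in zip(self.group_starts, self.group_starts[1:])]
        out.append(f"{self.group_starts[-1]}+" if self.terminal_open else f"{self.group_starts[-1]}-{self.max_single_year}")
        return tuple(out)

    @property
    def single_years(self) -> np.ndarray:
        return np.arange(self.max_single_year + 1)

    def group_index(self, age: float) -> int:
        """Index of the group containing ``age``."""
        if age < 0:
            raise DomainError(f"age must be non-negative, got {age}")
        return int(np.searchsorted(self.group_starts, age, side="right") - 1)


DEFAULT_AGE_GRID = AgeGrid()


@dataclass
class LifeTable:
    """Single-year survivorship l(x) for x = 0..max age, radix-scaled.

    ``source_abridged`` keeps the abridged anchors (at age-group starts) the
    single-year column was interpolated from, when applicable.
    """

    l: np.ndarray
    source_abridged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        if self.source_abridged is not None:
            self.source_abridged = np.asarray(self.source_abridged, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.l.ndim != 1 or self.l.size < 2:
            raise ValidationError("LifeTable.l: need a 1-d array of at least two ages")
        if not self.l[0] > 0:
            raise ValidationError("LifeTable.l: l(0) must be positive")
        if np.any(self.l < 0):
            raise ValidationError("LifeTable.l: survivorship must be non-negative")
        if np.any(np.diff(self.l) > 1e-9 * self.l[0]):
            raise ValidationError("LifeTable.l: survivorship must be non-increasing in age")

    @classmethod
    def from_abridged(cls, anchor_ages: Sequence[int], anchor_l: Sequence[float], max_age: int = 100) -> "LifeTable":
        """Linear interpolation of abridged survivorship to single years.

        Beyond the last anchor the last segment's slope is continued, clipped
        at zero.
        """
        ages = np.asarray(anchor_ages, dtype=float)
        lx = np.asarray(anchor_l, dtype=float)
        if ages.size != lx.size or ages.size < 2:
            raise ValidationError("LifeTable.from_abridged: anchors must be paired, >=2 points")
        single = np.interp(np.arange(max_age + 1), ages, lx)
        if ages[-1] < max_age:
            slope = (lx[-1] - lx[-2]) / (ages[-1] - ages[-2])
            tail = np.arange(int(ages[-1]) + 1, max_age + 1)
            single[tail] = np.maximum(lx[-1] + slope * (tail - ages[-1]), 0.0)
        single = np.minimum.accumulate(single)
        return cls(l=single, source_abridged=lx)

    def survival(self, a: int, t: int) -> float:
        """Conditional survival S(a, a+t) = l(a+t)/l(a)."""
        if a < 0 or t < 0:
            raise DomainError("survival: a and t must be non-negative")
        la = self.l[min(a, self.l.size - 1)]
        if la <= 0:
            raise DomainError(f"survival: l({a}) = 0, conditional survival undefined")
        lat = self.l[min(a + t, self.l.size - 1)]
        return float(lat / la)


@dataclass
class EmploymentProfile:
    """Fraction of people working, by age group on a fixed grid."""

    e: np.ndarray
    age_grid: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.validate()

    def validate(self, min_working_age: int | None = None) -> None:
        if self.e.size != self.age_grid.n_groups:
            raise ValidationError(
                f"EmploymentProfile.e: expected {self.age_grid.n_groups} groups, got {self.e.size}"
            )
        if np.any((self.e < 0) | (self.e > 1)):
            raise ValidationError("EmploymentProfile.e: fractions must lie in [0, 1]")
        if min_working_age is not None:
            for i, start in enumerate(self.age_grid.group_starts):
                width = self.age_grid.widths[i]
                if start + width <= min_working_age and self.e[i] != 0:
                    raise ValidationError(
                        f"EmploymentProfile.e: group starting {start} is below the "
                        f"minimum working age {min_working_age} but has e={self.e[i]}"
                    )

    def rate_at_age(self, age: float) -> float:
        return float(self.e[self.age_grid.group_index(age)])


@dataclass
class EconomyParams:
    """State economy block: output, growth and valuation parameters.

    ``gdp`` is in US$ millions per year; monetary results downstream keep that
    unit.
    """

    gdp: float
    labour_share: float
    employed_count: float
    growth_rate: float
    discount_rate: float = 0.06
    nonmarket_share: float = 0.30
    min_working_age: int = 15
    horizon_age: int = 65

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.gdp > 0:
            raise ValidationError("EconomyParams.gdp: must be positive")
        if not 0 < self.labour_share < 1:
            raise ValidationError("EconomyParams.labour_share: must lie in (0, 1)")
        if not self.employed_count > 0:
            raise ValidationError("EconomyParams.employed_count: must be positive")
        if not 0 <= self.nonmarket_share <= 1:
            raise ValidationError("EconomyParams.nonmarket_share: must lie in [0, 1]")
        if not self.min_working_age < self.horizon_age:
            raise ValidationError("EconomyParams: min_working_age must be below horizon_age")

    def with_rate(self, r: float) -> "EconomyParams":
        return replace(self, discount_rate=r)


@dataclass
class ExposureSummary:
    """Population-level exposure summaries for the three risk components."""

    pm25_mean: float  # μg/m³
    solid_fuel_prop: float  # fraction of population cooking with solid fuels
    ozone_ppb: float  # seasonal 8 h daily-max average

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pm25_mean < 0:
            raise ValidationError("ExposureSummary.pm25_mean: must be non-negative")
        if not 0 <= self.solid_fuel_prop <= 1:
            raise ValidationError("ExposureSummary.solid_fuel_prop: must lie in [0, 1]")
        if self.ozone_ppb < 0:
            raise ValidationError("ExposureSummary.ozone_ppb: must be non-negative")


@dataclass
class StatePanel:
    """One geographic unit's complete model inputs."""

    state_id: str
    population: np.ndarray  # persons per age group
    life_table: LifeTable
    employment: EmploymentProfile
    economy: EconomyParams
    exposure: ExposureSummary
    cause_envelopes: pd.DataFrame  # columns: age_start, cause, deaths, yll, yld
    age_grid: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.state_id:
            raise ValidationError("StatePanel.state_id: must be non-empty")
        if self.population.size != self.age_grid.n_groups:
            raise ValidationError(
                f"StatePanel.population [{self.state_id}]: expected "
                f"{self.age_grid.n_groups} age groups, got {self.population.size}"
            )
        if np.any(self.population < 0):
            raise ValidationError(f"StatePanel.population [{self.state_id}]: negative entries")
        env = self.cause_envelopes
        required = {"age_start", "cause", "deaths", "yll", "yld"}
        missing = required - set(env.columns)
        if missing:
            raise ValidationError(
                f"StatePanel.cause_envelopes [{self.state_id}]: missing columns {sorted(missing)}"
            )
        for col in ("deaths", "yll", "yld"):
            if (env[col] < 0).any():
                raise ValidationError(
                    f"StatePanel.cause_envelopes [{self.state_id}]: negative {col}"
                )
        pop_by_age = dict(zip(self.age_grid.group_starts, self.population))
        deaths_by_age = env.groupby("age_start")["deaths"].sum()
        for age_start, deaths in deaths_by_age.items():
            if deaths > pop_by_age.get(int(age_start), 0.0) * (1 + 1e-9):
                raise ValidationError(
                    f"StatePanel.cause_envelopes [{self.state_id}]: deaths at age "
                    f"{age_start} exceed population"
                )
        self.employment.validate(min_working_age=self.economy.min_working_age)

    @property
    def total_population(self) -> float:
        return float(self.population.sum())


@dataclass
class RiskCurve:
    """Exposure → relative-risk mapping for one (risk, cause) pair.

    ``continuous`` curves carry piecewise-linear knots above a TMREL;
    ``categorical`` curves carry a single RR for the exposed category.
    """

    risk: str
    cause: str
    kind: str  # "continuous" | "categorical"
    exposures: np.ndarray | None = None
    rrs: np.ndarray | None = None
    tmrel: float | None = None
    rr_exposed: float | None = None

    def __post_init__(self) -> None:
        if self.exposures is not None:
            self.exposures = np.asarray(self.exposures, dtype=float)
        if self.rrs is not None:
            self.rrs = np.asarray(self.rrs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValidationError(f"RiskCurve.kind: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if self.rr_exposed is None or self.rr_exposed < 1:
                raise ValidationError("RiskCurve.rr_exposed: must be >= 1 for categorical curves")
            return
        if self.exposures is None or self.rrs is None or self.tmrel is None:
            raise ValidationError("RiskCurve: continuous curves need exposures, rrs and tmrel")
        if self.exposures.size != self.rrs.size or self.exposures.size == 0:
            raise ValidationError("RiskCurve: exposures and rrs must be paired and non-empty")
        if np.any(np.diff(self.exposures) <= 0):
            raise ValidationError("RiskCurve.exposures: knots must be strictly increasing")
        if np.any(self.rrs < 1):
            raise ValidationError("RiskCurve.rrs: RR must be >= 1 at and above the TMREL")
        if np.any(self.exposures < self.tmrel):
            raise ValidationError("RiskCurve.exposures: knots must lie at or above the TMREL")


@dataclass
class BurdenTable:
    """Long-format attributable burden: state × age group × cause × risk."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(BURDEN_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"BurdenTable: missing columns {sorted(missing)}")
        for col in ("deaths", "yll", "yld", "daly"):
            if (self.df[col] < 0).any():
                raise ValidationError(f"BurdenTable: negative {col}")
        total = self.df["yll"] + self.df["yld"]
        scale = np.maximum(total.abs(), 1.0)
        if ((self.df["daly"] - total).abs() > 1e-9 * scale).any():
            raise ValidationError("BurdenTable: daly != yll + yld")

    def for_state_risk(self, state_id: str, risk: str) -> pd.DataFrame:
        mask = (self.df["state_id"] == state_id) & (self.df["risk"] == risk)
        return self.df.loc[mask]


@dataclass
class OutputSchedule:
    """Expected per-person output by single age at baseline (t = 0).

    ``expected(age, t)`` applies the growth factor (1+g)^t; the age pattern
    itself is held fixed at baseline.
    """

    y0: float  # US$ per worker-year
    per_age_expected: np.ndarray  # US$ per person-year at t = 0, index = single age
    growth_rate: float

    def __post_init__(self) -> None:
        self.per_age_expected = np.asarray(self.per_age_expected, dtype=float)
        if not self.y0 > 0:
            raise ValidationError("OutputSchedule.y0: must be positive")
        if np.any(self.per_age_expected < 0):
            raise ValidationError("OutputSchedule.per_age_expected: must be non-negative")

    def expected(self, age: int, t: int) -> float:
        if t < 0:
            raise DomainError("OutputSchedule.expected: t must be non-negative")
        if age >= self.per_age_expected.size:
            return 0.0
        return float(self.per_age_expected[age] * (1.0 + self.growth_rate) ** t)


@dataclass
class LossResult:
    """Economic loss for one state × risk, in US$ millions."""

    state_id: str
    risk: str
    mortality_loss: float
    morbidity_loss: float
    pct_gdp: float
    per_capita: float

    def __post_init__(self) -> None:
        self.validate()

    @property
    def total_loss(self) -> float:
        return self.mortality_loss + self.morbidity_loss

    def validate(self) -> None:
        if self.mortality_loss < 0 or self.morbidity_loss < 0:
            raise ValidationError(f"LossResult [{self.state_id}/{self.risk}]: negative loss")


@dataclass
class DrawSet:
    """Named quantity with values from repeated pipeline runs under input perturbation."""

    name: str
    draws: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.draws.size < 2:
            raise ValidationError("DrawSet.draws: need at least 2 draws")
        if not np.all(np.isfinite(self.draws)):
            raise ValidationError("DrawSet.draws: values must be finite")
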