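"""National aggregation, headline ratios/shares, simplified draw propagation,
and arithmetic consistency checks against the published summary tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .errors import DomainError, ValidationError
from .rounding import round_half_up
from .types import DrawSet, LossResult

__all__ = [
    "aggregate_national",
    "share_of_total",
    "extremes_ratio",
    "pct_of_gdp",
    "per_capita",
    "cause_decomposition",
    "uncertainty_interval",
    "propagate_draws",
    "Check",
    "VerificationReport",
    "verify_reference_arithmetic",
]

NATIONAL_ID = "national"


def aggregate_national(
    results: Sequence[LossResult],
    gdp_by_state: Mapping[str, float],
    population_by_state: Mapping[str, float],
) -> LossResult:
    """Sum state losses for one risk; %-of-GDP and per-capita recomputed against
    the summed GDP and population."""
    if not results:
        raise ValidationError("aggregate_national: no state results")
    ids = [r.state_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValidationError("aggregate_national: duplicate state ids")
    risks = {r.risk for r in results}
    if len(risks) != 1:
        raise ValidationError(f"aggregate_national: mixed risks {sorted(risks)}")
    mort = sum(r.mortality_loss for r in results)
    morb = sum(r.morbidity_loss for r in results)
    gdp = sum(gdp_by_state[i] for i in ids)
    pop = sum(population_by_state[i] for i in ids)
    total = mort + morb
    return LossResult(
        state_id=NATIONAL_ID,
        risk=risks.pop(),
        mortality_loss=mort,
        morbidity_loss=morb,
        pct_gdp=pct_of_gdp(total, gdp),
        per_capita=per_capita(total, pop),
    )


def share_of_total(part: float, whole: float) -> float:
    """part / whole × 100."""
    if whole <= 0:
        raise DomainError(f"share_of_total: whole must be positive, got {whole}")
    return part / whole * 100.0


def extremes_ratio(values: Iterable[float]) -> float:
    """max / min over a collection of positive values."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise DomainError("extremes_ratio: need at least 2 values")
    if any(v <= 0 for v in vals):
        raise DomainError("extremes_ratio: all values must be positive")
    return max(vals) / min(vals)


def pct_of_gdp(loss_musd: float, gdp_musd: float) -> float:
    """loss / GDP × 100, both in US$ millions."""
    if gdp_musd <= 0:
        raise DomainError(f"pct_of_gdp: gdp must be positive, got {gdp_musd}")
    return loss_musd / gdp_musd * 100.0


def per_capita(loss_musd: float, population: float) -> float:
    """Loss in US$ per person, from US$ millions and persons."""
    if population <= 0:
        raise DomainError(f"per_capita: population must be positive, got {population}")
    return loss_musd * 1e6 / population


def cause_decomposition(
    by_cause: Mapping[str, float],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Per-cause percentage shares (summing to 100), plus optional grouped shares.

    Group shares are sums of their members' shares and are returned under the
    group name alongside the individual causes.
    """
    values = {k: float(v) for k, v in by_cause.items()}
    if any(v < 0 for v in values.values()):
        raise DomainError("cause_decomposition: negative by-cause value")
    total = sum(values.values())
    if total <= 0:
        raise DomainError("cause_decomposition: zero total")
    shares = {k: v / total * 100.0 for k, v in values.items()}
    if groups:
        for name, members in groups.items():
            shares[name] = sum(shares[m] for m in members)
    return shares


def uncertainty_interval(draws: DrawSet, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval: ((1−level)/2, 1−(1−level)/2) quantiles,
    linear interpolation."""
    if not 0 < level < 1:
        raise DomainError(f"uncertainty_interval: level must lie in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws.draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def propagate_draws(
    pipeline: Callable[[np.random.Generator], float],
    n_draws: int,
    seed: int,
    name: str = "quantity",
) -> DrawSet:
    """Simplified uncertainty propagation: rerun a pipeline under perturbed
    inputs.

    ``pipeline`` receives a per-draw RNG and returns the scalar of interest.
    This is an explicitly simplified stand-in for draw-level burden machinery
    and makes no claim of equivalence to published intervals.
    """
    if n_draws < 2:
        raise ValidationError("propagate_draws: need at least 2 draws")
    root = np.random.default_rng(seed)
    children = root.spawn(n_draws)
    draws = np.array([pipeline(rng) for rng in children], dtype=float)
    return DrawSet(name=name, draws=draws, seed=seed)


@dataclass
class Check:
    check_id: str
    computed: float
    printed: float
    ndigits: int
    tolerance: float = 0.0  # extra slack beyond printed rounding, in output units
    n: int = 2  # number of printed inputs entering the computation

    @property
    def passed(self) -> bool:
        if self.tolerance:
            return abs(self.computed - self.printed) <= self.tolerance
        return round_half_up(self.computed, self.ndigits) == self.printed


@dataclass
class VerificationReport:
    checks: list[Check]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "check_id": [c.check_id for c in self.checks],
                "computed": [c.computed for c in self.checks],
                "printed": [c.printed for c in self.checks],
                "rounded": [round_half_up(c.computed, c.ndigits) for c in self.checks],
                "passed": [c.passed for c in self.checks],
            }
        )


def verify_reference_arithmetic() -> VerificationReport:
    """Recompute the internally checkable identities of the published summary
    from their printed inputs and compare at printed precision.

    Derived constants (national GDP, state populations) are back-solved from
    printed pairs at run time.
    """
    ref = reference
    checks: list[Check] = []

    for risk, label in (
        ("air_pollution", "deaths_air_pollution_share_pct"),
        ("ambient_pm", "deaths_ambient_pm_share_pct"),
        ("hap", "deaths_household_share_pct"),
        ("ozone", "deaths_ozone_share_pct"),
    ):
        checks.append(
            Check(
                label,
                share_of_total(ref.DEATHS_MILLIONS[risk], ref.TOTAL_DEATHS_MILLIONS),
                ref.DEATH_SHARE_PCT[risk],
                ndigits=1,
            )
        )
    checks.append(
        Check(
            "dalys_household_share_pct",
            share_of_total(ref.DALYS_MILLIONS["hap"], ref.TOTAL_DALYS_MILLIONS),
            ref.DALY_SHARE_PCT["hap"],
            ndigits=1,
        )
    )
    checks.append(
        Check(
            "total_loss_musd",
            ref.MORTALITY_LOSS_MUSD + ref.MORBIDITY_LOSS_MUSD,
            ref.TOTAL_LOSS_MUSD,
            ndigits=0,
        )
    )
    state_total = sum(row[3] for row in ref.STATE_LOSS_TABLE)
    n_states = len(ref.STATE_LOSS_TABLE)
    checks.append(
        Check(
            "state_loss_sum_musd",
            state_total,
            ref.TOTAL_LOSS_MUSD,
            ndigits=0,
            tolerance=0.5 * n_states,  # per-state rounding band
            n=n_states,
        )
    )
    gdp = ref.implied_national_gdp_musd()
    checks.append(
        Check(
            "total_loss_pct_gdp",
            pct_of_gdp(state_total, gdp),
            ref.TOTAL_LOSS_PCT_GDP,
            ndigits=2,
            n=n_states + 2,
        )
    )
    pops = ref.implied_state_populations()
    checks.append(
        Check(
            "per_capita_loss_usd",
            per_capita(state_total, sum(pops.values())),
            ref.PER_CAPITA_LOSS_USD,
            ndigits=1,
            tolerance=0.1,  # state-level rounding propagates into implied populations
            n=n_states,
        )
    )
    checks.append(
        Check(
            "healthcare_cost_busd",
            ref.HEALTHCARE_TOTAL_BUSD * ref.AIR_POLLUTION_DALY_FRACTION,
            ref.HEALTHCARE_ATTRIB_BUSD,
            ndigits=1,
        )
    )
    lung = (
        ref.DALY_CAUSE_SHARE_PCT["copd"]
        + ref.DALY_CAUSE_SHARE_PCT["lri"]
        + ref.DALY_CAUSE_SHARE_PCT["lung_cancer"]
    )
    checks.append(
        Check("lung_disease_daly_share_pct", lung, ref.LUNG_DISEASE_DALY_SHARE_PCT, ndigits=1, n=3)
    )
    checks.append(
        Check(
            "loss_cause_shares_sum_pct",
            sum(ref.LOSS_CAUSE_SHARE_PCT.values()),
            100.0,
            ndigits=1,
            n=len(ref.LOSS_CAUSE_SHARE_PCT),
        )
    )
    checks.append(
        Check(
            "pct_gdp_extremes_ratio",
            extremes_ratio([ref.PCT_GDP_STATE_MIN, ref.PCT_GDP_STATE_MAX]),
            ref.PCT_GDP_EXTREMES_RATIO,
            ndigits=1,
        )
    )
    checks.append(
        Check(
            "pm25_exposure_extremes_ratio",
            extremes_ratio([ref.PM25_STATE_MIN, ref.PM25_STATE_MAX]),
            ref.PM25_EXTREMES_RATIO,
            ndigits=1,
        )
    )
    checks.append(
        Check(
            "per_capita_loss_extremes_ratio",
            extremes_ratio([ref.PER_CAPITA_STATE_MIN, ref.PER_CAPITA_STATE_MAX]),
            ref.PER_CAPITA_EXTREMES_RATIO,
            ndigits=1,
        )
    )
    checks.append(
        Check(
            "hap_daly_gdp_correlation_r2",
            ref.HAP_DALY_GDP_CORRELATION_R**2,
            ref.HAP_DALY_GDP_CORRELATION_R2,
            ndigits=2,
            n=1,
        )
    )
    return VerificationReport(checks)
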