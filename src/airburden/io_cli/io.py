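"""CSV schemas and round-trip readers/writers.

Dialect is fixed: UTF-8, comma separator, '.' decimal, mandatory header row.
Every reader validates the header against the declared schema (raising
:class:`SchemaError` naming the column) and re-runs the domain-type
invariants (raising :class:`ValidationError` naming state and field).

Panel layout — one CSV per table inside a directory:

========================  =====================================================
file                      columns
========================  =====================================================
population.csv            state_id, age_start, population
life_table.csv            state_id, age, survivorship
employment.csv            state_id, age_start, employment_rate
economy.csv               state_id, gdp_musd, labour_share, employed_count,
                          growth_rate, discount_rate, nonmarket_share,
                          min_working_age, horizon_age
exposure.csv              state_id, pm25_mean, solid_fuel_prop, ozone_ppb
cause_envelopes.csv       state_id, age_start, cause, deaths, yll, yld
========================  =====================================================

Other tables: risk_curves.csv (risk, cause, kind, exposure, rr, tmrel,
rr_exposed — one row per knot for continuous curves, a single row for
categorical ones), burden.csv (the burden-table columns) and losses.csv
(state_id, risk, mortality_loss, morbidity_loss, total_loss, pct_gdp,
per_capita).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..errors import SchemaError
from ..types import (
    AgeGrid,
    BurdenTable,
    EconomyParams,
    EmploymentProfile,
    ExposureSummary,
    LifeTable,
    LossResult,
    RiskCurve,
    StatePanel,
)

PANEL_FILES = {
    "population": ("state_id", "age_start", "population"),
    "life_table": ("state_id", "age", "survivorship"),
    "employment": ("state_id", "age_start", "employment_rate"),
    "economy": (
        "state_id", "gdp_musd", "labour_share", "employed_count", "growth_rate",
        "discount_rate", "nonmarket_share", "min_working_age", "horizon_age",
    ),
    "exposure": ("state_id", "pm25_mean", "solid_fuel_prop", "ozone_ppb"),
    "cause_envelopes": ("state_id", "age_start", "cause", "deaths", "yll", "yld"),
}

CURVE_COLUMNS = ("risk", "cause", "kind", "exposure", "rr", "tmrel", "rr_exposed")
LOSS_COLUMNS = (
    "state_id", "risk", "mortality_loss", "morbidity_loss", "total_loss", "pct_gdp", "per_capita",
)


def _read_csv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header {list(columns)}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def write_panels(panels: Sequence[StatePanel], out_dir: str | Path) -> None:
    """Serialize panels to one CSV per table under ``out_dir``."""
    out = Path(out_dir)
    pop, lt, emp, eco, exp, env = [], [], [], [], [], []
    for p in panels:
        for start, n in zip(p.age_grid.group_starts, p.population):
            pop.append({"state_id": p.state_id, "age_start": start, "population": n})
        for age, l in enumerate(p.life_table.l):
            lt.append({"state_id": p.state_id, "age": age, "survivorship": l})
        for start, e in zip(p.age_grid.group_starts, p.employment.e):
            emp.append({"state_id": p.state_id, "age_start": start, "employment_rate": e})
        eco.append(
            {
                "state_id": p.state_id,
                "gdp_musd": p.economy.gdp,
                "labour_share": p.economy.labour_share,
                "employed_count": p.economy.employed_count,
                "growth_rate": p.economy.growth_rate,
                "discount_rate": p.economy.discount_rate,
                "nonmarket_share": p.economy.nonmarket_share,
                "min_working_age": p.economy.min_working_age,
                "horizon_age": p.economy.horizon_age,
            }
        )
        exp.append(
            {
                "state_id": p.state_id,
                "pm25_mean": p.exposure.pm25_mean,
                "solid_fuel_prop": p.exposure.solid_fuel_prop,
                "ozone_ppb": p.exposure.ozone_ppb,
            }
        )
        env.append(p.cause_envelopes.assign(state_id=p.state_id))
    _write_csv(pd.DataFrame(pop), out / "population.csv")
    _write_csv(pd.DataFrame(lt), out / "life_table.csv")
    _write_csv(pd.DataFrame(emp), out / "employment.csv")
    _write_csv(pd.DataFrame(eco), out / "economy.csv")
    _write_csv(pd.DataFrame(exp), out / "exposure.csv")
    env_df = pd.concat(env, ignore_index=True)
    _write_csv(env_df[list(PANEL_FILES["cause_envelopes"])], out / "cause_envelopes.csv")


def read_panels(in_dir: str | Path) -> list[StatePanel]:
    """Load and validate panels from a directory written by :func:`write_panels`."""
    d = Path(in_dir)
    tables = {
        name: _read_csv(d / f"{name}.csv", cols) for name, cols in PANEL_FILES.items()
    }
    grid = AgeGrid()
    panels: list[StatePanel] = []
    for state_id, eco_row in tables["economy"].set_index("state_id").iterrows():
        pop = (
            tables["population"].query("state_id == @state_id")
            .sort_values("age_start")["population"].to_numpy()
        )
        lt_rows = tables["life_table"].query("state_id == @state_id").sort_values("age")
        emp = (
            tables["employment"].query("state_id == @state_id")
            .sort_values("age_start")["employment_rate"].to_numpy()
        )
        exp_rows = tables["exposure"].query("state_id == @state_id")
        if exp_rows.empty:
            raise SchemaError(f"exposure.csv: no row for state {state_id!r}")
        env = (
            tables["cause_envelopes"].query("state_id == @state_id")
            .drop(columns=["state_id"]).reset_index(drop=True)
        )
        panels.append(
            StatePanel(
                state_id=str(state_id),
                population=pop,
                life_table=LifeTable(l=lt_rows["survivorship"].to_numpy()),
                employment=EmploymentProfile(e=emp, age_grid=grid),
                economy=EconomyParams(
                    gdp=float(eco_row["gdp_musd"]),
                    labour_share=float(eco_row["labour_share"]),
                    employed_count=float(eco_row["employed_count"]),
                    growth_rate=float(eco_row["growth_rate"]),
                    discount_rate=float(eco_row["discount_rate"]),
                    nonmarket_share=float(eco_row["nonmarket_share"]),
                    min_working_age=int(eco_row["min_working_age"]),
                    horizon_age=int(eco_row["horizon_age"]),
                ),
                exposure=ExposureSummary(
                    pm25_mean=float(exp_rows["pm25_mean"].iloc[0]),
                    solid_fuel_prop=float(exp_rows["solid_fuel_prop"].iloc[0]),
                    ozone_ppb=float(exp_rows["ozone_ppb"].iloc[0]),
                ),
                cause_envelopes=env,
                age_grid=grid,
            )
        )
    return panels


def write_risk_curves(curves: Sequence[RiskCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        if c.kind == "continuous":
            for x, rr in zip(c.exposures, c.rrs):
                rows.append(
                    {
                        "risk": c.risk, "cause": c.cause, "kind": c.kind,
                        "exposure": x, "rr": rr, "tmrel": c.tmrel, "rr_exposed": np.nan,
                    }
                )
        else:
            rows.append(
                {
                    "risk": c.risk, "cause": c.cause, "kind": c.kind,
                    "exposure": np.nan, "rr": np.nan, "tmrel": np.nan,
                    "rr_exposed": c.rr_exposed,
                }
            )
    _write_csv(pd.DataFrame(rows, columns=list(CURVE_COLUMNS)), Path(path))


def read_risk_curves(path: str | Path) -> list[RiskCurve]:
    df = _read_csv(Path(path), CURVE_COLUMNS)
    curves = []
    for (risk, cause, kind), g in df.groupby(["risk", "cause", "kind"], sort=False):
        if kind == "continuous":
            g = g.sort_values("exposure")
            curves.append(
                RiskCurve(
                    risk=risk, cause=cause, kind=kind,
                    exposures=g["exposure"].to_numpy(),
                    rrs=g["rr"].to_numpy(),
                    tmrel=float(g["tmrel"].iloc[0]),
                )
            )
        else:
            curves.append(
                RiskCurve(risk=risk, cause=cause, kind=kind, rr_exposed=float(g["rr_exposed"].iloc[0]))
            )
    return curves


def write_burden(table: BurdenTable, path: str | Path) -> None:
    _write_csv(table.df, Path(path))


def read_burden(path: str | Path) -> BurdenTable:
    from ..types import BURDEN_COLUMNS

    return BurdenTable(_read_csv(Path(path), BURDEN_COLUMNS))


def write_losses(results: Sequence[LossResult], path: str | Path) -> None:
    from ..econ import losses_to_frame

    _write_csv(losses_to_frame(results), Path(path))


def read_losses(path: str | Path) -> pd.DataFrame:
    return _read_csv(Path(path), LOSS_COLUMNS)
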