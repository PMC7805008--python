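"""Comparative-risk-assessment arithmetic and descriptive statistics.

Attributable burden is obtained by applying population attributable fractions
(PAFs) to all-risk cause envelopes:

* continuous exposures: PAF = (R̄ − 1)/R̄ with R̄ the exposure-weighted mean
  relative risk over a discrete exposure distribution;
* categorical exposures: PAF = p(RR − 1) / (1 + p(RR − 1)).

Relative-risk curves are piecewise linear in exposure, flat at 1 below the
TMREL and flat at the last knot above it.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedCorrelationError, ValidationError
from .types import BURDEN_COLUMNS, BurdenTable, RiskCurve, StatePanel

__all__ = [
    "relative_risk",
    "paf_continuous",
    "paf_categorical",
    "panel_paf",
    "combine_pafs",
    "attributable_burden",
    "compute_attributable",
    "recover_pafs",
    "point_mass",
    "trapezoid_weights",
    "crude_rate",
    "age_standardised_rate",
    "percent_change",
    "pearson_correlation",
]


def relative_risk(curve: RiskCurve, exposure: float) -> float:
    """RR at ``exposure`` for a continuous curve.

    1 at and below the TMREL, linear between knots, constant beyond the last
    knot.
    """
    if curve.kind != "continuous":
        raise TypeError("relative_risk requires a continuous curve")
    if exposure < 0:
        raise DomainError(f"exposure must be non-negative, got {exposure}")
    if exposure <= curve.tmrel:
        return 1.0
    xs = np.concatenate(([curve.tmrel], curve.exposures))
    ys = np.concatenate(([1.0], curve.rrs))
    # np.interp holds edge values, giving the plateau beyond the last knot
    return float(np.interp(exposure, xs, ys))


def _check_weights(weights: np.ndarray) -> None:
    if np.any(weights < 0):
        raise ValidationError("exposure weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError(f"exposure weights must sum to 1, got {weights.sum()!r}")


def paf_continuous(curve: RiskCurve, exposures: Sequence[float], weights: Sequence[float]) -> float:
    """PAF for a discrete exposure distribution: (R̄ − 1)/R̄, R̄ = Σ wᵢ RR(xᵢ)."""
    x = np.asarray(exposures, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size != w.size:
        raise ValidationError("exposures and weights must have equal length")
    _check_weights(w)
    mean_rr = float(sum(wi * relative_risk(curve, xi) for xi, wi in zip(x, w)))
    return (mean_rr - 1.0) / mean_rr


def paf_categorical(p_exposed: float, rr: float) -> float:
    """PAF for a binary exposure: p(RR − 1) / (1 + p(RR − 1))."""
    if not 0 <= p_exposed <= 1:
        raise DomainError(f"p_exposed must lie in [0, 1], got {p_exposed}")
    if rr < 1:
        raise DomainError(f"rr must be >= 1 (protective exposures unsupported), got {rr}")
    excess = p_exposed * (rr - 1.0)
    return excess / (1.0 + excess)


def point_mass(x: float) -> tuple[list[float], list[float]]:
    """Degenerate exposure distribution concentrated at ``x``."""
    return [x], [1.0]


def trapezoid_weights(grid: Sequence[float], density: Sequence[float]) -> np.ndarray:
    """Normalised trapezoidal quadrature weights for a density sampled on a grid."""
    g = np.asarray(grid, dtype=float)
    d = np.asarray(density, dtype=float)
    if g.size != d.size or g.size < 2:
        raise ValidationError("grid and density must be paired with >= 2 points")
    if np.any(np.diff(g) <= 0):
        raise ValidationError("grid must be strictly increasing")
    if np.any(d < 0):
        raise ValidationError("density must be non-negative")
    spacing = np.empty_like(g)
    spacing[0] = (g[1] - g[0]) / 2
    spacing[-1] = (g[-1] - g[-2]) / 2
    spacing[1:-1] = (g[2:] - g[:-2]) / 2
    w = d * spacing
    total = w.sum()
    if total <= 0:
        raise ValidationError("density integrates to zero")
    return w / total


def panel_paf(curve: RiskCurve, panel: StatePanel) -> float:
    """PAF implied by a panel's exposure summary for one (risk, cause) curve.

    Continuous risks use a point mass at the state mean exposure; the
    household (categorical) risk uses the solid-fuel-use proportion.
    """
    if curve.kind == "categorical":
        return paf_categorical(panel.exposure.solid_fuel_prop, curve.rr_exposed)
    exposure = panel.exposure.pm25_mean if curve.risk == "ambient_pm" else panel.exposure.ozone_ppb
    xs, ws = point_mass(exposure)
    return paf_continuous(curve, xs, ws)


def combine_pafs(pafs: Iterable[float]) -> float:
    """Multiplicative (independence) combination: 1 − Π(1 − PAFᵢ)."""
    out = 1.0
    for p in pafs:
        out *= 1.0 - p
    return 1.0 - out


def attributable_burden(paf: float, envelope: pd.DataFrame) -> pd.DataFrame:
    """Scale one cause's envelope rows by a PAF; DALY recomputed as YLL + YLD."""
    if not 0 <= paf <= 1:
        raise DomainError(f"paf must lie in [0, 1], got {paf}")
    out = envelope.copy()
    for col in ("deaths", "yll", "yld"):
        out[col] = out[col] * paf
    out["daly"] = out["yll"] + out["yld"]
    return out


def compute_attributable(
    panels: Sequence[StatePanel],
    curves: Sequence[RiskCurve],
    include_parent: bool = True,
) -> BurdenTable:
    """Apply the CRA arithmetic to every panel and curve.

    Produces one block of rows per state × (risk, cause) pair covered by
    ``curves``; when ``include_parent`` is set, parent-aggregate rows are added
    with the multiplicative combination of the component PAFs per cause (the
    component rows are never renormalised, so their sum may exceed the parent).
    """
    from .types import PARENT_RISK  # local to avoid cycle noise

    frames: list[pd.DataFrame] = []
    for panel in panels:
        env = panel.cause_envelopes
        pafs_by_cause: dict[str, list[float]] = {}
        for curve in curves:
            paf = panel_paf(curve, panel)
            pafs_by_cause.setdefault(curve.cause, []).append(paf)
            rows = attributable_burden(paf, env.loc[env["cause"] == curve.cause])
            rows = rows.assign(state_id=panel.state_id, risk=curve.risk)
            frames.append(rows[list(BURDEN_COLUMNS)])
        if include_parent:
            for cause, pafs in pafs_by_cause.items():
                parent = combine_pafs(pafs)
                rows = attributable_burden(parent, env.loc[env["cause"] == cause])
                rows = rows.assign(state_id=panel.state_id, risk=PARENT_RISK)
                frames.append(rows[list(BURDEN_COLUMNS)])
    if not frames:
        df = pd.DataFrame(columns=list(BURDEN_COLUMNS))
    else:
        df = pd.concat(frames, ignore_index=True)
    return BurdenTable(df)


def recover_pafs(burden: BurdenTable, panels: Sequence[StatePanel]) -> pd.DataFrame:
    """Back out PAFs from an attributable table and the all-risk envelopes.

    Returns rows (state_id, cause, risk, paf) for every cell whose envelope
    deaths are positive; the PAF is attributable deaths / envelope deaths.
    """
    env_frames = []
    for panel in panels:
        e = panel.cause_envelopes.groupby("cause", as_index=False)["deaths"].sum()
        e["state_id"] = panel.state_id
        env_frames.append(e.rename(columns={"deaths": "envelope_deaths"}))
    env = pd.concat(env_frames, ignore_index=True)
    attr = (
        burden.df.groupby(["state_id", "cause", "risk"], as_index=False)["deaths"].sum()
    )
    merged = attr.merge(env, on=["state_id", "cause"], how="left")
    merged = merged[merged["envelope_deaths"] > 0].copy()
    merged["paf"] = merged["deaths"] / merged["envelope_deaths"]
    return merged[["state_id", "cause", "risk", "paf"]]


def crude_rate(count: float, population: float) -> float:
    """Events per 100 000 population."""
    if population <= 0:
        raise DomainError(f"population must be positive, got {population}")
    return count / population * 100_000.0


def age_standardised_rate(age_rates: Sequence[float], std_weights: Sequence[float]) -> float:
    """Weighted mean of age-specific rates against a standard population."""
    rates = np.asarray(age_rates, dtype=float)
    w = np.asarray(std_weights, dtype=float)
    if rates.size != w.size:
        raise ValidationError("age_rates and std_weights must have equal length")
    _check_weights(w)
    return float(np.dot(w, rates))


def percent_change(v_start: float, v_end: float) -> float:
    """(v_end − v_start)/v_start × 100."""
    if v_start == 0:
        raise DomainError("percent_change undefined for a zero starting value")
    return (v_end - v_start) / v_start * 100.0


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Product-moment correlation: returns (r, r², two-sided p).

    p comes from the t transform with n − 2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValidationError("x and y must have equal length")
    if xa.size < 3:
        raise ValidationError("pearson_correlation needs at least 3 paired values")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("pearson_correlation requires finite values")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    n = xa.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, r * r, p


def pafs_by_state(panels: Sequence[StatePanel], curves: Sequence[RiskCurve]) -> pd.DataFrame:
    """Convenience table of generating/analysed PAFs: (state_id, risk, cause, paf)."""
    rows = []
    for panel in panels:
        for curve in curves:
            rows.append(
                {
                    "state_id": panel.state_id,
                    "risk": curve.risk,
                    "cause": curve.cause,
                    "paf": panel_paf(curve, panel),
                }
            )
    return pd.DataFrame(rows)
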