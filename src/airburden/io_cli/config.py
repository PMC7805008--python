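"""Run configuration: a YAML file validated against a pydantic schema."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from ..errors import ConfigurationError
from ..synthetic_data import GeneratorConfig


class RunConfig(BaseModel):
    """Top-level settings shared by the CLI stages; defaults encode the model's
    standing constants (6% discount, 30% non-market share, 4–8% sensitivity)."""

    seed: int = 0
    n_draws: int = 100
    draw_cv: float = 0.1  # coefficient of variation for input perturbation
    discount_rate: float = 0.06
    sensitivity_rates: list[float] = Field(default_factory=lambda: [0.04, 0.06, 0.08])
    horizon_age: int = 65
    min_working_age: int = 15
    nonmarket_share: float = 0.30
    report_decimals: int = 1  # half-up rounding applied at the reporting layer
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)

    @field_validator("discount_rate", "nonmarket_share")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0 <= v < 1:
            raise ValueError("rates must lie in [0, 1)")
        return v

    @field_validator("sensitivity_rates")
    @classmethod
    def _rates_open_unit(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("sensitivity_rates must be non-empty")
        if any(not 0 < r < 1 for r in v):
            raise ValueError("sensitivity_rates must lie in (0, 1)")
        return v

    def sync_generator(self) -> "RunConfig":
        """Push shared knobs down into the generator block."""
        self.generator.discount_rate = self.discount_rate
        self.generator.nonmarket_share = self.nonmarket_share
        self.generator.min_working_age = self.min_working_age
        self.generator.horizon_age = self.horizon_age
        return self


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return RunConfig().sync_generator()
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config file {p} is not valid YAML: {exc}") from exc
    try:
        return RunConfig.model_validate(data).sync_generator()
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"config file {p} failed validation: {exc}") from exc


def dump_defaults() -> str:
    """YAML rendering of the full default configuration."""
    return yaml.safe_dump(RunConfig().sync_generator().model_dump(), sort_keys=False)
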