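"""Run configuration: YAML round-trip of all pipeline policies."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .annualization import AnnualizationPolicy
from .currency import CurrencyPolicy

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a `compute` run needs besides the study directory.

    ``currency`` maps country labels to PPP/inflation policies; countries
    without an entry are reported in local currency only.
    """

    discount_rate: float = 0.03
    life: dict[str, float] = field(
        default_factory=lambda: {"equipment": 4.0, "furniture": 10.0, "training": 3.0}
    )
    currency: dict[str, dict] = field(default_factory=dict)
    stepdown_ordering: str = "by_cost_desc"
    basis_override: dict[str, str] = field(default_factory=dict)
    weighted_means: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def annualization_policy(self) -> AnnualizationPolicy:
        return AnnualizationPolicy(discount_rate=self.discount_rate, default_life=dict(self.life))

    def currency_policy(self, country: str) -> CurrencyPolicy | None:
        spec = self.currency.get(country)
        if spec is None:
            return None
        return CurrencyPolicy(
            ppp_factor=float(spec["ppp_factor"]),
            inflation_factor=float(spec.get("inflation_factor", 1.0)),
            base_year=str(spec.get("base_year", "2013")),
            label=str(spec.get("label", "Int$ 2013")),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return path
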