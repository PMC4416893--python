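"""Conversion of local-currency costs to base-year international dollars.

Costs collected in different countries and years are made comparable by
(1) inflating from the data year to the base year and (2) dividing by the
country's purchasing-power-parity (PPP) conversion factor, expressed as
local currency units per international dollar.  The composition is a
single positive multiplier, so conversion is linear and commutes with
every aggregation in the pipeline.  PPP and inflation factors are inputs
(supplied per country in config), not retrieved online.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CurrencyPolicy", "to_international"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CurrencyPolicy:
    """PPP and inflation factors for one country's currency.

    ``ppp_factor`` is local currency units per international dollar (> 0);
    ``inflation_factor`` is the multiplier from the data year to the base
    year (> 0, 1.0 when data and base year coincide).
    """

    ppp_factor: float
    inflation_factor: float = 1.0
    base_year: str = "2013"
    label: str = "Int$ 2013"

    def __post_init__(self) -> None:
        if self.ppp_factor <= 0:
            raise ConfigurationError(f"ppp_factor must be > 0, got {self.ppp_factor}")
        if self.inflation_factor <= 0:
            raise ConfigurationError(
                f"inflation_factor must be > 0, got {self.inflation_factor}"
            )

    @property
    def multiplier(self) -> float:
        return self.inflation_factor / self.ppp_factor


def to_international(amount, policy: CurrencyPolicy):
    """Convert local-currency ``amount`` to base-year international dollars.

    Accepts scalars or any array-like supporting scalar multiplication
    (numpy arrays, pandas Series/DataFrames), so whole cost matrices and
    report tables convert cell-wise in one call.
    """
    return amount * policy.multiplier
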