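"""Capital annualization: one-time outlays to equivalent annual costs.

Capital goods (equipment, furniture, training investments) deliver their
services over several years; costing a single year therefore spreads the
replacement value over the asset's useful life using the present-value
annuity factor at a discount rate (3% per year by default, the standard
rate in health-economic costing guidelines):

    a(r, n) = (1 - (1 + r)^-n) / r          (a(0, n) = n)

    annual cost = replacement value / a(r, n)

Buildings are the exception: they are valued directly as an annual
rental-equivalent (rent per square metre x floor area from a local rental
survey), which is already an annual cost and bypasses annuitization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cost_model import CapitalItem, ParameterError

__all__ = [
    "AnnualizationPolicy",
    "AnnualizedCost",
    "annualization_factor",
    "annualize_item",
    "annualize_training",
    "building_annual_rent",
]


class ConfigurationError(ValueError):
    """A policy/config value is missing or out of domain."""


@dataclass
class AnnualizationPolicy:
    """Discount rate and default asset lives (years) by capital subcategory.

    Equipment life defaults to 4 years (midpoint of the typical 3-5 year
    range), furniture to 10, training to 3; all overridable per item or
    via config.  Buildings carry no life: they are valued as annual rent.
    """

    discount_rate: float = 0.03
    default_life: dict[str, float] = field(
        default_factory=lambda: {"equipment": 4.0, "furniture": 10.0, "training": 3.0}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigurationError(
                f"discount_rate must be in [0, 1), got {self.discount_rate}"
            )
        for sub, life in self.default_life.items():
            if life <= 0:
                raise ConfigurationError(f"default life for {sub!r} must be > 0, got {life}")

    def life_for(self, item: CapitalItem) -> float:
        if item.useful_life is not None:
            return item.useful_life
        try:
            return self.default_life[item.subcategory]
        except KeyError:
            raise ConfigurationError(
                f"capital item {item.item_id}: no useful_life and no default life "
                f"for subcategory {item.subcategory!r}"
            ) from None


@dataclass(frozen=True)
class AnnualizedCost:
    """Economic and financial annual cost of one capital item."""

    economic: float
    financial: float


def annualization_factor(rate: float, life: float) -> float:
    """Present-value annuity factor a(rate, life) = sum_{t=1..life} (1+rate)^-t.

    At ``rate == 0`` the continuity limit ``life`` is returned exactly, so
    zero-rate annualization reduces to straight-line depreciation.
    """
    if life <= 0:
        raise ParameterError(f"life must be > 0, got {life}")
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    if rate == 0:
        return float(life)
    return (1.0 - (1.0 + rate) ** (-life)) / rate


def annualize_item(item: CapitalItem, policy: AnnualizationPolicy) -> AnnualizedCost:
    """Annual economic and financial cost of one capital item.

    Buildings (valued as annual rent) pass through unchanged; everything
    else is divided by the annuity factor over the item's resolved life.
    Donated goods have zero financial outlay, so their financial annual
    cost is zero while the economic cost reflects the replacement value.
    Values are per unit; the line total multiplies by ``quantity``.
    """
    q = item.quantity
    fin_outlay = item.financial_outlay or 0.0
    if item.subcategory == "building":
        return AnnualizedCost(economic=item.replacement_value * q, financial=fin_outlay * q)
    life = policy.life_for(item)
    af = annualization_factor(policy.discount_rate, life)
    return AnnualizedCost(
        economic=item.replacement_value * q / af,
        financial=fin_outlay * q / af,
    )


def annualize_training(
    facilitation_cost: float,
    per_diems: float,
    transport: float,
    policy: AnnualizationPolicy,
) -> float:
    """Annual cost of a training investment.

    Training is costed from its three components (facilitation, staff per
    diems, transport allowances) and annuitized over the policy training
    life, treating the acquired skills as a capital good.
    """
    components = (facilitation_cost, per_diems, transport)
    if any(c < 0 for c in components):
        raise ParameterError(f"training cost components must be >= 0, got {components}")
    total = float(sum(components))
    life = policy.default_life.get("training")
    if life is None:
        raise ConfigurationError("policy has no default life for 'training'")
    return total / annualization_factor(policy.discount_rate, life)


def building_annual_rent(rent_per_sqm: float, floor_area: float) -> float:
    """Annual rental-equivalent value of building space (rent/m2 x m2)."""
    if rent_per_sqm < 0 or floor_area < 0:
        raise ParameterError("rent_per_sqm and floor_area must be >= 0")
    return rent_per_sqm * floor_area
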