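"""Bottom-up micro-costing of the injectate.

Per-injection cost of a low-cost platelet-rich plasma (LC-PRP) preparation
is built from an itemized supply list plus timed medical-assistant labor;
the corticosteroid comparator is costed as the medication vial alone.
All currency arithmetic is carried out in integer cents so that totals are
exact and independent of summation order; reported totals are rounded
half-up to whole dollars, matching the convention of quoting whole-dollar
injection prices assembled from sub-dollar components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "CostItem",
    "LaborInput",
    "InjectionCost",
    "injectate_cost",
    "default_supply_items",
    "dollars_to_cents",
    "cents_to_dollars",
]


def dollars_to_cents(amount: float | str | Decimal) -> int:
    """Convert a dollar amount to integer cents (half-up at the cent)."""
    cents = (Decimal(str(amount)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    return int(cents)


def cents_to_dollars(cents: int) -> float:
    return cents / 100.0


def _round_half_up_dollars(cents: int) -> int:
    """Round integer cents to whole dollars, half-up."""
    if cents < 0:
        raise ValueError("negative currency amount")
    return (cents + 50) // 100


@dataclass(frozen=True)
class CostItem:
    """One supply line item: unit cost in integer cents x quantity per injection."""

    name: str
    unit_cost_cents: int
    quantity: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_cost_cents < 0:
            raise ValueError(f"negative unit cost for item {self.name!r}")
        if self.quantity < 0:
            raise ValueError(f"negative quantity for item {self.name!r}")

    @classmethod
    def from_dollars(cls, name: str, unit_cost_usd: float, quantity: float = 1.0) -> "CostItem":
        return cls(name=name, unit_cost_cents=dollars_to_cents(unit_cost_usd), quantity=quantity)

    @property
    def line_total_cents(self) -> int:
        total = Decimal(self.unit_cost_cents) * Decimal(str(self.quantity))
        return int(total.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LaborInput:
    """Timed labor: hourly wage (cents/h) and minutes per injection."""

    wage_cents_per_hour: int
    minutes_per_injection: float

    def __post_init__(self) -> None:
        if self.wage_cents_per_hour < 0:
            raise ValueError("negative wage rate")
        if self.minutes_per_injection < 0:
            raise ValueError("negative labor minutes")

    @classmethod
    def from_dollars(cls, wage_usd_per_hour: float, minutes_per_injection: float) -> "LaborInput":
        return cls(dollars_to_cents(wage_usd_per_hour), minutes_per_injection)

    @property
    def exact_cost(self) -> Fraction:
        """Exact labor cost in cents (rational): wage x minutes / 60, unrounded."""
        return (
            Fraction(self.wage_cents_per_hour)
            * Fraction(Decimal(str(self.minutes_per_injection)))
            / 60
        )

    @property
    def cost_cents(self) -> int:
        total = Decimal(self.wage_cents_per_hour) * Decimal(str(self.minutes_per_injection)) / Decimal(60)
        return int(total.quantize(Decimal("1"), rounding=ROUND_HALF_UP))

    @classmethod
    def from_timing_log(
        cls, wage_usd_per_hour: float, durations_minutes: Sequence[float]
    ) -> "LaborInput":
        """Build labor input from per-injection processing times (mean minutes)."""
        if len(durations_minutes) == 0:
            raise ValueError("empty timing log")
        if any(d < 0 for d in durations_minutes):
            raise ValueError("negative duration in timing log")
        mean_minutes = float(sum(durations_minutes)) / len(durations_minutes)
        return cls.from_dollars(wage_usd_per_hour, mean_minutes)


@dataclass(frozen=True)
class InjectionCost:
    """Per-injection cost decomposition for one strategy."""

    strategy: str
    supplies_cents: int
    labor_cents: int
    medication_cents: int

    @property
    def total_cents(self) -> int:
        return self.supplies_cents + self.labor_cents + self.medication_cents

    @property
    def total_unrounded_usd(self) -> float:
        return cents_to_dollars(self.total_cents)

    @property
    def total_reported_usd(self) -> int:
        """Whole-dollar reported figure (round half-up)."""
        return _round_half_up_dollars(self.total_cents)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "supplies_usd": cents_to_dollars(self.supplies_cents),
            "labor_usd": cents_to_dollars(self.labor_cents),
            "medication_usd": cents_to_dollars(self.medication_cents),
            "total_unrounded_usd": self.total_unrounded_usd,
            "total_reported_usd": self.total_reported_usd,
        }


def injectate_cost(
    items: Iterable[CostItem],
    labor: LaborInput | None = None,
    medication_cents: int = 0,
    strategy: str = "lc_prp",
) -> InjectionCost:
    """Sum itemized supplies, labor time x wage, and medication into one injection cost.

    Parameters
    ----------
    items:
        Supply line items; an empty iterable contributes $0.
    labor:
        Wage rate and preparation minutes; ``None`` contributes $0.
    medication_cents:
        Drug cost in integer cents (e.g. a triamcinolone vial for the
        corticosteroid strategy).
    """
    if medication_cents < 0:
        raise ValueError("negative medication cost")
    supplies = sum(item.line_total_cents for item in items)
    labor_cents = labor.cost_cents if labor is not None else 0
    return InjectionCost(
        strategy=strategy,
        supplies_cents=supplies,
        labor_cents=labor_cents,
        medication_cents=medication_cents,
    )


def default_supply_items() -> list[CostItem]:
    """The LC-PRP preparation supply list: $4.00 of consumables per injection."""
    return [
        CostItem.from_dollars("tourniquet", 0.25, 1),
        CostItem.from_dollars("butterfly venipuncture kit", 0.50, 1),
        CostItem.from_dollars("three-way stopcock", 0.50, 1),
        CostItem.from_dollars("syringe cap", 0.25, 3),
        CostItem.from_dollars("syringe", 0.25, 4),
        CostItem.from_dollars("anticoagulant (ACD-A)", 1.00, 1),
    ]
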