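"""Protocol cost accounting in exact decimal arithmetic.

Currency is unit-agnostic (a label is carried through from configuration)
and handled as :class:`decimal.Decimal` so totals are exact to the cent —
no binary floating drift in money columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Union

from .errors import ValidationError

__all__ = ["CostParams", "CostReport", "protocol_cost"]

Money = Union[int, str, Decimal]


def _to_decimal(name: str, value: Money) -> Decimal:
    try:
        dec = Decimal(repr(value)) if isinstance(value, float) else Decimal(value)
    except Exception as exc:
        raise ValidationError(f"{name} must be a decimal amount, got {value!r}") from exc
    if dec < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")
    return dec


@dataclass(frozen=True)
class CostParams:
    """Unit costs and the number of cheap-test rounds in the protocol."""

    fit_unit_cost: Decimal = Decimal(5)
    colonoscopy_unit_cost: Decimal = Decimal(500)
    n_fit_rounds: int = 4
    currency: str = "USD"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fit_unit_cost", _to_decimal("fit_unit_cost", self.fit_unit_cost)
        )
        object.__setattr__(
            self,
            "colonoscopy_unit_cost",
            _to_decimal("colonoscopy_unit_cost", self.colonoscopy_unit_cost),
        )
        if int(self.n_fit_rounds) != self.n_fit_rounds or self.n_fit_rounds < 0:
            raise ValidationError(
                f"n_fit_rounds must be a nonnegative integer, got {self.n_fit_rounds!r}"
            )


@dataclass(frozen=True)
class CostReport:
    """Cost totals; ``savings = full_screen_total - protocol_total``."""

    fit_total: Decimal
    colonoscopy_total: Decimal
    protocol_total: Decimal
    full_screen_total: Decimal
    savings: Decimal
    currency: str = "USD"


def protocol_cost(
    cohort_size: int, urgent_integer: int, params: CostParams
) -> CostReport:
    """Cost of the repeated-test protocol versus screening everyone directly.

    ``cohort_size * n_fit_rounds * fit_unit_cost`` for the cheap tests plus
    ``urgent_integer * colonoscopy_unit_cost`` confirmatory procedures,
    compared against ``cohort_size * colonoscopy_unit_cost``.
    """
    if cohort_size < 0:
        raise ValidationError(f"cohort_size must be >= 0, got {cohort_size!r}")
    if urgent_integer < 0:
        raise ValidationError(f"urgent_integer must be >= 0, got {urgent_integer!r}")
    fit_total = Decimal(cohort_size) * params.n_fit_rounds * params.fit_unit_cost
    colonoscopy_total = Decimal(urgent_integer) * params.colonoscopy_unit_cost
    protocol_total = fit_total + colonoscopy_total
    full_screen_total = Decimal(cohort_size) * params.colonoscopy_unit_cost
    return CostReport(
        fit_total=fit_total,
        colonoscopy_total=colonoscopy_total,
        protocol_total=protocol_total,
        full_screen_total=full_screen_total,
        savings=full_screen_total - protocol_total,
        currency=params.currency,
    )
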