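"""Currency-tagged amounts and report-precision rounding.

All internal computation is carried out in Indian rupees (INR); US-dollar
figures appear only at reporting time through an explicit conversion at a
stated exchange rate. Report cells are rounded half-up (the convention used
for printed cost tables), never with banker's rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from .errors import CurrencyError


class Currency(str, Enum):
    INR = "INR"
    USD = "USD"


def printed(x: float, dp: int = 1) -> float:
    """Round *x* half-up to *dp* decimal places, as a printed table cell.

    Golden comparisons against published tables must go through this helper
    rather than ``round`` (which rounds half-even) or raw float comparison.
    """
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Money:
    """A non-negative amount in a single currency.

    Arithmetic is only defined between equal currencies; mixing raises
    :class:`~costkit.errors.CurrencyError`. Subtraction below zero raises
    ``ValueError`` because cost components are non-negative by construction.
    """

    amount: float
    currency: Currency = Currency.INR

    def __post_init__(self):
        if isinstance(self.currency, str) and not isinstance(self.currency, Currency):
            object.__setattr__(self, "currency", Currency(self.currency))
        if not math.isfinite(self.amount):
            raise ValueError(f"money amount must be finite, got {self.amount!r}")
        if self.amount < 0:
            raise ValueError(f"money amount must be non-negative, got {self.amount!r}")

    def _check(self, other: "Money") -> None:
        if not isinstance(other, Money):
            raise TypeError(f"expected Money, got {type(other).__name__}")
        if other.currency != self.currency:
            raise CurrencyError(
                f"cannot combine {self.currency.value} with {other.currency.value}; "
                "convert explicitly first"
            )

    def __add__(self, other: "Money") -> "Money":
        self._check(other)
        return Money(self.amount + other.amount, self.currency)

    def __sub__(self, other: "Money") -> "Money":
        self._check(other)
        diff = self.amount - other.amount
        if diff < -1e-9:
            raise ValueError(
                f"subtraction would produce negative money ({diff:.4f} {self.currency.value})"
            )
        return Money(max(diff, 0.0), self.currency)

    def __mul__(self, k: float) -> "Money":
        if isinstance(k, Money):
            raise TypeError("cannot multiply Money by Money")
        return Money(self.amount * float(k), self.currency)

    __rmul__ = __mul__

    def __truediv__(self, k: float) -> "Money":
        return Money(self.amount / float(k), self.currency)

    def printed(self, dp: int = 1) -> float:
        return printed(self.amount, dp)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sym = "₹" if self.currency is Currency.INR else "US$"
        return f"{sym}{self.amount:,.2f}"


def inr(amount: float) -> Money:
    return Money(amount, Currency.INR)


def usd(amount: float) -> Money:
    return Money(amount, Currency.USD)


def to_usd(x: Money, rate: float, decimals: int = 2) -> Money:
    """Convert an INR amount to USD at ``rate`` INR per USD.

    Rounds half-up to ``decimals`` places (2 for unit prices, 1 for report
    cells). Converting an amount that is already in USD is an error so that
    a figure can never be divided by the exchange rate twice.
    """
    if x.currency is Currency.USD:
        raise CurrencyError("amount is already in USD; refusing double conversion")
    if rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {rate!r}")
    q = Decimal(1).scaleb(-decimals)
    converted = (Decimal(repr(x.amount)) / Decimal(repr(float(rate)))).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return Money(float(converted), Currency.USD)
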