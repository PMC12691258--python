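"""Decimal-based display rounding helpers (half-up, unlike Python's round)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` half away from zero at ``ndigits`` decimals.

    Operates on the shortest decimal repr of the float, so 2.675 (stored as
    2.67499…) still rounds the way its printed form suggests it should not —
    i.e. faithfully to the binary value.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
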