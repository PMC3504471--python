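"""Reporting-precision helpers.

Printed ages are rounded to the nearest whole day and fractions to two
decimals, with ties rounded half away from zero (so 56.5 reports as 57, and
-0.5 as -1) — the convention used throughout the reported numbers, as opposed
to Python's banker's rounding.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away", "days_to_weeks"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def days_to_weeks(days: float) -> float:
    """Convert days to weeks at the 1-decimal reporting precision."""
    return round_half_away(days / 7.0, 1)
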