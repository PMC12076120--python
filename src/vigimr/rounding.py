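"""Half-up decimal rounding, as used for every printed percentage."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero upward."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_of(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """``100·numerator/denominator`` rounded half-up, computed in exact
    decimal arithmetic so printed-ratio checks are not at the mercy of
    binary floating point."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for a zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))
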