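"""Half-up rounding, matching the SAS-style convention of the printed tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

__all__ = ["round_half_up", "pct"]


def round_half_up(x: float | int | Decimal, decimals: int = 0) -> float:
    """Round *x* half-up (ties away from zero) at *decimals* places.

    Python's built-in round() is banker's rounding (round-half-even); the
    published tables round 0.5 up, so 22.15 -> 22.2 and 866.5 -> 867.
    """
    if not isinstance(x, Decimal):
        x = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-decimals)
    return float(x.quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``100*numerator/denominator`` rounded half-up.

    Exact for integer inputs (no binary-float division error): 655/2958
    gives 22.1, 2303/2958 gives 77.9, 31/241 gives 12.9.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    if float(numerator).is_integer() and float(denominator).is_integer():
        frac = Fraction(int(numerator) * 100, int(denominator))
        return round_half_up(Decimal(frac.numerator) / Decimal(frac.denominator), decimals)
    return round_half_up(100.0 * numerator / denominator, decimals)
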