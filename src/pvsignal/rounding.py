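"""Fixed rounding rule for all printed percentages.

Published cohort tables in pharmacovigilance papers round percentages
half-up to one decimal place (86/421 prints as 20.4, 274/421 as 65.1).
Every percentage this package prints goes through :func:`percentage`, so
tables recompute exactly from their printed numerators and denominators.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float | Decimal, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to 1 decimal.

    The division is done in decimal arithmetic so ties round predictably.
    """
    if denominator <= 0:
        raise ValueError("percentage: denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("percentage: numerator must lie in [0, denominator]")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
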