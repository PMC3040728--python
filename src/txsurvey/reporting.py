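"""Table-parity rounding helpers.

Published assembly reports print ratios and percentages at one-decimal
precision.  Survey summaries here carry full-precision values and round only
at the reporting boundary, using half-up rounding (so 8.75 -> 8.8), which is
what spreadsheet-style reports produce; Python's builtin banker's rounding
would disagree on exact .x5 boundaries.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round `value` to `ndigits` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float) -> float:
    """Full-precision percentage numerator/denominator * 100."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return 100.0 * numerator / denominator


def report_percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded the way the summary tables print it."""
    return round_half_up(percent(numerator, denominator), ndigits)


def report_ratio(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Ratio rounded at report precision (e.g. mean isotigs per isogroup)."""
    if denominator == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    return round_half_up(numerator / denominator, ndigits)
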