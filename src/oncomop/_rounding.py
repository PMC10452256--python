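"""Half-up decimal rounding shared by the reporting operations.

Python's built-in ``round`` uses banker's rounding; registry reports
conventionally round half away from zero, so percentages are computed
through :func:`round_half_up`.
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round *value* to *ndigits* decimals, ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded.

    Raises ``ValueError`` on a zero denominator: a rate over an empty
    base is undefined, not 0 or 100.
    """
    if denominator == 0:
        raise ValueError("cannot compute a percentage over a zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
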