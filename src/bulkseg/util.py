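"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding.

    Reported percentages and Mb spans use this so printed values are stable
    and match the two-decimal convention used throughout the results tables.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
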