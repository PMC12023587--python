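"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as clinical tables are printed.

    Python's builtin ``round`` is banker's rounding; percentage tables in
    pathology reports round 0.005 up, so we go through ``Decimal``.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """count/total as a percentage rounded half-up; 0.0 for an empty total."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)
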