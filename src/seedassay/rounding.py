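"""Display rounding used throughout reports.

All internal arithmetic is carried at full double precision; only values
destined for human-readable tables pass through :func:`round_half_away`.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's builtin ``round`` uses banker's rounding; clinical QA tables
    conventionally round 0.05 up (and -0.05 down), so we go through
    ``decimal`` with ``ROUND_HALF_UP`` on the shortest decimal
    representation of the float.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
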